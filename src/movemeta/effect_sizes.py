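"""Effect-size arithmetic for individual-level physiology-movement correlations.

Raw records carry either a correlation coefficient ``r`` directly or an
inferential statistic (t, F with numerator df = 1, or chi-square with df = 1)
that converts to ``r`` by the standard point-biserial / contingency formulas.
Correlations are placed on the Fisher-z scale,

    z = atanh(r) = 0.5 * ln((1 + r) / (1 - r)),    v(z) = 1 / (n - 3),

which stabilises the sampling variance and makes effects approximately
Gaussian.  Effects are then sign-aligned so that positive values always mean
"more physiological capacity goes with more movement": traits where a *lower*
raw value indicates higher performance (critical thermal minimum, latency to
enter a novel area, cost of transport) have their sign reversed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "fisher_z",
    "fisher_z_variance",
    "r_from_stat",
    "align_sign",
    "recode_metabolic",
    "min_k_filter",
    "compute_effect_sizes",
    "load_individual_csv",
    "REVERSE_CODED_TRAITS",
    "METABOLIC_GROUPS",
    "ConversionError",
]

RAW_COLUMNS = [
    "study_id", "species", "r", "stat_type", "stat_value", "df", "n",
    "direction", "movement_class", "trait_category", "trait_subtype",
    "taxon_group", "thermal_strategy", "sex", "age", "origin", "pub_year",
]

#: Traits measured so that a smaller raw value means better performance.
#: Effects on these traits are multiplied by -1 during alignment.  The set is
#: config-driven: callers may pass their own collection to align_sign.
REVERSE_CODED_TRAITS = frozenset({
    "ctmin",
    "latency",
    "cost of transport",
})

#: Metabolic-rate subtype labels collapsed into three analysis groups:
#: non-active (basal/resting/standard), active (voluntary movement averaged
#: over a recording period, e.g. routine/field), and maximum (forced exercise
#: or immediately post-exhaustion).
METABOLIC_GROUPS: dict[str, str] = {
    "basal metabolic rate": "non-active MR",
    "resting metabolic rate": "non-active MR",
    "standard metabolic rate": "non-active MR",
    "routine metabolic rate": "active MR",
    "field metabolic rate": "active MR",
    "active metabolic rate": "active MR",
    "maximum metabolic rate": "maximum MR",
    "peak metabolic rate": "maximum MR",
    "post-exhaustion vo2max": "maximum MR",
    "vo2max": "maximum MR",
}


class ConversionError(ValueError):
    """A raw record cannot be converted to a valid effect size."""

    def __init__(self, reason_code: str, message: str):
        self.reason_code = reason_code
        super().__init__(message)


def fisher_z(r: float) -> float:
    """Fisher z-transform of a correlation, 0.5*ln((1+r)/(1-r)).

    Raises ConversionError for |r| >= 1 (transform diverges).
    """
    if not -1.0 < r < 1.0:
        raise ConversionError("r_out_of_range", f"correlation r={r!r} not in (-1, 1)")
    return math.atanh(r)


def fisher_z_variance(n: int) -> float:
    """Sampling variance of Fisher z, 1/(n-3); requires n >= 4."""
    n = int(n)
    if n < 4:
        raise ConversionError("n_too_small", f"sample size n={n} < 4; variance 1/(n-3) undefined")
    return 1.0 / (n - 3)


def r_from_stat(stat_type: str, stat_value: float, df: int | None = None,
                n: int | None = None, direction: str | None = None) -> float:
    """Convert an inferential statistic to a correlation coefficient.

    t:    r = t / sqrt(t^2 + df), carrying the sign of t.
    F:    only numerator df = 1 admits a unique r; r = sqrt(F / (F + df))
          with df the denominator df, sign taken from ``direction``.
    chi2: only df = 1; r = sqrt(chi2 / n), sign from ``direction``.

    Unsigned statistics (F, chi2) with no reported direction are rejected
    rather than assigned a sign.
    """
    stat_type = stat_type.strip().lower()
    if stat_type == "t":
        if df is None or df < 1:
            raise ConversionError("missing_df", "t-statistic requires positive df")
        t = float(stat_value)
        return t / math.sqrt(t * t + df)
    if stat_type in ("f", "chi2"):
        if stat_value < 0:
            raise ConversionError("negative_stat", f"{stat_type} statistic must be >= 0")
        if direction not in ("positive", "negative"):
            raise ConversionError(
                "missing_direction",
                f"unsigned {stat_type} statistic requires a reported direction")
        sign = 1.0 if direction == "positive" else -1.0
        if stat_type == "f":
            if df is None or df < 1:
                raise ConversionError("missing_df", "F-statistic requires denominator df")
            r = math.sqrt(stat_value / (stat_value + df))
        else:
            if n is None or n < 4:
                raise ConversionError("missing_n", "chi2 conversion requires n >= 4")
            r = math.sqrt(stat_value / n)
            if r >= 1.0:
                raise ConversionError("r_out_of_range", f"chi2/n gives |r|={r} >= 1")
        return sign * r
    raise ConversionError("unknown_stat", f"unknown statistic type {stat_type!r}")


def align_sign(effect: float, trait_subtype: str,
               reverse_coded=REVERSE_CODED_TRAITS) -> tuple[float, bool]:
    """Align an effect so positive means higher capacity with more movement.

    Reverse-coded traits (lower raw value = better performance) are negated;
    returns (aligned_effect, sign_flipped).  Applying twice restores the input.
    """
    key = str(trait_subtype).strip().lower()
    if key in {t.lower() for t in reverse_coded}:
        return -effect, True
    return effect, False


def recode_metabolic(trait_subtype: str, groups: dict[str, str] | None = None) -> str:
    """Collapse a metabolic-rate subtype label into one of three groups.

    Returns "unclassified" for labels outside the mapping; such records are
    excluded from the subtype model but kept elsewhere.
    """
    mapping = METABOLIC_GROUPS if groups is None else groups
    key = str(trait_subtype).strip().lower()
    return mapping.get(key, "unclassified")


def min_k_filter(records: pd.DataFrame, grouping: str, k_min: int = 5
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Keep only groups with at least ``k_min`` effect sizes.

    Returns (retained records, counts of dropped groups).
    """
    if records.empty:
        return records, pd.Series(dtype=int)
    counts = records[grouping].value_counts()
    keep = counts[counts >= k_min].index
    dropped = counts[counts < k_min]
    return records[records[grouping].isin(keep)].copy(), dropped


@dataclass
class EffectSizeTable:
    """Converted effect sizes plus the rejection log."""

    effects: pd.DataFrame
    rejections: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["study_id", "row", "reason_code", "detail"]))

    @property
    def k(self) -> int:
        return len(self.effects)


def _convert_row(row: pd.Series) -> dict:
    has_r = pd.notna(row.get("r"))
    stat_type = row.get("stat_type")
    has_stat = pd.notna(stat_type) and str(stat_type).strip().lower() in ("t", "f", "chi2")
    if has_r == has_stat:
        raise ConversionError(
            "ambiguous_source",
            "exactly one of r or an inferential statistic must be present")
    n = row.get("n")
    if pd.isna(n):
        raise ConversionError("missing_n", "sample size n is required")
    n = int(n)
    if has_r:
        r = float(row["r"])
    else:
        df = row.get("df")
        r = r_from_stat(
            str(stat_type), float(row["stat_value"]),
            df=int(df) if pd.notna(df) else None,
            n=n, direction=row.get("direction") if pd.notna(row.get("direction")) else None)
    z = fisher_z(r)
    v = fisher_z_variance(n)
    z_aligned, flipped = align_sign(z, row.get("trait_subtype", ""))
    return {
        "z": z_aligned,
        "v_z": v,
        "se_z": math.sqrt(v),
        "sign_flipped": flipped,
        "r_source": r,
        "high_variance": n <= 6,
    }


def compute_effect_sizes(raw: pd.DataFrame) -> EffectSizeTable:
    """Convert a table of raw records into aligned Fisher-z effect sizes.

    Invalid records (unconvertible statistics, n < 4, |r| >= 1, missing
    direction) are dropped into the rejection log with a reason code instead
    of raising.
    """
    effects, rejects = [], []
    for idx, row in raw.iterrows():
        try:
            out = _convert_row(row)
        except ConversionError as exc:
            rejects.append({
                "study_id": row.get("study_id"), "row": idx,
                "reason_code": exc.reason_code, "detail": str(exc)})
            continue
        rec = {c: row.get(c) for c in RAW_COLUMNS if c in raw.columns}
        rec.update(out)
        if str(rec.get("trait_category", "")).strip().lower() == "metabolism":
            rec["metabolic_group"] = recode_metabolic(rec.get("trait_subtype", ""))
        effects.append(rec)
    effects_df = pd.DataFrame(effects)
    rejections_df = pd.DataFrame(
        rejects, columns=["study_id", "row", "reason_code", "detail"])
    return EffectSizeTable(effects=effects_df, rejections=rejections_df)


def load_individual_csv(path) -> EffectSizeTable:
    """Read a raw individual-movement CSV and convert it to effect sizes."""
    raw = pd.read_csv(path)
    missing = [c for c in ("study_id", "species", "n") if c not in raw.columns]
    if missing:
        raise ValueError(f"input CSV missing required columns: {missing}")
    return compute_effect_sizes(raw)
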