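"""Core-versus-edge contrasts and the range-expansion regressions.

Each record compares a physiological trait between an established range core
and the expanding range edge (dispersal front).  The effect size is the log
response ratio

    lnRR = ln(mean_edge / mean_core),
    v(lnRR) = SD_edge^2 / (N_edge * mean_edge^2) + SD_core^2 / (N_core * mean_core^2),

and the rate of range expansion is the core-to-edge distance divided by the
time since the populations diverged (km per year).  Two unweighted Gaussian
regressions follow: dispersal rate on a climate difference (temperature or
precipitation) interacting with dispersal mode, and |lnRR| on divergence time
interacting with dispersal mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .effect_sizes import align_sign, ConversionError

__all__ = [
    "lnrr", "lnrr_variance", "dispersal_rate",
    "sd_from_se", "sd_from_ci",
    "compute_range_effects", "load_core_edge_csv",
    "RegressionResult", "climate_rate_regression", "divergence_time_regression",
    "DISPERSAL_MODES",
]

DISPERSAL_MODES = ("aerial", "aquatic", "terrestrial")

CORE_EDGE_COLUMNS = [
    "study_id", "species", "trait_category", "trait_subtype",
    "mean_core", "mean_edge", "sd_core", "sd_edge", "n_core", "n_edge",
    "year_core_established", "year_edge_established", "distance_km",
    "delta_temp_C", "delta_precip_mm", "dispersal_mode", "range_type",
    "taxon_group", "pub_year",
]


def lnrr(mean_edge: float, mean_core: float) -> float:
    """Log response ratio ln(mean_edge / mean_core); both means must be > 0."""
    if mean_edge <= 0 or mean_core <= 0:
        raise ConversionError("nonpositive_mean",
                              f"lnRR undefined for means ({mean_edge}, {mean_core})")
    return math.log(mean_edge / mean_core)


def lnrr_variance(sd_edge: float, n_edge: int, mean_edge: float,
                  sd_core: float, n_core: int, mean_core: float) -> float:
    """Delta-method sampling variance of the log response ratio."""
    if mean_edge <= 0 or mean_core <= 0:
        raise ConversionError("nonpositive_mean", "means must be positive")
    if n_edge < 2 or n_core < 2:
        raise ConversionError("n_too_small", "group sizes must be >= 2")
    if sd_edge < 0 or sd_core < 0:
        raise ConversionError("negative_sd", "standard deviations must be >= 0")
    return (sd_edge ** 2 / (n_edge * mean_edge ** 2)
            + sd_core ** 2 / (n_core * mean_core ** 2))


def dispersal_rate(distance_km: float, year_core: float, year_edge: float) -> float:
    """Range-expansion rate in km per year; undefined when the years coincide."""
    if distance_km < 0:
        raise ConversionError("negative_distance", "distance must be >= 0")
    dt = year_edge - year_core
    if dt <= 0:
        raise ConversionError("zero_divergence_time",
                              "edge establishment must postdate the core")
    return distance_km / dt


def sd_from_se(se: float, n: int) -> float:
    return se * math.sqrt(n)


def sd_from_ci(ci_half_width: float, n: int) -> float:
    return ci_half_width * math.sqrt(n) / 1.96


@dataclass
class RangeEffectTable:
    effects: pd.DataFrame
    rejections: pd.DataFrame


def compute_range_effects(raw: pd.DataFrame) -> RangeEffectTable:
    """Turn raw core/edge rows into lnRR effects with dispersal rates.

    Variation may arrive as SD (``sd_*``), SE (``se_*``) or 95% CI half-width
    (``ci_*``) columns; SE/CI are converted to SD on load.  Records with
    nonpositive means or missing establishment years are rejected with a
    reason code, mirroring the exclusion of studies that did not report when
    the core population was established.
    """
    effects, rejects = [], []
    for idx, row in raw.iterrows():
        try:
            rec = _convert_range_row(row)
        except ConversionError as exc:
            rejects.append({"study_id": row.get("study_id"), "row": idx,
                            "reason_code": exc.reason_code, "detail": str(exc)})
            continue
        effects.append(rec)
    return RangeEffectTable(
        effects=pd.DataFrame(effects),
        rejections=pd.DataFrame(rejects, columns=["study_id", "row",
                                                  "reason_code", "detail"]))


def _group_sd(row, side: str) -> float:
    n = int(row[f"n_{side}"])
    sd = row.get(f"sd_{side}")
    if pd.notna(sd):
        return float(sd)
    se = row.get(f"se_{side}")
    if pd.notna(se):
        return sd_from_se(float(se), n)
    ci = row.get(f"ci_{side}")
    if pd.notna(ci):
        return sd_from_ci(float(ci), n)
    raise ConversionError("missing_dispersion", f"no SD/SE/CI for {side} group")


def _convert_range_row(row: pd.Series) -> dict:
    mode = str(row.get("dispersal_mode", "")).strip().lower()
    if mode not in DISPERSAL_MODES:
        raise ConversionError("bad_dispersal_mode",
                              f"dispersal_mode must be one of {DISPERSAL_MODES}")
    for col in ("mean_core", "mean_edge", "n_core", "n_edge"):
        if pd.isna(row.get(col)):
            raise ConversionError("missing_field", f"{col} is required")
    m_c, m_e = float(row["mean_core"]), float(row["mean_edge"])
    n_c, n_e = int(row["n_core"]), int(row["n_edge"])
    sd_c, sd_e = _group_sd(row, "core"), _group_sd(row, "edge")
    value = lnrr(m_e, m_c)
    v = lnrr_variance(sd_e, n_e, m_e, sd_c, n_c, m_c)
    flagged_zero_var = v == 0.0
    value, flipped = align_sign(value, row.get("trait_subtype", ""))
    yc, ye = row.get("year_core_established"), row.get("year_edge_established")
    if pd.isna(yc) or pd.isna(ye):
        raise ConversionError("missing_year", "establishment years are required")
    rate = dispersal_rate(float(row.get("distance_km", np.nan)), float(yc), float(ye))
    inv_ntilde = (n_c + n_e) / (n_c * n_e)
    rec = {c: row.get(c) for c in CORE_EDGE_COLUMNS if c in row.index}
    rec.update({
        "lnrr": value, "v_lnrr": v, "abs_lnrr": abs(value),
        "sign_flipped": flipped, "zero_variance": flagged_zero_var,
        "dispersal_rate_km_y": rate,
        "time_diverged_y": float(ye) - float(yc),
        "sqrt_inv_eff_n": math.sqrt(inv_ntilde),
        "dispersal_mode": mode,
    })
    return rec


def load_core_edge_csv(path) -> RangeEffectTable:
    return compute_range_effects(pd.read_csv(path))


@dataclass
class RegressionResult:
    """Per-mode intercepts and slopes, with 95% Wald intervals."""

    response: str
    predictor: str
    slopes: pd.DataFrame       # index = dispersal mode; estimate/lower/upper
    intercepts: pd.DataFrame
    n: int
    interaction: bool
    model: object = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "response": self.response, "predictor": self.predictor,
            "n": self.n, "interaction": self.interaction,
            "slopes": self.slopes.to_dict(orient="index"),
            "intercepts": self.intercepts.to_dict(orient="index"),
        }


def _mode_regression(data: pd.DataFrame, response: str, predictor: str,
                     min_per_mode: int = 3) -> RegressionResult:
    data = data.dropna(subset=[response, predictor, "dispersal_mode"]).copy()
    if np.ptp(data[predictor].to_numpy(dtype=float)) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    counts = data["dispersal_mode"].value_counts()
    data = data[data["dispersal_mode"].isin(counts[counts >= min_per_mode].index)]
    modes = sorted(data["dispersal_mode"].unique())
    if not modes:
        raise ValueError("no dispersal mode retains enough records")
    interaction = len(modes) > 1
    if interaction:
        formula = (f"{response} ~ 0 + C(dispersal_mode) "
                   f"+ C(dispersal_mode):{predictor}")
    else:
        formula = f"{response} ~ {predictor}"
    res = smf.ols(formula, data=data).fit()
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    table = pd.concat([res.params.rename("estimate"), ci], axis=1)

    def _pick(mode, kind):
        if not interaction:
            name = "Intercept" if kind == "icept" else predictor
        elif kind == "icept":
            name = f"C(dispersal_mode)[{mode}]"
        else:
            name = f"C(dispersal_mode)[{mode}]:{predictor}"
        return table.loc[name]

    slopes = pd.DataFrame({m: _pick(m, "slope") for m in modes}).T
    icepts = pd.DataFrame({m: _pick(m, "icept") for m in modes}).T
    return RegressionResult(response=response, predictor=predictor,
                            slopes=slopes, intercepts=icepts,
                            n=len(data), interaction=interaction, model=res)


def climate_rate_regression(records: pd.DataFrame,
                            predictor: str = "delta_temp_C") -> RegressionResult:
    """Dispersal rate regressed on a core-to-edge climate difference,
    with dispersal mode as an interactive term (full interaction)."""
    if predictor not in ("delta_temp_C", "delta_precip_mm"):
        raise ValueError("predictor must be delta_temp_C or delta_precip_mm")
    return _mode_regression(records, "dispersal_rate_km_y", predictor)


def divergence_time_regression(records: pd.DataFrame) -> RegressionResult:
    """|lnRR| regressed on time since core-edge divergence, with dispersal
    mode as an interactive term; a positive slope means core and edge
    populations differentiate more the longer they have been separated."""
    return _mode_regression(records, "abs_lnrr", "time_diverged_y")
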