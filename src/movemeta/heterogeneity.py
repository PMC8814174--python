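"""Extended I-squared heterogeneity partition and publication-bias diagnostics.

Total heterogeneity is expressed relative to a "typical" sampling variance
computed from the inverse-variance weights,

    v_typical = (k - 1) * sum(w) / (sum(w)^2 - sum(w^2)),   w = 1 / v,

and each random level contributes

    I2_x = sigma2_x / (sigma2_species + sigma2_phylo + sigma2_study
                       + sigma2_obs + v_typical),

with I2_total the sum of the four component ratios.  Publication and
time-lag bias are assessed by refitting the multilevel model with an
SE-type covariate (Egger analogue) and publication year; an interval
excluding zero flags bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meta_model import ModelSpec, FitResult, fit as _fit, RANDOM_TERMS

__all__ = [
    "HeterogeneityPartition", "BiasDiagnostics",
    "typical_sampling_variance", "i2_partition", "i2_from_fit",
    "effective_sample_size_inv", "bias_regression", "funnel_data",
]


@dataclass
class HeterogeneityPartition:
    i2_total: float
    i2_species: float
    i2_phylo: float
    i2_study: float
    i2_effect: float
    typical_sampling_variance: float

    def as_dict(self) -> dict[str, float]:
        return {
            "i2_total": self.i2_total, "i2_species": self.i2_species,
            "i2_phylo": self.i2_phylo, "i2_study": self.i2_study,
            "i2_effect": self.i2_effect,
            "typical_sampling_variance": self.typical_sampling_variance,
        }


def typical_sampling_variance(v) -> float:
    """Typical within-study variance from inverse-variance weights.

    Lies between min(v) and max(v); equals the common value when all v agree.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 sampling variances")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    w = 1.0 / v
    sw = w.sum()
    return float((len(v) - 1) * sw / (sw ** 2 - (w ** 2).sum()))


_I2_KEYS = {"species": "i2_species", "phylogeny": "i2_phylo",
            "study": "i2_study", "observation": "i2_effect"}


def i2_partition(variance_components: dict[str, float], v_typical: float
                 ) -> HeterogeneityPartition:
    """Partition total heterogeneity across the four random levels.

    Missing components (e.g. no phylogeny term) count as zero.
    """
    if v_typical <= 0:
        raise ValueError("typical sampling variance must be positive")
    s2 = {t: float(variance_components.get(t, 0.0)) for t in RANDOM_TERMS}
    if any(x < 0 for x in s2.values()):
        raise ValueError("variance components must be nonnegative")
    denom = sum(s2.values()) + v_typical
    parts = {_I2_KEYS[t]: s2[t] / denom for t in RANDOM_TERMS}
    return HeterogeneityPartition(i2_total=sum(parts.values()),
                                  typical_sampling_variance=v_typical, **parts)


def i2_from_fit(result: FitResult, v) -> HeterogeneityPartition | pd.DataFrame:
    """I-squared partition for a fitted model.

    REML fits are plugged in at the point estimate.  MCMC fits are computed
    per posterior draw and summarised (median and equal-tailed 95% interval)
    in a DataFrame, one row per component.
    """
    vt = typical_sampling_variance(v)
    if result.method == "mcmc" and result.vc_draws is not None:
        rows = [i2_partition(dict(zip(result.vc_draws.columns, draw)), vt).as_dict()
                for draw in result.vc_draws.to_numpy()]
        per_draw = pd.DataFrame(rows).drop(columns="typical_sampling_variance")
        return pd.DataFrame({
            "median": per_draw.median(),
            "lower": per_draw.quantile(0.025),
            "upper": per_draw.quantile(0.975),
        })
    return i2_partition(result.variance_components, vt)


def effective_sample_size_inv(n_core, n_front) -> float:
    """Inverse effective sample size of a two-group contrast,
    (N_C + N_F) / (N_C * N_F); symmetric in its arguments."""
    n_core, n_front = float(n_core), float(n_front)
    if n_core < 1 or n_front < 1:
        raise ValueError("group sizes must be >= 1")
    return (n_core + n_front) / (n_core * n_front)


@dataclass
class BiasDiagnostics:
    funnel_points: pd.DataFrame          # effect, se, precision per record
    egger_slope: dict                    # estimate/lower/upper of SE covariate
    timelag_slope: dict                  # estimate/lower/upper of year covariate
    bias_flagged: bool = False
    fit: FitResult | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {"egger_slope": self.egger_slope,
                "timelag_slope": self.timelag_slope,
                "bias_flagged": self.bias_flagged}


def funnel_data(effects: pd.Series, variances: pd.Series) -> pd.DataFrame:
    se = np.sqrt(np.asarray(variances, dtype=float))
    return pd.DataFrame({"effect": np.asarray(effects, dtype=float),
                         "se": se, "precision": 1.0 / se})


def bias_regression(dataset: pd.DataFrame, spec: ModelSpec,
                    bias_covariate: str = "se_z",
                    pub_year: str = "pub_year") -> BiasDiagnostics:
    """Publication- and time-lag-bias test via covariate-adjusted refit.

    Adds the SE-type covariate (``se_z`` for Fisher-z data, or the square
    root of the inverse effective sample size for two-group lnRR data) and
    publication year to the model; their slopes with 95% intervals are the
    Egger-type and time-lag diagnostics.
    """
    for col in (bias_covariate, pub_year):
        if col not in dataset.columns:
            raise KeyError(f"bias covariate column {col!r} missing")
        if np.ptp(dataset[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"bias covariate {col!r} is constant")
    covs = tuple(dict.fromkeys(spec.covariates + (bias_covariate, pub_year)))
    bias_spec = ModelSpec(
        response=spec.response, variance=spec.variance,
        moderators=spec.moderators, covariates=covs,
        random_terms=spec.random_terms, phylo=spec.phylo,
        estimation=spec.estimation, mcmc=spec.mcmc,
        coef_prior_sd=spec.coef_prior_sd,
        sigma_prior_scale=spec.sigma_prior_scale)
    result = _fit(dataset, bias_spec)

    def _slope(term):
        row = result.coefficients.loc[term]
        return {"estimate": float(row["estimate"]),
                "lower": float(row["lower"]), "upper": float(row["upper"]),
                "excludes_zero": bool(row["lower"] > 0 or row["upper"] < 0)}

    egger = _slope(bias_covariate)
    timelag = _slope(pub_year)
    return BiasDiagnostics(
        funnel_points=funnel_data(dataset[spec.response], dataset[spec.variance]),
        egger_slope=egger, timelag_slope=timelag,
        bias_flagged=egger["excludes_zero"] or timelag["excludes_zero"],
        fit=result)
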