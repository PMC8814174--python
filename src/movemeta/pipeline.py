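"""End-to-end orchestration: load -> effect sizes -> tree -> fits -> report.

A run is driven by a small config mapping (usually loaded from YAML):

    data: individual_movement.csv      # or range_expansion.csv
    tree: individual_movement.nwk
    outdir: results/
    seed: 42                           # polytomy resolution + MCMC
    estimation: reml                   # or mcmc
    strict: false                      # fail on non-convergence
    rho: 1.0                           # Grafen power
    moderators: [movement_class, trait_category, taxon_group]
    mcmc: {chains: 4, iterations: 10000, warmup: 5000}

Every run writes a manifest (config hash, input digests, seeds, per-stage
record counts) so results are reproducible; rerunning with the same seeds
gives identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effect_sizes import load_individual_csv, min_k_filter
from .heterogeneity import bias_regression, i2_from_fit
from .meta_model import MCMCControls, ModelSpec, fit as fit_model
from .phylogeny import prepare_tree, read_tree
from .range_regression import (climate_rate_regression,
                               divergence_time_regression, load_core_edge_csv)

__all__ = ["RunManifest", "ConvergenceFailure", "run_individual_analysis",
           "run_range_analysis", "load_config"]


class ConvergenceFailure(RuntimeError):
    """A model failed the R-hat criterion while running in strict mode."""


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "data" not in cfg:
        raise ValueError("config must be a mapping with at least a 'data' entry")
    return cfg


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    input_digests: dict[str, str]
    seeds: dict[str, int]
    version: str = __version__
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def record_stage(self, stage: str, read: int, retained: int, rejected: int):
        if read != retained + rejected:
            raise ValueError(f"stage {stage}: {read} read != "
                             f"{retained} retained + {rejected} rejected")
        self.counts[stage] = {"read": read, "retained": retained,
                              "rejected": rejected}

    def as_dict(self) -> dict:
        return {"config_hash": self.config_hash, "version": self.version,
                "input_digests": self.input_digests, "seeds": self.seeds,
                "counts": self.counts}


def _manifest(cfg: dict) -> RunManifest:
    seed = int(cfg.get("seed", 0))
    digests = {"data": _digest(cfg["data"])}
    if cfg.get("tree"):
        digests["tree"] = _digest(cfg["tree"])
    return RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16],
        input_digests=digests,
        seeds={"polytomy": seed, "mcmc": seed, "generator": seed})


def _mcmc_controls(cfg: dict) -> MCMCControls:
    m = cfg.get("mcmc") or {}
    return MCMCControls(chains=int(m.get("chains", 4)),
                        iterations=int(m.get("iterations", 10_000)),
                        warmup=int(m.get("warmup", 5_000)),
                        seed=int(cfg.get("seed", 0)))


def _check_convergence(result, strict: bool, label: str):
    if result.method == "mcmc" and not result.converged and strict:
        worst = max(result.rhat.values())
        raise ConvergenceFailure(f"model {label!r}: max R-hat {worst:.4f} > 1.01")


def _fit_table(result) -> list[dict]:
    return (result.coefficients.reset_index().rename(columns={"index": "term"})
            .to_dict(orient="records"))


def run_individual_analysis(cfg: dict) -> dict:
    """Full individual-movement analysis; returns the report bundle.

    Fits the overall phylogenetic model (with publication-year and SE bias
    covariates), one no-intercept model per configured moderator (the taxon
    model drops the phylogeny random term, since taxa group related species
    categorically), the I-squared partition and the bias diagnostics.
    """
    seed = int(cfg.get("seed", 0))
    strict = bool(cfg.get("strict", False))
    estimation = cfg.get("estimation", "reml")
    table = load_individual_csv(cfg["data"])
    manifest = _manifest(cfg)
    manifest.record_stage("effect_sizes", len(table.effects) + len(table.rejections),
                          len(table.effects), len(table.rejections))

    tree = read_tree(cfg["tree"])
    _, phylo = prepare_tree(tree, seed=seed, rho=float(cfg.get("rho", 1.0)))
    data = table.effects
    controls = _mcmc_controls(cfg)

    def spec_for(moderators=(), covariates=("pub_year", "se_z"),
                 with_phylo=True):
        terms = ("species", "phylogeny", "study", "observation") if with_phylo \
            else ("species", "study", "observation")
        return ModelSpec(response="z", variance="v_z",
                         moderators=moderators, covariates=covariates,
                         random_terms=terms,
                         phylo=phylo if with_phylo else None,
                         estimation=estimation, mcmc=controls)

    report: dict = {"manifest": manifest.as_dict(), "models": {},
                    "dropped_groups": {}, "rejections":
                    table.rejections.to_dict(orient="records")}

    overall = fit_model(data, spec_for())
    _check_convergence(overall, strict, "overall")
    report["models"]["overall"] = overall.to_dict()

    i2 = i2_from_fit(overall, data["v_z"])
    report["heterogeneity"] = (i2.as_dict() if hasattr(i2, "as_dict")
                               else i2.to_dict())

    bias = bias_regression(data, spec_for(covariates=()),
                           bias_covariate="se_z")
    report["bias"] = bias.as_dict()

    for moderator in cfg.get("moderators",
                             ["movement_class", "trait_category", "taxon_group"]):
        kept, dropped = min_k_filter(data, moderator, k_min=int(cfg.get("k_min", 5)))
        report["dropped_groups"][moderator] = dropped.to_dict()
        if kept.empty or kept[moderator].nunique() == 0:
            continue
        with_phylo = moderator != "taxon_group"
        res = fit_model(kept, spec_for(moderators=(moderator,),
                                       with_phylo=with_phylo))
        _check_convergence(res, strict, moderator)
        report["models"][moderator] = res.to_dict()

    _write_report(cfg, report, "individual")
    return report


def run_range_analysis(cfg: dict) -> dict:
    """Full range-expansion analysis; returns the report bundle.

    Fits the overall lnRR model with sqrt(1/n-tilde) and year covariates,
    moderator models, the I-squared partition, bias diagnostics, and the
    climate-rate and divergence-time regressions.
    """
    seed = int(cfg.get("seed", 0))
    strict = bool(cfg.get("strict", False))
    estimation = cfg.get("estimation", "reml")
    table = load_core_edge_csv(cfg["data"])
    manifest = _manifest(cfg)
    manifest.record_stage("range_effects", len(table.effects) + len(table.rejections),
                          len(table.effects), len(table.rejections))
    data = table.effects
    tree = read_tree(cfg["tree"])
    _, phylo = prepare_tree(tree, seed=seed, rho=float(cfg.get("rho", 1.0)))
    controls = _mcmc_controls(cfg)

    def spec_for(moderators=(), covariates=("pub_year", "sqrt_inv_eff_n"),
                 with_phylo=True):
        terms = ("species", "phylogeny", "study", "observation") if with_phylo \
            else ("species", "study", "observation")
        return ModelSpec(response="lnrr", variance="v_lnrr",
                         moderators=moderators, covariates=covariates,
                         random_terms=terms,
                         phylo=phylo if with_phylo else None,
                         estimation=estimation, mcmc=controls)

    report: dict = {"manifest": manifest.as_dict(), "models": {},
                    "regressions": {}, "dropped_groups": {},
                    "rejections": table.rejections.to_dict(orient="records")}

    overall = fit_model(data, spec_for())
    _check_convergence(overall, strict, "overall_lnrr")
    report["models"]["overall"] = overall.to_dict()

    i2 = i2_from_fit(overall, data["v_lnrr"])
    report["heterogeneity"] = (i2.as_dict() if hasattr(i2, "as_dict")
                               else i2.to_dict())
    bias = bias_regression(data, spec_for(covariates=()),
                           bias_covariate="sqrt_inv_eff_n")
    report["bias"] = bias.as_dict()

    for moderator in cfg.get("moderators", ["trait_category", "taxon_group"]):
        kept, dropped = min_k_filter(data, moderator, k_min=int(cfg.get("k_min", 5)))
        report["dropped_groups"][moderator] = dropped.to_dict()
        if kept.empty:
            continue
        res = fit_model(kept, spec_for(moderators=(moderator,),
                                       with_phylo=moderator != "taxon_group"))
        _check_convergence(res, strict, moderator)
        report["models"][moderator] = res.to_dict()

    for predictor in ("delta_temp_C", "delta_precip_mm"):
        if data[predictor].notna().sum() == 0:
            report["regressions"][predictor] = {"skipped": "no climate data"}
            continue
        reg = climate_rate_regression(data, predictor)
        report["regressions"][predictor] = reg.as_dict()
    report["regressions"]["time_diverged"] = divergence_time_regression(data).as_dict()

    _write_report(cfg, report, "range")
    return report


def _write_report(cfg: dict, report: dict, label: str):
    outdir = cfg.get("outdir")
    if not outdir:
        return
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"{label}_report.json").write_text(
        json.dumps(report, indent=2, default=float, sort_keys=True))
    rows = []
    for model, res in report["models"].items():
        for coef in res["coefficients"]:
            rows.append({"model": model, **coef})
    pd.DataFrame(rows).to_csv(outdir / f"{label}_estimates.csv", index=False)
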