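"""Synthetic datasets with known ground truth.

Everything downstream (effect-size conversion, the multilevel model, the
heterogeneity partition, bias diagnostics, the range regressions) is tested
against data generated here, where the pooled effect, every variance
component, the phylogeny and the regression slopes are known exactly.

The individual-movement generator is the exact inverse of the analysis
model: species effects are drawn from N(0, sigma2_species I + sigma2_phylo A)
on the Fisher-z scale, study and observation effects as independent normals,
sampling noise with variance v_i = 1/(n_i - 3) from simulated sample sizes,
and the observed correlation is r_i = tanh(z_i).  A configurable fraction of
records is emitted as t statistics (exercising the conversion path) and a
fraction as reverse-coded traits (exercising sign alignment).  An optional
selection mechanism retains each record with probability
logistic(a + b * z / SE), emulating publication bias against weak or
negative results.

The range-expansion generator draws per-mode dispersal rates as linear
functions of the core-to-edge temperature difference, and |lnRR| as a linear
function of divergence time, then constructs group means/SDs/Ns that realise
those effects exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit

from .phylogeny import grafen_branch_lengths, correlation_matrix

__all__ = [
    "BiasMechanism", "RegressionTruth", "SyntheticTruth",
    "simulate_tree", "simulate_individual_dataset", "simulate_range_dataset",
    "write_individual_bundle", "write_range_bundle",
]

MOVEMENT_CLASSES = ("activity", "exploration", "dispersal")
PLAIN_SUBTYPES = (
    ("locomotor performance", "sprint"),
    ("locomotor performance", "endurance"),
    ("metabolism", "resting metabolic rate"),
    ("metabolism", "maximum metabolic rate"),
    ("hormone", "corticosterone"),
    ("body condition", "body condition index"),
)
REVERSED_SUBTYPES = (
    ("thermal tolerance", "ctmin"),
    ("locomotor performance", "cost of transport"),
)


@dataclass
class BiasMechanism:
    """One-sided censoring: P(retain) = logistic(intercept + slope * z / SE)."""

    intercept: float = -2.0
    slope: float = 3.0
    timelag_slope: float = 0.0    # drift of true effects per publication year


@dataclass
class RegressionTruth:
    """Generating slopes for the range-expansion regressions."""

    rate_slopes: dict = field(default_factory=lambda: {
        "aerial": 1.0, "aquatic": 0.5, "terrestrial": 0.1})
    rate_intercepts: dict = field(default_factory=lambda: {
        "aerial": 5.0, "aquatic": 2.0, "terrestrial": 1.0})
    rate_noise_sd: float = 0.3
    lnrr_time_slope: float = 0.01
    lnrr_base: float = 0.3
    lnrr_noise_sd: float = 0.15


@dataclass
class SyntheticTruth:
    """Generating parameters; the oracle for every recovery test."""

    mu: float = 0.2
    moderator_means: dict | None = None        # movement_class level -> mean
    sigma2: dict = field(default_factory=lambda: {
        "species": 0.05, "phylogeny": 0.05, "study": 0.05, "observation": 0.05})
    n_species: int = 40
    n_studies: int = 30
    k: int = 200
    n_range: tuple = (10, 100)                 # v_i = 1/(n_i - 3), n_i uniform here
    t_stat_fraction: float = 0.2
    reverse_coded_fraction: float = 0.1
    bias: BiasMechanism | None = None
    regression_truth: RegressionTruth = field(default_factory=RegressionTruth)
    seed: int = 0

    def as_dict(self) -> dict:
        out = asdict(self)
        return out


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth species tree with Grafen branch lengths (tip depth 1).

    Deterministic for a given (n_species, seed); tips are labelled sp001..spN.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = random.Random(int(seed))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng)
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda nd: nd.taxon.label), start=1):
        leaf.taxon.label = f"sp{i:03d}"
    tree.is_rooted = True
    return grafen_branch_lengths(tree)


def _species_effects(A: np.ndarray, sigma2: dict, rng: np.random.Generator
                     ) -> np.ndarray:
    n = A.shape[0]
    cov = sigma2["phylogeny"] * A + sigma2["species"] * np.eye(n)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return L @ rng.standard_normal(n)


def simulate_individual_dataset(truth: SyntheticTruth):
    """Generate a raw individual-movement table plus its tree.

    Returns (raw DataFrame in the loader's CSV dialect, tree, hidden table
    with the pre-noise latent values for back-transform checks).
    """
    rng = np.random.default_rng(truth.seed)
    tree = simulate_tree(truth.n_species, truth.seed)
    phylo = correlation_matrix(tree)
    species = phylo.labels
    sp_eff = _species_effects(phylo.matrix, truth.sigma2, rng)
    study_eff = rng.normal(0.0, np.sqrt(truth.sigma2["study"]), truth.n_studies)
    levels = list(truth.moderator_means) if truth.moderator_means else list(MOVEMENT_CLASSES)

    rows, latents = [], []
    attempts, max_attempts = 0, 200 * truth.k + 1000
    while len(rows) < truth.k:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("censoring mechanism rejected nearly all records; "
                               "infeasible bias configuration")
        i = len(rows)
        sp = int(rng.integers(truth.n_species))
        st = int(rng.integers(truth.n_studies))
        mc = levels[i % len(levels)]
        mu = (truth.moderator_means[mc] if truth.moderator_means else truth.mu)
        n_i = int(rng.integers(truth.n_range[0], truth.n_range[1] + 1))
        v_i = 1.0 / (n_i - 3)
        pub_year = int(rng.integers(2000, 2021))
        if truth.bias is not None:
            mu = mu + truth.bias.timelag_slope * (pub_year - 2010)
        z = (mu + sp_eff[sp] + study_eff[st]
             + rng.normal(0.0, np.sqrt(truth.sigma2["observation"]))
             + rng.normal(0.0, np.sqrt(v_i)))
        if truth.bias is not None and truth.bias.slope != 0.0:
            if rng.uniform() > expit(truth.bias.intercept
                                     + truth.bias.slope * z / np.sqrt(v_i)):
                continue
        r = np.tanh(z)
        reversed_trait = rng.uniform() < truth.reverse_coded_fraction
        if reversed_trait:
            cat, sub = REVERSED_SUBTYPES[int(rng.integers(len(REVERSED_SUBTYPES)))]
            r_emit = -r     # alignment will restore the true sign
        else:
            cat, sub = PLAIN_SUBTYPES[int(rng.integers(len(PLAIN_SUBTYPES)))]
            r_emit = r
        as_t = rng.uniform() < truth.t_stat_fraction and abs(r_emit) < 0.999
        row = {
            "study_id": f"study{st + 1:03d}",
            "species": species[sp],
            "r": np.nan, "stat_type": np.nan, "stat_value": np.nan, "df": np.nan,
            "n": n_i, "direction": np.nan,
            "movement_class": mc,
            "trait_category": cat, "trait_subtype": sub,
            "taxon_group": f"taxon{sp % 6 + 1}",
            "thermal_strategy": "ectotherm" if sp % 2 else "endotherm",
            "sex": ("mixed", "male", "female")[i % 3],
            "age": "adult" if i % 4 else "juvenile",
            "origin": "wild" if i % 5 else "captive",
            "pub_year": pub_year,
        }
        if as_t:
            df = n_i - 2
            row["stat_type"] = "t"
            row["stat_value"] = r_emit * np.sqrt(df / (1.0 - r_emit ** 2))
            row["df"] = df
        else:
            row["r"] = r_emit
        rows.append(row)
        latents.append({"z_true": z, "v": v_i, "species_idx": sp, "study_idx": st})
    raw = pd.DataFrame(rows)
    return raw, tree, pd.DataFrame(latents)


def simulate_range_dataset(truth: SyntheticTruth, k: int | None = None):
    """Generate a raw core/edge table realising the configured regressions.

    Returns (raw DataFrame, tree).  Dispersal rate follows
    intercept_mode + slope_mode * delta_T + noise; |lnRR| follows
    base + time_slope * years_diverged + noise, with a random sign.
    """
    rt = truth.regression_truth
    k = truth.k if k is None else k
    rng = np.random.default_rng(truth.seed + 1)
    n_species = max(2, min(truth.n_species, 16))
    tree = simulate_tree(n_species, truth.seed + 1)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    modes = sorted(rt.rate_slopes)
    rows = []
    for i in range(k):
        mode = modes[i % len(modes)]
        d_temp = rng.normal(0.0, 1.5)
        d_precip = rng.normal(0.0, 150.0)
        years = int(rng.integers(10, 101))
        rate = (rt.rate_intercepts[mode] + rt.rate_slopes[mode] * d_temp
                + rng.normal(0.0, rt.rate_noise_sd))
        rate = max(rate, 1e-3)
        magnitude = max(rt.lnrr_base + rt.lnrr_time_slope * years
                        + rng.normal(0.0, rt.lnrr_noise_sd), 1e-3)
        value = magnitude * (1 if rng.uniform() < 0.5 else -1)
        mean_core = rng.uniform(0.5, 2.0)
        mean_edge = mean_core * np.exp(value)
        n_core = int(rng.integers(5, 31))
        n_edge = int(rng.integers(5, 31))
        cv_c, cv_e = rng.uniform(0.1, 0.3, 2)
        year_core = int(rng.integers(1950, 1991))
        cat, sub = PLAIN_SUBTYPES[int(rng.integers(len(PLAIN_SUBTYPES)))]
        row = {
            "study_id": f"rstudy{i // 6 + 1:03d}",
            "species": species[int(rng.integers(len(species)))],
            "trait_category": cat, "trait_subtype": sub,
            "mean_core": mean_core, "mean_edge": mean_edge,
            "sd_core": np.nan, "sd_edge": np.nan,
            "se_core": np.nan, "se_edge": np.nan,
            "n_core": n_core, "n_edge": n_edge,
            "year_core_established": year_core,
            "year_edge_established": year_core + years,
            "distance_km": rate * years,
            "delta_temp_C": d_temp, "delta_precip_mm": d_precip,
            "dispersal_mode": mode,
            "range_type": "introduced" if i % 5 else "native",
            "taxon_group": f"taxon{i % 4 + 1}",
            "pub_year": int(rng.integers(2002, 2021)),
        }
        # a fifth of the rows report SE instead of SD, exercising conversion
        if i % 5 == 4:
            row["se_core"] = cv_c * mean_core / np.sqrt(n_core)
            row["se_edge"] = cv_e * mean_edge / np.sqrt(n_edge)
        else:
            row["sd_core"] = cv_c * mean_core
            row["sd_edge"] = cv_e * mean_edge
        rows.append(row)
    return pd.DataFrame(rows), tree


def write_individual_bundle(truth: SyntheticTruth, outdir) -> dict:
    """Write raw CSV + Newick tree + truth JSON; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw, tree, _ = simulate_individual_dataset(truth)
    paths = {
        "data": str(outdir / "individual_movement.csv"),
        "tree": str(outdir / "individual_movement.nwk"),
        "truth": str(outdir / "truth_individual.json"),
    }
    raw.to_csv(paths["data"], index=False)
    tree.write(path=paths["tree"], schema="newick")
    Path(paths["truth"]).write_text(json.dumps(truth.as_dict(), indent=2, default=float))
    return paths


def write_range_bundle(truth: SyntheticTruth, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw, tree = simulate_range_dataset(truth)
    paths = {
        "data": str(outdir / "range_expansion.csv"),
        "tree": str(outdir / "range_expansion.nwk"),
        "truth": str(outdir / "truth_range.json"),
    }
    raw.to_csv(paths["data"], index=False)
    tree.write(path=paths["tree"], schema="newick")
    Path(paths["truth"]).write_text(json.dumps(truth.as_dict(), indent=2, default=float))
    return paths
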