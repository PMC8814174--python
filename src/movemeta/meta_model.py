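"""Multilevel meta-analytic model with four random effects.

The observed effect sizes y_i (Fisher z or lnRR) follow

    y = X beta + u_species + u_phylo + u_study + u_obs + e,
    e_i ~ N(0, v_i)  with v_i the known sampling variance,

where the random effects are zero-mean Gaussians: species identity
(iid across species), phylogeny (covariance sigma2_phylo * A with A the
shared-ancestry correlation matrix), study identity (iid across studies) and
an observation-level effect (iid per effect size, the residual analogue).
Marginally,

    y ~ N(X beta, V),  V = sigma2_sp Zs Zs' + sigma2_ph Zs A Zs'
                           + sigma2_st Zu Zu' + sigma2_obs I + diag(v).

Fixed effects use a no-intercept coding: one indicator column per moderator
level, so each coefficient is that level's mean effect; continuous covariates
(publication year, SE-type bias terms) are mean-centered so level means are
interpreted at average covariate values.

Two estimation paths share this marginal model:

* ``fit_reml`` maximises the restricted likelihood over the nonnegative
  variance components (deterministic; Wald 95% intervals).
* ``fit_mcmc`` samples the posterior under half-Cauchy(0, 1) priors on each
  sigma and Normal(0, 10^2) priors on coefficients.  The coefficients are
  conjugate given the variance components, so the sampler is a collapsed
  adaptive random-walk Metropolis on log sigma with exact Gaussian draws of
  beta at each retained iteration; convergence is monitored with split-chain
  R-hat (flagged unless max |R-hat - 1| <= 0.01).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylogeny import PhyloCorrelation

__all__ = [
    "MCMCControls", "ModelSpec", "Design", "FitResult",
    "build_design", "fit_reml", "fit_mcmc", "fit", "compare_fits",
    "RANDOM_TERMS", "RHAT_THRESHOLD",
]

RANDOM_TERMS = ("species", "phylogeny", "study", "observation")
RHAT_THRESHOLD = 1.01


@dataclass
class MCMCControls:
    """Sampler settings; defaults mirror the headline analysis configuration."""

    chains: int = 4
    iterations: int = 10_000
    warmup: int = 5_000
    seed: int = 0
    target_accept: float = 0.35  # RW-Metropolis optimum for few dimensions


@dataclass
class ModelSpec:
    response: str = "z"
    variance: str = "v_z"
    moderators: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = RANDOM_TERMS
    phylo: PhyloCorrelation | None = None
    estimation: str = "reml"
    mcmc: MCMCControls = field(default_factory=MCMCControls)
    coef_prior_sd: float = 10.0
    sigma_prior_scale: float = 1.0  # half-Cauchy scale on each random-effect SD

    def __post_init__(self):
        self.moderators = tuple(self.moderators)
        self.covariates = tuple(self.covariates)
        terms = tuple(t for t in self.random_terms if t != "observation")
        # the observation-level term is the residual analogue; always present
        self.random_terms = terms + ("observation",)
        unknown = set(self.random_terms) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")
        if "phylogeny" in self.random_terms and self.phylo is None:
            raise ValueError("random term 'phylogeny' requires a phylo matrix")


@dataclass
class Design:
    """Numeric design extracted from a dataset under a ModelSpec."""

    y: np.ndarray
    v: np.ndarray                      # known sampling variances (diagonal)
    X: np.ndarray
    coef_names: list[str]
    blocks: dict[str, np.ndarray]      # random-term name -> k x k covariance block
    spec: ModelSpec

    @property
    def k(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def vc_names(self) -> list[str]:
        return [t for t in RANDOM_TERMS if t in self.blocks]

    def V(self, sigma2: np.ndarray) -> np.ndarray:
        """Marginal covariance for a vector of variance components."""
        V = np.diag(self.v.copy())
        for s2, name in zip(sigma2, self.vc_names):
            V += s2 * self.blocks[name]
        return V


def _indicator(codes: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(codes.astype(str).unique())
    Z = (codes.astype(str).to_numpy()[:, None] == np.array(levels)).astype(float)
    return Z, levels


def build_design(dataset: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build fixed-effect matrix and random-effect covariance blocks.

    Moderators become indicator columns (no global intercept); with no
    moderators a plain intercept column is used.  Covariates are mean-centered.
    A singular fixed-effects matrix raises, naming the dependent columns.
    """
    y = dataset[spec.response].to_numpy(dtype=float)
    v = dataset[spec.variance].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    cols, names = [], []
    if spec.moderators:
        for mod in spec.moderators:
            Z, levels = _indicator(dataset[mod])
            cols.append(Z)
            names.extend(f"{mod}[{lv}]" for lv in levels)
    else:
        cols.append(np.ones((len(y), 1)))
        names.append("intercept")
    for cov in spec.covariates:
        x = dataset[cov].to_numpy(dtype=float)
        cols.append((x - x.mean())[:, None])
        names.append(cov)
    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"fixed-effects matrix is singular; dependent columns: {bad}")

    blocks: dict[str, np.ndarray] = {}
    if "species" in spec.random_terms or "phylogeny" in spec.random_terms:
        Zs, sp_levels = _indicator(dataset["species"])
        if "species" in spec.random_terms:
            blocks["species"] = Zs @ Zs.T
        if "phylogeny" in spec.random_terms:
            A = spec.phylo.submatrix(sp_levels).matrix
            blocks["phylogeny"] = Zs @ A @ Zs.T
    if "study" in spec.random_terms:
        Zu, _ = _indicator(dataset["study_id"])
        blocks["study"] = Zu @ Zu.T
    blocks["observation"] = np.eye(len(y))
    return Design(y=y, v=v, X=X, coef_names=names, blocks=blocks, spec=spec)


# ---------------------------------------------------------------------------
# REML


def _gls(design: Design, sigma2: np.ndarray):
    """Cholesky-based GLS pieces at a given variance-component vector."""
    V = design.V(sigma2)
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = linalg.cho_solve(cf, design.X, check_finite=False)
    Vi_y = linalg.cho_solve(cf, design.y, check_finite=False)
    C = design.X.T @ Vi_X
    b = design.X.T @ Vi_y
    return cf, logdet_V, C, b, Vi_y


def restricted_loglik(design: Design, sigma2: np.ndarray) -> float:
    """Restricted (REML) log-likelihood of the Gaussian marginal model."""
    cf, logdet_V, C, b, Vi_y = _gls(design, sigma2)
    cC = linalg.cho_factor(C, lower=True, check_finite=False)
    logdet_C = 2.0 * np.sum(np.log(np.diag(cC[0])))
    beta = linalg.cho_solve(cC, b, check_finite=False)
    quad = design.y @ Vi_y - b @ beta
    k, p = design.k, design.p
    return -0.5 * (logdet_V + logdet_C + quad + (k - p) * math.log(2 * math.pi))


@dataclass
class FitResult:
    coefficients: pd.DataFrame   # estimate, se/sd, lower, upper per term
    variance_components: dict[str, float]
    n_effects: int
    method: str
    rhat: dict[str, float] | None = None
    converged: bool = True
    boundary: list[str] = field(default_factory=list)
    log_likelihood_restricted: float | None = None
    seed: int | None = None
    settings: dict = field(default_factory=dict)
    vc_draws: pd.DataFrame | None = None
    coef_draws: pd.DataFrame | None = None

    def coef(self, name: str) -> pd.Series:
        return self.coefficients.loc[name]

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "n_effects": self.n_effects,
            "coefficients": self.coefficients.reset_index()
                .rename(columns={"index": "term"}).to_dict(orient="records"),
            "variance_components": self.variance_components,
            "converged": self.converged,
            "boundary": self.boundary,
            "settings": self.settings,
        }
        if self.rhat is not None:
            out["rhat"] = self.rhat
        if self.log_likelihood_restricted is not None:
            out["log_likelihood_restricted"] = self.log_likelihood_restricted
        if self.seed is not None:
            out["seed"] = self.seed
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=float, **kw)


def fit_reml(dataset: pd.DataFrame, spec: ModelSpec,
             fix_sigma2: dict[str, float] | None = None) -> FitResult:
    """Restricted-maximum-likelihood fit of the multilevel model.

    ``fix_sigma2`` pins named variance components (e.g. all to 0 to recover
    the fixed-effect inverse-variance weighted estimate).  Boundary estimates
    (sigma2 = 0) are legal and reported in ``boundary``.
    """
    design = build_design(dataset, spec)
    if design.k <= design.p:
        raise ValueError(f"k={design.k} effect sizes cannot identify {design.p} coefficients")
    names = design.vc_names
    fixed = dict(fix_sigma2 or {})
    free = [n for n in names if n not in fixed]

    def full(theta):
        s2 = np.empty(len(names))
        it = iter(theta)
        for i, n in enumerate(names):
            s2[i] = fixed[n] if n in fixed else next(it)
        return s2

    if free:
        resid_var = max(np.var(design.y) - np.mean(design.v), 1e-4)
        starts = [np.full(len(free), resid_var / len(free)),
                  np.full(len(free), 1e-3),
                  np.full(len(free), resid_var)]
        obj = lambda th: -restricted_loglik(design, full(th))
        best = None
        for x0 in starts:
            res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                    bounds=[(0.0, None)] * len(free))
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        if not best.success and not np.isfinite(best.fun):
            raise RuntimeError(f"REML optimizer failed: {best.message}")
        sigma2 = full(best.x)
        llr = -best.fun
    else:
        sigma2 = full([])
        llr = restricted_loglik(design, sigma2)

    _, _, C, b, _ = _gls(design, sigma2)
    cC = linalg.cho_factor(C, lower=True, check_finite=False)
    beta = linalg.cho_solve(cC, b, check_finite=False)
    cov = linalg.cho_solve(cC, np.eye(design.p), check_finite=False)
    se = np.sqrt(np.diag(cov))
    zq = stats.norm.ppf(0.975)
    coef = pd.DataFrame({
        "estimate": beta, "se": se,
        "lower": beta - zq * se, "upper": beta + zq * se,
    }, index=design.coef_names)
    vc = {n: float(s2) for n, s2 in zip(names, sigma2)}
    boundary = [n for n in free if vc[n] < 1e-8]
    return FitResult(coefficients=coef, variance_components=vc,
                     n_effects=design.k, method="reml",
                     boundary=boundary, log_likelihood_restricted=float(llr),
                     settings={"fixed_sigma2": fixed})


# ---------------------------------------------------------------------------
# MCMC


def _log_marginal(design: Design, sigma2: np.ndarray, tau2: float):
    """log p(y | sigma2) with coefficients integrated out under N(0, tau2 I).

    Returns (logp, (M_chol, b)) where M = I/tau2 + X'V^-1 X is the posterior
    precision of beta and b = X'V^-1 y; beta | sigma2, y ~ N(M^-1 b, M^-1).
    """
    cf, logdet_V, C, b, Vi_y = _gls(design, sigma2)
    M = C + np.eye(design.p) / tau2
    cM = linalg.cho_factor(M, lower=True, check_finite=False)
    logdet_M = 2.0 * np.sum(np.log(np.diag(cM[0])))
    mean = linalg.cho_solve(cM, b, check_finite=False)
    quad = design.y @ Vi_y - b @ mean
    logp = -0.5 * (design.k * math.log(2 * math.pi) + logdet_V
                   + design.p * math.log(tau2) + logdet_M + quad)
    return logp, (cM, mean)


def adaptive_metropolis(logpost, x0: np.ndarray, iterations: int, warmup: int,
                        rng: np.random.Generator, target_accept: float = 0.35):
    """Adaptive random-walk Metropolis chain.

    ``logpost(x) -> (lp, aux)``; the proposal scale adapts toward the target
    acceptance rate during warmup only (diminishing adaptation), and the
    per-coordinate scales are refreshed from the warmup sample spread.
    Returns (draws, aux_list, acceptance_rate) for the post-warmup phase.
    """
    d = len(x0)
    x = np.asarray(x0, dtype=float).copy()
    lp, aux = logpost(x)
    log_step = math.log(2.38 / math.sqrt(d))
    L = np.eye(d)                       # proposal covariance Cholesky factor
    draws = np.empty((iterations - warmup, d))
    aux_out = []
    accepted_post = 0
    history = []
    for it in range(iterations):
        prop = x + math.exp(log_step) * (L @ rng.standard_normal(d))
        lp_prop, aux_prop = logpost(prop)
        accept = math.log(rng.uniform()) < lp_prop - lp
        if accept:
            x, lp, aux = prop, lp_prop, aux_prop
        if it < warmup:
            gamma = (it + 1) ** -0.6
            log_step += gamma * ((1.0 if accept else 0.0) - target_accept)
            history.append(x.copy())
            # Haario-style covariance adaptation from the warmup history
            if (it + 1) % 100 == 0 and len(history) >= 200:
                cov = np.cov(np.array(history[len(history) // 2:]).T)
                cov = np.atleast_2d(cov) + 1e-8 * np.eye(d)
                scale = np.exp(np.mean(np.log(np.diag(cov))))  # keep |L| ~ 1
                L = np.linalg.cholesky(cov / scale)
        else:
            j = it - warmup
            draws[j] = x
            aux_out.append(aux)
            accepted_post += accept
    return draws, aux_out, accepted_post / max(iterations - warmup, 1)


def _split_rhat(chains: np.ndarray) -> float:
    """Rank-normalized split-chain R-hat for draws shaped (chain, iter)."""
    if np.ptp(chains) == 0:
        return 1.0
    import arviz as az
    return float(az.rhat(az.convert_to_dataset(chains))["x"].values)


def fit_mcmc(dataset: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Bayesian fit: half-Cauchy(0, 1) priors on each random-effect SD,
    Normal(0, 10^2) priors on coefficients.

    Collapsed sampler: adaptive Metropolis on log sigma with the coefficient
    vector marginalised analytically, then drawn exactly from its Gaussian
    conditional at every retained iteration.  Reports posterior means and
    equal-tailed 95% credible intervals, with split-chain R-hat per parameter.
    """
    design = build_design(dataset, spec)
    if design.k <= design.p:
        raise ValueError(f"k={design.k} effect sizes cannot identify {design.p} coefficients")
    ctl = spec.mcmc
    tau2 = spec.coef_prior_sd ** 2
    hc_scale = spec.sigma_prior_scale
    names = design.vc_names
    m = len(names)

    def logpost(theta):
        # sampled on the natural sigma scale, reflected at 0 (|.| keeps the
        # proposal symmetric); avoids the long log-scale tail near sigma = 0
        sigma = np.abs(theta)
        if np.any(sigma > 1e4):
            return -np.inf, None
        lml, aux = _log_marginal(design, sigma ** 2, tau2)
        lprior = np.sum(-np.log1p((sigma / hc_scale) ** 2))
        return lml + lprior, aux

    # overdispersed inits around the REML solution
    reml = fit_reml(dataset, spec)
    base = np.array([max(reml.variance_components[n], 1e-3) for n in names])
    root = np.random.default_rng(ctl.seed)
    chain_draws, chain_betas = [], []
    for c in range(ctl.chains):
        rng = np.random.default_rng(root.integers(2 ** 31))
        x0 = np.sqrt(base) * np.exp(0.5 * rng.standard_normal(m))
        draws, aux, _ = adaptive_metropolis(
            logpost, x0, ctl.iterations, ctl.warmup, rng,
            target_accept=ctl.target_accept)
        draws = np.abs(draws)
        betas = np.empty((len(draws), design.p))
        for i, (cM, mean) in enumerate(aux):
            z = rng.standard_normal(design.p)
            # cM holds chol(M) with M the posterior precision of beta
            betas[i] = mean + linalg.solve_triangular(
                cM[0].T, z, lower=False, check_finite=False)
        chain_draws.append(draws)                  # sigma draws
        chain_betas.append(betas)

    sig = np.stack(chain_draws)                    # (chains, iters, m)
    bet = np.stack(chain_betas)                    # (chains, iters, p)
    rhat = {}
    for j, n in enumerate(names):
        rhat[f"sigma_{n}"] = _split_rhat(sig[:, :, j])
    for j, n in enumerate(design.coef_names):
        rhat[n] = _split_rhat(bet[:, :, j])
    converged = max(abs(r - 1.0) for r in rhat.values()) <= RHAT_THRESHOLD - 1.0

    sig_flat = sig.reshape(-1, m)
    bet_flat = bet.reshape(-1, design.p)
    coef = pd.DataFrame({
        "estimate": bet_flat.mean(axis=0),
        "sd": bet_flat.std(axis=0, ddof=1),
        "lower": np.percentile(bet_flat, 2.5, axis=0),
        "upper": np.percentile(bet_flat, 97.5, axis=0),
    }, index=design.coef_names)
    vc = {n: float(np.mean(sig_flat[:, j] ** 2)) for j, n in enumerate(names)}
    return FitResult(
        coefficients=coef, variance_components=vc, n_effects=design.k,
        method="mcmc", rhat=rhat, converged=converged, seed=ctl.seed,
        settings={"chains": ctl.chains, "iterations": ctl.iterations,
                  "warmup": ctl.warmup, "coef_prior_sd": spec.coef_prior_sd,
                  "sigma_prior_scale": hc_scale},
        vc_draws=pd.DataFrame(sig_flat ** 2, columns=names),
        coef_draws=pd.DataFrame(bet_flat, columns=design.coef_names))


def fit(dataset: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Dispatch to the estimation path named in the spec."""
    if spec.estimation == "reml":
        return fit_reml(dataset, spec)
    if spec.estimation == "mcmc":
        return fit_mcmc(dataset, spec)
    raise ValueError(f"unknown estimation method {spec.estimation!r}")


def compare_fits(reml: FitResult, mcmc: FitResult) -> pd.DataFrame:
    """Coefficient-wise agreement between the REML and MCMC paths.

    A row passes when |REML - posterior mean| < 0.5 posterior SD; small or
    weakly identified datasets may legitimately fail (report only).
    """
    terms = reml.coefficients.index
    sd_col = "sd" if "sd" in mcmc.coefficients.columns else "se"
    delta = reml.coefficients["estimate"] - mcmc.coefficients.loc[terms, "estimate"]
    tol = 0.5 * mcmc.coefficients.loc[terms, sd_col]
    return pd.DataFrame({
        "reml": reml.coefficients["estimate"],
        "mcmc": mcmc.coefficients.loc[terms, "estimate"],
        "delta": delta, "tolerance": tol,
        "pass": delta.abs() < tol,
    })
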