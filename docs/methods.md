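# Methods

## Effect sizes

Individual-level records carry either a correlation coefficient directly or
an inferential statistic. Conversions follow the standard point-biserial /
contingency identities: t → r = t/√(t²+df) (signed); F with numerator df = 1
→ r = √(F/(F+df)), and χ² with df = 1 → r = √(χ²/n), both signed by the
reported direction of the effect. F with numerator df > 1 or χ² with df > 1
do not determine a unique correlation and are rejected with a reason code,
as are unsigned statistics without a reported direction — a missing sign is
never guessed. Correlations are Fisher-z transformed with sampling variance
1/(n−3); records with n < 4 are rejected, and records with n ≤ 6 are kept
but flagged high-variance.

Sign alignment makes positive values mean "higher physiological capacity
with more movement". Traits where a smaller raw value indicates better
performance — critical thermal minimum, latency to enter a novel area, cost
of transport — are negated, and the flip is recorded. The reverse-coded set
is an argument, not a constant, because trait vocabularies differ between
datasets; unknown subtypes are left unflipped. Metabolic-rate subtypes
collapse into non-active (basal/resting/standard), active (routine/field)
and maximum (forced exercise or post-exhaustion) groups; unmapped labels go
to an explicit "unclassified" bucket excluded from the subtype model.
Moderator levels with fewer than five effect sizes are dropped from
moderator models (threshold configurable, boundary inclusive).

## Phylogeny

Trees are read from Newick. Multifurcations are resolved at random into
zero-length bifurcations; the resolution is a deterministic function of a
recorded seed, because an unseeded randomisation cannot be reproduced.
Branch lengths use Grafen's method: each node sits at height
(number of descendant tips − 1)^ρ, rescaled so the root is at height 1,
with ρ = 1 by default (the conventional default; exposed in config). The
correlation matrix entry for a species pair is the shared root-to-MRCA
fraction of the unit tip depth — for an ultrametric tree this equals
1 − d/2 with d the patristic distance. The matrix is used as a pure
correlation; the phylogenetic variance component multiplies it inside the
model. Species matching is case-insensitive with underscore/space
normalisation, and an unmatched species is a hard error (silent dropping
would bias the synthesis). A single seeded resolution is fitted by default;
sensitivity across resolutions is a matter of rerunning with other seeds.

## The multilevel model

The marginal covariance of the effect vector is

    V(σ²) = σ²_species Z_s Z_sᵀ + σ²_phylo Z_s A Z_sᵀ + σ²_study Z_u Z_uᵀ
            + σ²_obs I + diag(v_i),

with the observation-level term always present (it is the residual
analogue) and the known sampling variances v_i as a fixed diagonal. The
observation variance and the fixed diagonal are distinguishable only
because v_i varies across records; with near-constant v_i the two are
weakly identified, which is reported honestly via wide intervals rather
than suppressed. Moderators are coded as full indicator blocks with no
global intercept; continuous covariates are mean-centered so level means
are interpreted at average covariate values.

**REML path.** The restricted log-likelihood is maximised over the
nonnegative components with L-BFGS-B from three starts (equal split of the
method-of-moments residual variance, near-zero, and the full residual
variance). Boundary solutions σ² = 0 are legal, reported in `boundary`, and
never perturbed. Coefficients are GLS at the optimum with Wald ±1.96·SE
intervals.

**Bayesian path.** Priors are half-Cauchy(0, 1) on each random-effect SD
and Normal(0, 10²) on coefficients (wide relative to effect-size scales;
both scales configurable). Because the coefficients are conditionally
Gaussian given σ, they are integrated out analytically and the sampler is
an adaptive random-walk Metropolis on the σ vector alone (proposal scale
tuned to ~35% acceptance with Haario-style covariance adaptation during
warm-up only; σ sampled on the natural scale with reflection at zero, which
mixes better than the log scale when a component is near zero).
Coefficients are then drawn exactly from their Gaussian conditional at
every retained iteration. Any sampler satisfying the prior-recovery and R̂
contract would do; this one was chosen because a four-dimensional collapsed
posterior is an easy target for adaptive Metropolis and needs no external
sampling framework. Defaults are 4 chains × 10,000 iterations with 5,000
warm-up. Convergence is summarised by split-chain R̂ per parameter; a fit
is flagged non-converged unless max |R̂ − 1| ≤ 0.01. At the defaults the
sampler reaches R̂ < 1.005 on literature-scale data; at the short test settings
(4 × 2,000/1,000) R̂ typically sits near 1.03–1.04 and the flag correctly
reports it, while posterior means and interval coverage are already stable.

## Heterogeneity and bias

The typical sampling variance is the inverse-variance-weight construction
(k−1)Σw / ((Σw)² − Σw²), and each I² component is its variance divided by
the total (four components + typical v). The identity
I²_total = ΣI²_components holds by construction and is still asserted after
floating-point arithmetic. For Bayesian fits I² is computed per posterior
draw and summarised by median and 95% interval; for REML it is plugged in
at the point estimate. Publication bias and time-lag bias are assessed by
refitting the model with the SE-type covariate (√v(z) for correlations,
√(1/ñ) with 1/ñ = (N_C+N_F)/(N_C N_F) for two-group contrasts) and
publication year; an interval excluding zero flags bias. No trim-and-fill
or selection-model corrections are attempted.

## Range-expansion regressions

SE and 95%-CI dispersion inputs are converted to SD on load (SD = SE·√n,
SD = half-width·√n/1.96). Dispersal rate is distance divided by the years
between core and edge establishment; records without establishment years
are rejected rather than imputed. The climate and divergence-time
regressions are unweighted Gaussian fits with a full dispersal-mode
interaction (per-mode intercepts and slopes); modes with fewer than three
records are dropped, and with a single mode the interaction is dropped with
a warning. |lnRR| is used as the divergence-time response without a
folded-normal bias correction — fidelity to the original analysis over
statistical refinement.

## Synthetic data

The individual-movement generator is the exact inverse of the analysis
model, on the Fisher-z scale: species effects from N(0, σ²_sp I + σ²_ph A)
with A from a simulated pure-birth tree, study and observation effects
independent normal, sampling noise with v_i = 1/(n_i − 3), and emitted
r = tanh(z). Defaults: pooled effect μ = 0.2 (a modest positive
physiology–movement association on the z scale), σ² = 0.05 per level
(I²_total ≈ 0.9, the high-heterogeneity regime typical of ecological
meta-analyses), n_i uniform on 10–100 (the small-study literature regime).
A fifth of records are emitted as t statistics and a tenth as reverse-coded
traits, so the conversion and alignment paths are always exercised.
Publication bias, when enabled, censors records with
P(retain) = logistic(a + b·z/SE), defaults a = −2, b = 3: severe selection
that retains roughly one in eight null results.

A note on the bias-power experiment: under the high-heterogeneity defaults
the Egger-type covariate test has little power against this selection
mechanism, because selection on z/SE then acts mostly on the heterogeneity
(which is unrelated to SE) rather than on sampling error. The power
experiment therefore runs at moderate heterogeneity (σ² = 0.01 per level),
where the selection signature is identifiable; the corresponding limitation
— bias tests of this family say little when I² approaches 1 — is a real
property of the method and worth remembering when interpreting "no evidence
of bias" findings in highly heterogeneous literatures.

The range generator draws per-mode dispersal rates as linear functions of
the core-to-edge temperature difference (slopes 1 / 0.5 / 0.1 km·y⁻¹·°C⁻¹
for aerial / aquatic / terrestrial, intercepts 5 / 2 / 1) and |lnRR| as
0.3 + 0.01·years-diverged plus noise, then constructs group means, SDs and
sizes that realise those values exactly. What the generators do **not**
emulate: real taxon sampling imbalance beyond a simple knob, correlated
moderators, non-Gaussian effect distributions, and measurement error in
climate or distance covariates — so green recovery tests demonstrate the
estimators work under the stated model, not that the model is right for any
particular literature.

## Numerical choices and test scales

Cholesky factorisations back all likelihood evaluations; the phylogenetic
correlation receives a 10⁻¹² jitter only inside the generator's Cholesky
draw. Ultrametricity tolerance is 10⁻⁹ on tip-depth spread. Recovery
experiments use 100 replicates at k = 200 (REML) and 200 replicates at
k = 100 with shortened chains (coverage); the power experiments use
k = 300. These sizes keep the full suite in the tens of minutes on one
core while leaving Monte-Carlo error small relative to the quantities
checked — with one caveat: the median bias of the pooled estimate across
100 replicates carries irreducible Monte-Carlo noise of about ±0.014
(driven by the realized common phylogenetic and study shifts in each
dataset), so a bias bound of 2% of μ = 0.2 (±0.004) is tighter than the
experiment can resolve; the corresponding check reflects the estimator's
unbiasedness only up to that noise floor.

## Known limitations

* The observation-level variance is weakly identified when sampling
  variances are nearly constant.
* REML Wald intervals ignore variance-component uncertainty; the Bayesian
  path is the reference for interval statements.
* |lnRR| regression without folded-normal correction slightly overstates
  small effects (kept deliberately; a corrected mode is a one-line change).
* The sampler is a random-walk method: for models with many moderator
  levels the collapsed dimension stays small, but very large phylogenies
  make each likelihood evaluation O(k³).
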