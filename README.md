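# movemeta

Phylogenetic multilevel meta-analysis of the links between physiology and
animal movement, for comparative ecologists and meta-analysts. The package
covers two analysis tracks:

1. **Individual movement** — synthesis of individual-level correlations
   between a physiological trait (metabolic rate, locomotor performance,
   hormones, thermal tolerance, ...) and movement behaviour (activity,
   exploration, dispersal), on the Fisher-z scale.
2. **Range expansion** — contrasts of physiological traits between
   established range cores and expanding range edges (dispersal fronts), as
   log response ratios, plus regressions of dispersal rate on climate
   differences and of |lnRR| on divergence time.

## The model

Each effect size enters with a known sampling variance: a correlation *r*
with sample size *n* becomes

    z = 0.5 ln((1+r)/(1-r)),        v(z) = 1/(n-3),

and a core/edge contrast with group means, SDs and sizes becomes

    lnRR = ln(x̄_F / x̄_C),          v(lnRR) = SD_F²/(N_F x̄_F²) + SD_C²/(N_C x̄_C²).

Effects are modelled with four crossed random effects,

    y_i = x_iᵝ + u_species + u_phylo + u_study + u_obs + e_i,
    u_phylo ~ N(0, σ²_phylo A),     e_i ~ N(0, v_i),

where **A** is the shared-ancestry correlation matrix of an ultrametric
species tree (polytomies resolved at random under a recorded seed, Grafen
branch lengths, unit depth). Moderators (trait, taxon, movement class) are
fitted without a global intercept so every level gets its own mean;
publication year and an SE-type covariate adjust for time-lag and
publication bias. Heterogeneity is partitioned with the extended I²
statistic across the four levels.

Two estimation paths share the marginal Gaussian likelihood: deterministic
REML (Wald intervals) and a Bayesian sampler with half-Cauchy(0, 1) priors
on each random-effect SD and Normal(0, 10²) priors on coefficients
(posterior means, equal-tailed 95% credible intervals, split-chain R̂).

## Worked example

```python
from movemeta.synthetic import SyntheticTruth, write_individual_bundle
from movemeta.pipeline import run_individual_analysis

paths = write_individual_bundle(SyntheticTruth(k=120, n_species=20,
                                               n_studies=15, seed=42), "demo")
report = run_individual_analysis({"data": paths["data"],
                                  "tree": paths["tree"], "seed": 42})
mu = next(c for c in report["models"]["overall"]["coefficients"]
          if c["term"] == "intercept")
print(round(mu["estimate"], 3), [round(mu["lower"], 3), round(mu["upper"], 3)])
print(round(report["heterogeneity"]["i2_total"], 3))
```

prints

```
0.205 [-0.205, 0.614]
0.907
```

— the pooled physiology–movement correlation on the Fisher-z scale with its
95% interval (the generating value 0.2 lies inside), and the proportion of
variance in the simulated literature attributable to heterogeneity rather
than sampling error (the generator is configured for a high-heterogeneity
literature, so I² ≈ 0.9).

The same pipeline runs from the shell:

```bash
movemeta simulate --seed 42 --k 120 --outdir demo
movemeta effects demo/individual_movement.csv --out demo/effects.csv
movemeta range-analysis --config range_config.yaml --estimation reml
```

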