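import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from movemeta.meta_model import (MCMCControls, ModelSpec, adaptive_metropolis,
                                 build_design, compare_fits, fit_mcmc,
                                 fit_reml)

OBS_ONLY = ("observation",)


def ivw(y, v):
    w = 1.0 / np.asarray(v)
    return float(np.sum(w * y) / np.sum(w)), float(1.0 / np.sum(w))


class TestBuildDesign:
    def test_moderator_partition(self, small_dataset):
        spec = ModelSpec(moderators=("movement_class",), random_terms=OBS_ONLY)
        d = build_design(small_dataset["effects"], spec)
        assert d.X.shape[1] == 3
        np.testing.assert_allclose(d.X.sum(axis=1), 1.0)

    def test_centered_covariate(self, small_dataset):
        spec = ModelSpec(covariates=("pub_year",), random_terms=OBS_ONLY)
        d = build_design(small_dataset["effects"], spec)
        assert abs(d.X[:, 1].mean()) < 1e-12

    def test_no_phylo_blueprint(self, small_dataset):
        spec = ModelSpec(random_terms=("species", "study", "observation"))
        d = build_design(small_dataset["effects"], spec)
        assert "phylogeny" not in d.blocks
        assert set(d.blocks) == {"species", "study", "observation"}

    def test_singular_design_named(self, small_dataset):
        # two complete indicator partitions are collinear
        spec = ModelSpec(moderators=("movement_class", "sex"),
                         random_terms=OBS_ONLY)
        with pytest.raises(ValueError, match="singular"):
            build_design(small_dataset["effects"], spec)

    @pytest.mark.parametrize("seed", range(5))
    def test_marginal_covariance_psd(self, small_dataset, seed):
        spec = ModelSpec(phylo=small_dataset["phylo"])
        d = build_design(small_dataset["effects"], spec)
        rng = np.random.default_rng(seed)
        V = d.V(rng.uniform(0, 0.5, len(d.vc_names)))
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V)[0] > 0


class TestREML:
    def test_matches_inverse_variance_oracle(self, two_point):
        spec = ModelSpec(random_terms=OBS_ONLY)
        res = fit_reml(two_point, spec, fix_sigma2={"observation": 0.0})
        mu, var = ivw(two_point["z"], two_point["v_z"])
        assert res.coefficients.loc["intercept", "estimate"] == pytest.approx(0.30, abs=1e-12)
        assert res.coefficients.loc["intercept", "se"] == pytest.approx(np.sqrt(0.005), abs=1e-12)
        assert mu == pytest.approx(0.30)

    def test_identical_values_zero_heterogeneity(self):
        df = pd.DataFrame({"z": [0.25] * 10, "v_z": [0.02] * 10})
        res = fit_reml(df, ModelSpec(random_terms=OBS_ONLY))
        assert res.variance_components["observation"] == pytest.approx(0.0, abs=1e-6)
        assert res.coefficients.loc["intercept", "estimate"] == pytest.approx(0.25)
        assert "observation" in res.boundary

    def test_row_order_invariance(self, small_dataset):
        spec = ModelSpec(phylo=small_dataset["phylo"])
        data = small_dataset["effects"]
        shuffled = data.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a, b = fit_reml(data, spec), fit_reml(shuffled, spec)
        pd.testing.assert_frame_equal(a.coefficients, b.coefficients,
                                      atol=1e-6, rtol=1e-5)

    def test_level_relabel_permutes_coefficients(self, small_dataset):
        data = small_dataset["effects"].copy()
        spec = ModelSpec(moderators=("movement_class",), random_terms=OBS_ONLY)
        a = fit_reml(data, spec)
        relabeled = data.assign(
            movement_class=data["movement_class"].map(
                {"activity": "zz_activity", "exploration": "exploration",
                 "dispersal": "dispersal"}))
        b = fit_reml(relabeled, spec)
        assert b.coefficients.loc["movement_class[zz_activity]", "estimate"] == \
            pytest.approx(a.coefficients.loc["movement_class[activity]", "estimate"], abs=1e-8)

    def test_location_shift_equivariance(self, small_dataset):
        spec = ModelSpec(moderators=("movement_class",),
                         phylo=small_dataset["phylo"])
        data = small_dataset["effects"]
        a = fit_reml(data, spec)
        b = fit_reml(data.assign(z=data["z"] + 0.7), spec)
        np.testing.assert_allclose(b.coefficients["estimate"],
                                   a.coefficients["estimate"] + 0.7, atol=1e-6)
        assert b.variance_components == pytest.approx(a.variance_components, abs=1e-6)

    def test_intervals_contain_estimate(self, small_dataset):
        res = fit_reml(small_dataset["effects"],
                       ModelSpec(phylo=small_dataset["phylo"]))
        c = res.coefficients
        assert ((c["lower"] <= c["estimate"]) & (c["estimate"] <= c["upper"])).all()
        assert all(v >= 0 for v in res.variance_components.values())


class TestAgainstMetafor:
    def test_reml_matches_rma_mv(self, small_dataset, tmp_path):
        """Independent cross-check of the multilevel REML fit against
        metafor::rma.mv on the same data and phylogenetic correlation."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; cross-check cannot run")
        data = small_dataset["effects"][["z", "v_z", "species", "study_id"]].copy()
        data["phylo"] = data["species"]
        data["obs"] = np.arange(len(data))
        A = small_dataset["phylo"]
        data.to_csv(tmp_path / "d.csv", index=False)
        A.to_dataframe().to_csv(tmp_path / "A.csv")
        script = textwrap.dedent("""
            suppressMessages(library(metafor))
            d <- read.csv(commandArgs(TRUE)[1])
            A <- as.matrix(read.csv(commandArgs(TRUE)[2], row.names=1, check.names=FALSE))
            res <- rma.mv(z, v_z, random = list(~1|species, ~1|phylo, ~1|study_id, ~1|obs),
                          R = list(phylo=A), data=d, method="REML")
            cat(coef(res), res$sigma2, sep="\\n")
        """)
        (tmp_path / "check.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "check.R"), str(tmp_path / "d.csv"),
             str(tmp_path / "A.csv")],
            capture_output=True, text=True, check=True)
        vals = [float(x) for x in out.stdout.split()]
        mu_r, sigma2_r = vals[0], vals[1:5]
        res = fit_reml(data, ModelSpec(phylo=A))
        assert res.coefficients.loc["intercept", "estimate"] == pytest.approx(mu_r, abs=1e-3)
        mine = [res.variance_components[n]
                for n in ("species", "phylogeny", "study", "observation")]
        np.testing.assert_allclose(mine, sigma2_r, atol=2e-3)


class TestMCMC:
    def test_degenerate_dataset_matches_oracle(self, two_point):
        spec = ModelSpec(random_terms=OBS_ONLY, estimation="mcmc",
                         sigma_prior_scale=1e-4,
                         mcmc=MCMCControls(chains=4, iterations=1500,
                                           warmup=750, seed=11))
        res = fit_mcmc(two_point, spec)
        assert res.coefficients.loc["intercept", "estimate"] == pytest.approx(0.30, abs=0.02)

    def test_prior_recovery_half_cauchy(self):
        """With a flat likelihood the sampler must reproduce the half-Cauchy
        prior quantiles (checks the sampling machinery itself)."""
        def logpost(theta):
            s = abs(float(theta[0]))
            return -np.log1p(s * s), None

        rng = np.random.default_rng(5)
        qs = []
        for _ in range(4):
            draws, _, _ = adaptive_metropolis(
                logpost, np.array([1.0]), 6000, 2000, rng)
            qs.append(np.percentile(np.abs(draws[:, 0]), [25, 50, 75]))
        med = np.median(np.array(qs), axis=0)
        expected = stats.halfcauchy.ppf([0.25, 0.5, 0.75])  # 0.414, 1, 2.414
        np.testing.assert_allclose(med, expected, rtol=0.2)

    def test_rhat_and_interval_invariants(self, small_dataset):
        spec = ModelSpec(phylo=small_dataset["phylo"], estimation="mcmc",
                         mcmc=MCMCControls(chains=4, iterations=1200,
                                           warmup=600, seed=2))
        res = fit_mcmc(small_dataset["effects"], spec)
        c = res.coefficients
        assert ((c["lower"] <= c["estimate"]) & (c["estimate"] <= c["upper"])).all()
        assert set(res.rhat) >= {"sigma_species", "sigma_phylogeny",
                                 "sigma_study", "sigma_observation"}
        assert all(v >= 0 for v in res.variance_components.values())
        # flag must reflect the R-hat rule
        worst = max(abs(r - 1) for r in res.rhat.values())
        assert res.converged == (worst <= 0.01)


class TestCompareFits:
    def test_identical_fits_zero_delta(self, small_dataset):
        res = fit_reml(small_dataset["effects"],
                       ModelSpec(phylo=small_dataset["phylo"]))
        mc = res  # identical inputs: all deltas zero
        report = compare_fits(res, mc)
        assert (report["delta"] == 0).all()

    def test_reml_mcmc_agree_on_well_identified_data(self, small_dataset):
        spec_r = ModelSpec(phylo=small_dataset["phylo"])
        spec_m = ModelSpec(phylo=small_dataset["phylo"], estimation="mcmc",
                           mcmc=MCMCControls(chains=4, iterations=1500,
                                             warmup=750, seed=8))
        reml = fit_reml(small_dataset["effects"], spec_r)
        mcmc = fit_mcmc(small_dataset["effects"], spec_m)
        report = compare_fits(reml, mcmc)
        assert report.loc["intercept", "pass"]
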