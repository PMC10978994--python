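"""NB-GLM fitting, dispersion estimation, the rank LRT, BH adjustment and
DMR merging."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

import rankmeth as rm
from rankmeth import glm
from rankmeth.diffmeth import (DesignSpec, DispersionEstimates, WindowFits,
                               add_q, bh_adjust, call_dmrs, lrt_rank)


def _fixed_disp(counts, phi):
    return DispersionEstimates(phi, pd.Series(phi, index=counts.window_ids),
                               prior_df=10.0)


def _samples(ranks, ages=None):
    n = len(ranks)
    ages = ages or ["adult"] * n
    return pd.DataFrame({"rank_class": ranks, "age_class": ages},
                        index=[f"s{i}" for i in range(n)])


class TestFits:
    def test_saturated_two_group_means_and_logfc(self):
        """Equal offsets, groups {2,4} vs {8,16}: NB score equations give the
        arithmetic group means 3 and 12 for any dispersion, logFC = 2."""
        samples = _samples(["high", "high", "low", "low"])
        mat = pd.DataFrame(np.array([[2, 4, 8, 16]]), index=["c:0-300"],
                           columns=samples.index).T
        cm = rm.CountMatrix(mat.T, lib_sizes=pd.Series(1e6, index=samples.index))
        design = DesignSpec(include_age=False)
        for phi in (0.0, 0.1, 0.5):
            fits = rm.fit_window_models(cm, design, pd.Series(1.0, index=samples.index),
                                        _fixed_disp(cm, phi), samples)
            X, _, _ = design.matrices(samples)
            beta, mu, _, conv = glm.irls_fit(
                cm.counts.to_numpy(float), X, np.log(1e6) * np.ones(4), phi)
            assert conv.all()
            assert mu[0, :2] == pytest.approx([3, 3], rel=1e-5)
            assert mu[0, 2:] == pytest.approx([12, 12], rel=1e-5)
            assert fits.logfc[0] == pytest.approx(2.0, abs=1e-5)

    def test_identical_counts_give_zero_effect(self):
        samples = _samples(["high"] * 3 + ["low"] * 3,
                           ["cub", "adult", "cub", "adult", "cub", "adult"])
        mat = pd.DataFrame({s: [17] for s in samples.index}, index=["c:0-300"])
        cm = rm.CountMatrix(mat, lib_sizes=pd.Series(1e6, index=samples.index))
        fits = rm.fit_window_models(cm, DesignSpec(), pd.Series(1.0, index=samples.index),
                                    _fixed_disp(cm, 0.2), samples)
        assert fits.logfc[0] == pytest.approx(0.0, abs=1e-6)
        assert (fits.deviance_reduced[0] - fits.deviance_full[0]) \
            == pytest.approx(0.0, abs=1e-6)

    def test_phi_zero_matches_poisson_glm(self):
        """phi = 0 reduces the fit to a Poisson GLM (independent fit via
        statsmodels)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        samples = _samples(["high"] * 5 + ["low"] * 5,
                           ["cub", "adult"] * 5)
        y = rng.poisson(30, size=(3, 10))
        design = DesignSpec()
        X, _, _ = design.matrices(samples)
        off = np.log(np.full(10, 1e6))
        beta, _, _, conv = glm.irls_fit(y.astype(float), X, off, 0.0)
        assert conv.all()
        for g in range(3):
            ref = sm.GLM(y[g], X, family=sm.families.Poisson(),
                         offset=off).fit()
            assert beta[g] == pytest.approx(ref.params, abs=1e-6)

    def test_irls_matches_bruteforce_likelihood_maximization(self):
        """On 5 windows x 6 samples, IRLS coefficients agree to 4 decimals
        with direct numerical maximization of the NB log-likelihood."""
        rng = np.random.default_rng(7)
        samples = _samples(["high"] * 3 + ["low"] * 3,
                           ["cub", "adult", "cub", "adult", "adult", "cub"])
        y = rng.negative_binomial(5, 5 / (5 + 40), size=(5, 6)).astype(float)
        phi = 0.2
        design = DesignSpec()
        X, _, _ = design.matrices(samples)
        off = np.log(rng.uniform(8e5, 1.2e6, size=6))
        beta, _, _, conv = glm.irls_fit(y, X, off, phi)
        assert conv.all()
        for g in range(5):
            def nll(b, g=g):
                mu = np.exp(X @ b + off)[None, :]
                return -glm.nb_loglik(y[g][None, :], mu, phi)[0]
            res = minimize(nll, np.zeros(3), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 20000})
            assert beta[g] == pytest.approx(res.x, abs=1e-4)

    def test_matches_edger_glmfit(self):
        """Independent oracle: edgeR::glmFit at a fixed dispersion
        reproduces the same coefficients and deviances."""
        rng = np.random.default_rng(3)
        samples = _samples(["high"] * 4 + ["low"] * 4,
                           ["cub", "adult"] * 4)
        y = rng.negative_binomial(5, 5 / (5 + 50), size=(20, 8))
        design = DesignSpec()
        X, _, _ = design.matrices(samples)
        lib = rng.uniform(8e5, 1.2e6, size=8)
        beta, _, dev, conv = glm.irls_fit(y.astype(float), X, np.log(lib), 0.15)
        assert conv.all()
        csv = pd.DataFrame(y).to_csv(index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            y <- as.matrix(read.csv('stdin'))
            X <- matrix(c({','.join(str(v) for v in X.T.ravel())}), ncol=3)
            lib <- c({','.join(str(v) for v in lib)})
            fit <- glmFit(y, design=X, dispersion=0.15, offset=log(lib),
                          prior.count=0)
            write.csv(cbind(fit$coefficients, fit$deviance), row.names=FALSE)
        """)
        res = subprocess.run(["Rscript", "-e", script], input=csv,
                             capture_output=True, text=True, check=True)
        ref = pd.read_csv(pd.io.common.StringIO(res.stdout)).to_numpy()
        assert np.allclose(beta, ref[:, :3], atol=1e-4)
        assert np.allclose(dev, ref[:, 3], rtol=1e-5)


class TestDispersionEstimation:
    def _simulated(self, phi, seed=4, n_windows=2000):
        cfg = rm.SimConfig(seed=seed,
                           contigs=[("c1", n_windows * 300, False)],
                           dispersion=phi)
        samples = rm.simulate_cohort(cfg)
        counts, _ = rm.simulate_methylation_counts(cfg, None, samples)
        filtered = rm.filter_windows(counts)
        factors = rm.tmm_factors(filtered)
        return filtered, factors, samples

    def test_poisson_data_gives_near_zero_common(self):
        filtered, factors, samples = self._simulated(0.0)
        disp = rm.estimate_dispersions(filtered, DesignSpec(), factors, samples)
        assert disp.common < 0.02

    def test_nb_dispersion_recovered(self):
        filtered, factors, samples = self._simulated(0.3)
        disp = rm.estimate_dispersions(filtered, DesignSpec(), factors, samples)
        assert disp.common == pytest.approx(0.3, rel=0.2)

    def test_infinite_prior_df_collapses_tagwise_to_common(self):
        filtered, factors, samples = self._simulated(0.2, n_windows=300)
        disp = rm.estimate_dispersions(filtered, DesignSpec(), factors,
                                       samples, prior_df=1e8)
        assert np.allclose(disp.tagwise, disp.common, rtol=0.05)

    def test_non_full_rank_design_rejected(self):
        filtered, factors, samples = self._simulated(0.2, n_windows=10)
        lopsided = samples.copy()
        lopsided["age_class"] = np.where(lopsided["rank_class"] == "low",
                                         "cub", "adult")
        with pytest.raises(ValueError, match="full rank"):
            rm.estimate_dispersions(filtered, DesignSpec(), factors, lopsided)


class TestLRT:
    def _fits(self, dev_red, dev_full, logfc=1.0, converged=True):
        return WindowFits(window_ids=["c:0-300"], logfc=np.array([logfc]),
                          deviance_full=np.array([dev_full]),
                          deviance_reduced=np.array([dev_red]),
                          converged=np.array([converged]),
                          dispersions=np.array([0.2]))

    def test_chisq_reference_value(self):
        t = lrt_rank(self._fits(13.841, 10.0))
        assert t["lr_stat"].iloc[0] == pytest.approx(3.841)
        assert t["p"].iloc[0] == pytest.approx(0.0500, abs=2e-4)

    def test_zero_statistic_gives_p_one(self):
        t = lrt_rank(self._fits(10.0, 10.0))
        assert t["p"].iloc[0] == 1.0

    def test_nonconverged_window_carries_na(self):
        t = lrt_rank(self._fits(15.0, 10.0, converged=False))
        assert np.isnan(t["p"].iloc[0])

    def test_inconsistent_fits_rejected(self):
        with pytest.raises(ValueError, match="negative LR"):
            lrt_rank(self._fits(10.0, 11.0))


class TestBH:
    def test_hand_computed_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _tests_frame(grid, sig_windows, logfc_map=None, q_sig=0.01):
    rows = {}
    for wid in grid.ids:
        sig = wid in sig_windows
        lf = (logfc_map or {}).get(wid, 1.0 if sig else 0.01)
        rows[wid] = {"logFC": lf, "lr_stat": 5.0, "p": 0.001 if sig else 0.5,
                     "q": q_sig if sig else 0.6}
    return pd.DataFrame.from_dict(rows, orient="index")


class TestDMRCalling:
    def test_twelve_adjacent_windows_merge_to_3600bp(self):
        grid = rm.tile_windows([("c1", 6000)], 300)
        sig = {f"c1:{s}-{s + 300}" for s in range(1200, 4800, 300)}
        dmrs = call_dmrs(_tests_frame(grid, sig), grid)
        assert len(dmrs) == 1
        assert dmrs[0].length == 3600
        assert dmrs[0].n_windows == 12

    def test_no_significant_windows(self):
        grid = rm.tile_windows([("c1", 3000)], 300)
        assert call_dmrs(_tests_frame(grid, set()), grid) == []

    def test_opposite_signs_split(self):
        grid = rm.tile_windows([("c1", 1200)], 300)
        sig = {"c1:300-600", "c1:600-900"}
        dmrs = call_dmrs(_tests_frame(grid, sig,
                                      {"c1:300-600": 1.5, "c1:600-900": -1.5}),
                         grid)
        assert len(dmrs) == 2
        assert [d.length for d in dmrs] == [300, 300]
        assert {d.direction for d in dmrs} == {"hyper", "hypo"}

    def test_gap_breaks_run(self):
        grid = rm.tile_windows([("c1", 1500)], 300)
        sig = {"c1:0-300", "c1:300-600", "c1:900-1200"}
        dmrs = call_dmrs(_tests_frame(grid, sig), grid)
        assert [d.n_windows for d in dmrs] == [2, 1]

    def test_partition_property(self, small_pipeline_run):
        """Every significant window belongs to exactly one DMR; no DMR holds
        a non-significant or opposite-sign window."""
        tests, dmrs = small_pipeline_run["tests"], small_pipeline_run["dmrs"]
        member = [w for d in dmrs for w in d.window_ids]
        assert len(member) == len(set(member))
        sig = set(tests.index[(tests["q"] <= 0.05) & (tests["logFC"] != 0)])
        assert set(member) == sig
        for d in dmrs:
            signs = np.sign(tests.loc[d.window_ids, "logFC"])
            assert (signs == (1 if d.direction == "hyper" else -1)).all()
            assert (tests.loc[d.window_ids, "q"] <= 0.05).all()
            assert d.length == sum(
                e - s for _, s, e in
                (rm.counts.parse_window_id(w) for w in d.window_ids))


class TestPipelineCalibration:
    def test_logfc_recovery_at_planted_windows(self, small_pipeline_run):
        run = small_pipeline_run
        eff = run["truth"].window_effects
        tests = run["tests"]
        planted = [w for w in tests.index if eff.get(w, 0) != 0]
        bias = (tests.loc[planted, "logFC"] - eff[planted]).mean()
        assert abs(bias) < 0.15
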