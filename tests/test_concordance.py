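"""Age-class effect concordance and Wilcoxon comparisons, with exact
enumeration oracles for the signed-rank null."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import rankmeth as rm
from rankmeth.concordance import (AgeClassEffects, ageclass_effects,
                                  effect_correlation_test,
                                  mito_nuclear_compare, wilcoxon_rank_sum,
                                  wilcoxon_signed_rank)
from rankmeth.genome import Contig, Gene, GeneModelSet
from rankmeth.simulate import plant_random_dmrs


def _planted_run(seed=21, shared=True):
    contigs = [("c1", 240_000, False)]
    dmrs = plant_random_dmrs(contigs, 300, 20, 2, 2.0, seed=seed)
    cfg = rm.SimConfig(seed=seed, contigs=contigs, planted_dmrs=dmrs)
    samples = rm.simulate_cohort(cfg)
    counts, truth = rm.simulate_methylation_counts(cfg, None, samples)
    filtered = rm.filter_windows(counts)
    return cfg, samples, filtered, truth


class TestAgeClassEffects:
    def test_shared_effect_agrees_between_classes(self):
        """Simulated rank effects are identical in cubs and adults, so the
        class-specific logFC estimates agree windowwise."""
        _, samples, filtered, truth = _planted_run()
        planted = [w for w in filtered.window_ids
                   if truth.window_effects.get(w, 0) != 0]
        eff = ageclass_effects(filtered, samples, planted)
        true = truth.window_effects[planted].to_numpy()
        assert np.corrcoef(eff.effects["logFC_cub"],
                           eff.effects["logFC_adult"])[0, 1] > 0.9
        # class-specific estimates are unbiased for the shared truth
        assert abs((eff.effects["logFC_cub"] * np.sign(true) -
                    np.abs(true)).mean()) < 0.25
        assert abs((eff.effects["logFC_adult"] * np.sign(true) -
                    np.abs(true)).mean()) < 0.25

    def test_duplicated_columns_give_identical_vectors(self):
        """If the adult samples are literal copies of the cub samples, the
        two class-specific fits coincide."""
        rng = np.random.default_rng(0)
        cubs = pd.DataFrame({"rank_class": ["high"] * 4 + ["low"] * 4,
                             "age_class": "cub"},
                            index=[f"c{i}" for i in range(8)])
        adults = cubs.copy()
        adults.index = [f"a{i}" for i in range(8)]
        adults["age_class"] = "adult"
        samples = pd.concat([cubs, adults])
        base = rng.poisson(40, size=(50, 8))
        mat = pd.DataFrame(np.hstack([base, base]),
                           index=[f"c1:{i * 300}-{(i + 1) * 300}"
                                  for i in range(50)],
                           columns=samples.index)
        eff = ageclass_effects(rm.CountMatrix(mat), samples,
                               list(mat.index[:10]))
        assert np.allclose(eff.effects["logFC_cub"],
                           eff.effects["logFC_adult"], atol=1e-6)

    def test_missing_rank_level_rejected(self):
        samples = pd.DataFrame({
            "rank_class": ["high"] * 4 + ["low"] * 2 + ["high"] * 2,
            "age_class": ["cub"] * 4 + ["adult"] * 4},
            index=[f"s{i}" for i in range(8)])
        mat = pd.DataFrame(np.ones((5, 8), dtype=int) * 20,
                           index=[f"c1:{i * 300}-{(i + 1) * 300}"
                                  for i in range(5)], columns=samples.index)
        with pytest.raises(ValueError, match="lacks a rank level"):
            ageclass_effects(rm.CountMatrix(mat), samples, list(mat.index))


class TestCorrelationTest:
    def _effects(self, n=500, seed=1):
        rng = np.random.default_rng(seed)
        idx = [f"c1:{i * 300}-{(i + 1) * 300}" for i in range(n)]
        return AgeClassEffects(effects=pd.DataFrame(
            {"logFC_cub": rng.normal(0, 0.3, n),
             "logFC_adult": rng.normal(0, 0.3, n)}, index=idx))

    def test_identical_vectors_give_r_one(self):
        eff = self._effects()
        eff.effects["logFC_adult"] = eff.effects["logFC_cub"]
        res = effect_correlation_test(eff, list(eff.effects.index[:50]),
                                      n_draws=50, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_shared_planted_effects_reach_minimal_p(self):
        """Candidates carry a shared effect, nothing else does: the observed
        r exceeds every null draw, so p = 1/(n_draws+1)."""
        eff = self._effects()
        cand = list(eff.effects.index[:40])
        shared = np.linspace(-2, 2, 40)
        eff.effects.loc[cand, "logFC_cub"] = shared + \
            np.random.default_rng(2).normal(0, 0.1, 40)
        eff.effects.loc[cand, "logFC_adult"] = shared + \
            np.random.default_rng(3).normal(0, 0.1, 40)
        res = effect_correlation_test(eff, cand, n_draws=1000, seed=5)
        assert res.empirical_p == pytest.approx(1 / 1001)

    def test_null_candidate_p_roughly_uniform(self):
        """Candidate sets drawn from the same null pool give roughly uniform
        empirical p-values."""
        eff = self._effects(seed=7)
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(40):
            cand = list(rng.choice(eff.effects.index, 30, replace=False))
            ps.append(effect_correlation_test(eff, cand, n_draws=99,
                                              seed=int(rng.integers(1e6))
                                              ).empirical_p)
        assert 0.25 < np.mean(ps) < 0.75

    def test_oversized_candidate_set_rejected(self):
        eff = self._effects(n=10)
        with pytest.raises(ValueError):
            effect_correlation_test(eff, [f"c1:{i * 300}-{(i + 1) * 300}"
                                          for i in range(11)], n_draws=10,
                                    seed=0)


def _exact_signed_rank_p(d):
    """Enumerate all 2^n sign assignments of the ranked |d| to get the exact
    two-sided p of the observed W+."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mu = n * (n + 1) / 2 / 2
    dev_obs = abs(w_obs - mu)
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= dev_obs - 1e-9:
            count += 1
    return count / 2 ** n


class TestWilcoxon:
    def test_six_positive_differences_exact_p(self):
        res = wilcoxon_signed_rank(np.arange(1, 7) + 10.0, np.arange(1, 7.0))
        assert res.p == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_full_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.normal(0.3, 1, n)
        y = np.zeros(n)
        res = wilcoxon_signed_rank(x, y)
        assert res.p == pytest.approx(_exact_signed_rank_p(x), abs=1e-12)

    def test_all_zero_differences_report_p_one(self):
        res = wilcoxon_signed_rank(np.ones(5), np.ones(5))
        assert res.p == 1.0 and res.n == 0

    def test_large_n_uses_normal_approximation_with_z(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.4, 1, 40)
        res = wilcoxon_signed_rank(x, np.zeros(40))
        assert res.z is not None
        assert 0 < res.p < 1

    def test_rank_sum_null_p_uniformish(self):
        rng = np.random.default_rng(5)
        ps = [wilcoxon_rank_sum(rng.normal(size=10), rng.normal(size=6)).p
              for _ in range(200)]
        assert 0.4 < np.mean(ps) < 0.6
        assert (np.array(ps) <= 0.05).mean() < 0.12


class TestMitoNuclear:
    def _setup(self, multiplier, seed=13, n_cells=4):
        cfg = rm.SimConfig(
            seed=seed,
            contigs=[("c1", 60_000, False), ("cM", 15_000, True)],
            n_per_cell={("high", "cub"): n_cells, ("high", "adult"): n_cells,
                        ("low", "cub"): n_cells, ("low", "adult"): n_cells},
            mito_multiplier=multiplier)
        samples = rm.simulate_cohort(cfg)
        genome = rm.simulate_gene_model(cfg, genes_per_contig=6)
        meth, _ = rm.simulate_methylation_counts(cfg, genome, samples)
        expr = rm.simulate_expression_counts(cfg, genome, samples)
        return samples, genome, meth, expr

    def test_elevated_mito_abundance_detected(self):
        samples, genome, meth, expr = self._setup(8.0)
        results, table = mito_nuclear_compare(meth, expr, genome, samples)
        by_label = {r.label: r for r in results}
        assert by_label["dna_mito_vs_nuclear"].p < 0.01
        assert by_label["rna_mito_vs_nuclear"].p < 0.01
        assert (table["dna_mito_mean_cpm"] > table["dna_nuclear_mean_cpm"]).all()

    def test_rank_contrast_null_when_ranks_equivalent(self):
        samples, genome, meth, expr = self._setup(8.0, seed=14)
        results, _ = mito_nuclear_compare(meth, expr, genome, samples)
        by_label = {r.label: r for r in results}
        # no rank effect simulated: the high-vs-low contrasts stay null
        assert by_label["dna_high_vs_low"].p > 0.05
        assert by_label["rna_high_vs_low"].p > 0.05

    def test_requires_mitochondrial_contig(self):
        cfg = rm.SimConfig(seed=1, contigs=[("c1", 30_000, False)])
        samples = rm.simulate_cohort(cfg)
        genome = rm.simulate_gene_model(cfg)
        meth, _ = rm.simulate_methylation_counts(cfg, genome, samples)
        expr = rm.simulate_expression_counts(cfg, genome, samples)
        with pytest.raises(ValueError, match="mitochondrial"):
            mito_nuclear_compare(meth, expr, genome, samples)

    def test_paired_signed_rank_power_at_multiplier_three(self):
        """With multiplier >= 3 and 16 individuals the paired DNA test
        rejects at the 5% level in nearly all replicates."""
        rejections = 0
        for seed in range(10):
            samples, genome, meth, expr = self._setup(3.0, seed=100 + seed)
            results, _ = mito_nuclear_compare(meth, expr, genome, samples)
            by_label = {r.label: r for r in results}
            rejections += by_label["dna_mito_vs_nuclear"].p <= 0.05
        assert rejections >= 9
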