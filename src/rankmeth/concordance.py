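"""Age-class effect concordance and mitochondrial/nuclear abundance tests.

Two questions: (1) is the rank effect at the candidate DMR windows shared
by cubs and adults (separate rank-only NB fits per age class, Pearson
correlation of the two logFC vectors, empirical p from random equal-size
window draws); (2) are mitochondrial regions more abundant than nuclear
ones in both the methylation (DNA) and expression (RNA) data (paired
Wilcoxon signed-rank across individuals), and do rank classes differ in
overall mean abundance (independent Wilcoxon rank-sum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix, cpm, parse_window_id, tmm_factors
from .diffmeth import DesignSpec, estimate_dispersions, fit_window_models, \
    lrt_rank
from .genome import GeneModelSet


@dataclass
class AgeClassEffects:
    """Per-window rank logFC from rank-only fits within each age class."""

    effects: pd.DataFrame  # columns logFC_cub, logFC_adult; index = window


@dataclass
class CorrelationTest:
    r: float
    n_windows: int
    n_draws: int
    empirical_p: float
    null_r: np.ndarray


@dataclass
class WilcoxonResult:
    label: str
    test: str        # 'signed_rank_paired' or 'rank_sum_independent'
    statistic: float
    z: float | None
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"label": self.label, "test": self.test,
                "statistic": self.statistic, "Z": self.z, "p": self.p,
                "n": self.n}


def ageclass_effects(counts: CountMatrix, samples: pd.DataFrame,
                     candidate_windows: list[str],
                     prior_df: float = 10.0) -> AgeClassEffects:
    """Rank-only NB-LRT per age class (own TMM factors and dispersions),
    evaluated at the fixed candidate windows."""
    design = DesignSpec(include_age=False)
    cols = {}
    for age in ("cub", "adult"):
        ids = list(samples.index[samples["age_class"] == age])
        if not ids:
            raise ValueError(f"no samples in age class {age!r}")
        sub_samples = samples.loc[ids]
        if not {"high", "low"} <= set(sub_samples["rank_class"]):
            raise ValueError(f"age class {age!r} lacks a rank level")
        sub = counts.subset_samples(ids)
        factors = tmm_factors(sub)
        disp = estimate_dispersions(sub, design, factors, sub_samples,
                                    prior_df=prior_df)
        fits = fit_window_models(sub, design, factors, disp, sub_samples)
        tests = lrt_rank(fits)
        cols[f"logFC_{age}"] = tests.loc[candidate_windows, "logFC"]
    return AgeClassEffects(effects=pd.DataFrame(cols))


def effect_correlation_test(effects_all: AgeClassEffects,
                            candidate_windows: list[str],
                            n_draws: int = 1000, seed: int = 0
                            ) -> CorrelationTest:
    """Pearson r between cub and adult logFC at the candidate windows, with
    a one-sided empirical p from ``n_draws`` equal-size random window
    subsets (without replacement) of the full pool: p = (1 + #{r_null >=
    r_obs}) / (1 + n_draws)."""
    eff = effects_all.effects
    missing = [w for w in candidate_windows if w not in eff.index]
    if missing:
        raise ValueError(f"candidate windows missing from effect table: "
                         f"{missing[:5]}")
    m = len(candidate_windows)
    if m < 3:
        raise ValueError("need at least 3 candidate windows")
    if m > len(eff):
        raise ValueError("candidate set larger than the window pool")
    x = eff.loc[candidate_windows, "logFC_cub"].to_numpy()
    y = eff.loc[candidate_windows, "logFC_adult"].to_numpy()
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng([int(seed), 29])
    pool_x = eff["logFC_cub"].to_numpy()
    pool_y = eff["logFC_adult"].to_numpy()
    null_r = np.empty(n_draws)
    for b in range(n_draws):
        ix = rng.choice(len(eff), size=m, replace=False)
        null_r[b] = np.corrcoef(pool_x[ix], pool_y[ix])[0, 1]
    p = (1 + int(np.sum(null_r >= r_obs))) / (1 + n_draws)
    return CorrelationTest(r=r_obs, n_windows=m, n_draws=n_draws,
                           empirical_p=p, null_r=null_r)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by dynamic
    programming over the 2^n equiprobable sign assignments; tied ranks
    (half-integers after midranking) are handled by doubling."""
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r or None]
    w2 = 2 * w_plus
    mu2 = total / 2
    dev = abs(w2 - mu2)
    support = np.arange(total + 1)
    p = counts[np.abs(support - mu2) >= dev - 1e-9].sum() / counts.sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray,
                         label: str = "") -> WilcoxonResult:
    """Two-sided paired signed-rank test; zero differences dropped. Exact
    null (full sign-assignment distribution, ties allowed) for n <= 25,
    normal approximation with tie and continuity correction otherwise.
    All-zero differences report p = 1 by convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired test needs equal-length vectors")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(label=label, test="signed_rank_paired",
                              statistic=0.0, z=0.0, p=1.0, n=0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4
    tie_sizes = np.unique(ranks, return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24 \
        - np.sum(tie_sizes**3 - tie_sizes) / 48
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(sigma2) \
        if sigma2 > 0 else 0.0
    if n <= 25:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        p = float(2 * stats.norm.sf(abs(z))) if sigma2 > 0 else 1.0
    return WilcoxonResult(label=label, test="signed_rank_paired",
                          statistic=w_plus, z=float(z), p=min(1.0, p), n=n)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray,
                      label: str = "", exact: bool = False) -> WilcoxonResult:
    """Two-sided independent-samples rank-sum test; normal approximation
    with continuity and tie correction by default, exact on request."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u = float(res.statistic)
    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2
    allv = np.concatenate([x, y])
    tie_sizes = np.unique(allv, return_counts=True)[1]
    n = n1 + n2
    sigma2 = n1 * n2 / 12 * ((n + 1) - np.sum(tie_sizes**3 - tie_sizes)
                             / (n * (n - 1)))
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return WilcoxonResult(label=label, test="rank_sum_independent",
                          statistic=u, z=float(z), p=float(res.pvalue),
                          n=n)


def mito_nuclear_compare(meth_counts: CountMatrix, expr_counts: CountMatrix,
                         genome: GeneModelSet, samples: pd.DataFrame,
                         meth_factors: pd.Series | None = None,
                         expr_factors: pd.Series | None = None
                         ) -> tuple[list[WilcoxonResult], pd.DataFrame]:
    """Four tests plus the per-individual paired abundance table.

    DNA: per individual, mean CPM over mitochondrial windows vs over nuclear
    windows (paired signed-rank); RNA likewise over genes. Rank contrasts:
    independent rank-sum of the per-individual overall mean CPM (DNA and
    RNA) between high- and low-ranking animals.
    """
    mito_contigs = genome.mitochondrial_contigs
    if not mito_contigs:
        raise ValueError("gene model flags no mitochondrial contig")
    if meth_factors is None:
        meth_factors = tmm_factors(meth_counts)
    if expr_factors is None:
        expr_factors = tmm_factors(expr_counts)

    meth_cpm = cpm(meth_counts, meth_factors)
    is_mito_w = np.array([parse_window_id(w)[0] in mito_contigs
                          for w in meth_counts.window_ids])
    if is_mito_w.all() or not is_mito_w.any():
        raise ValueError("need both mitochondrial and nuclear windows")
    dna_mito = meth_cpm.loc[is_mito_w].mean(axis=0)
    dna_nucl = meth_cpm.loc[~is_mito_w].mean(axis=0)

    expr_cpm_mat = cpm(expr_counts, expr_factors)
    gene_mito = {g.gene_id: genome.is_mitochondrial_gene(g)
                 for g in genome.genes}
    is_mito_g = np.array([gene_mito.get(g, False)
                          for g in expr_counts.window_ids])
    if is_mito_g.all() or not is_mito_g.any():
        raise ValueError("need both mitochondrial and nuclear genes")
    rna_mito = expr_cpm_mat.loc[is_mito_g].mean(axis=0)
    rna_nucl = expr_cpm_mat.loc[~is_mito_g].mean(axis=0)

    shared = [s for s in meth_counts.samples if s in expr_counts.samples]
    table = pd.DataFrame({
        "dna_mito_mean_cpm": dna_mito,
        "dna_nuclear_mean_cpm": dna_nucl,
    })
    table["rank_class"] = samples.loc[table.index, "rank_class"]
    rna_table = pd.DataFrame({"rna_mito_mean_cpm": rna_mito,
                              "rna_nuclear_mean_cpm": rna_nucl})
    table = table.join(rna_table, how="outer")

    results = [
        wilcoxon_signed_rank(dna_mito.to_numpy(), dna_nucl.to_numpy(),
                             label="dna_mito_vs_nuclear"),
        wilcoxon_signed_rank(rna_mito.to_numpy(), rna_nucl.to_numpy(),
                             label="rna_mito_vs_nuclear"),
    ]
    rank_dna = samples.loc[meth_counts.samples, "rank_class"]
    overall_dna = meth_cpm.mean(axis=0)
    results.append(wilcoxon_rank_sum(
        overall_dna[rank_dna == "high"].to_numpy(),
        overall_dna[rank_dna == "low"].to_numpy(),
        label="dna_high_vs_low"))
    rank_rna = samples.loc[expr_counts.samples, "rank_class"]
    overall_rna = expr_cpm_mat.mean(axis=0)
    results.append(wilcoxon_rank_sum(
        overall_rna[rank_rna == "high"].to_numpy(),
        overall_rna[rank_rna == "low"].to_numpy(),
        label="rna_high_vs_low"))
    return results, table
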