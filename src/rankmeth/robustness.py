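"""Subsample-coherence selection of candidate DMRs.

Samples are randomly partitioned into K groups (default 6) under the
constraint that every group contains at least one sample of each rank class
and each age class; subset k is the cohort minus group k. The full
window-level analysis (TMM, dispersion estimation, NB fits, LRT) is rerun
on every subset, evaluated at the candidate DMR windows found on the full
data. A candidate survives ("selected") only if every member window has
p <= alpha in every subset with one coherent effect direction; otherwise it
is "excluded" with the violating cells recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountMatrix, tmm_factors
from .diffmeth import DMR, DesignSpec, estimate_dispersions, \
    fit_window_models, lrt_rank


@dataclass
class SubsetScheme:
    k: int
    assignment: pd.Series          # sample id -> group (0..K-1)
    seed: int

    @property
    def groups(self) -> list[list[str]]:
        return [list(self.assignment.index[self.assignment == g])
                for g in range(self.k)]

    @property
    def subsets(self) -> list[list[str]]:
        if self.k == 1:
            # degenerate consistency path: the single "subset" is the full
            # cohort, so refits must reproduce the full-data statistics
            return [list(self.assignment.index)]
        return [list(self.assignment.index[self.assignment != g])
                for g in range(self.k)]

    def to_frame(self) -> pd.DataFrame:
        return self.assignment.rename("group").to_frame()


def make_subset_scheme(samples: pd.DataFrame, k: int = 6, seed: int = 0,
                       max_tries: int = 10_000) -> SubsetScheme:
    """Constrained random partition into k near-equal groups, each holding
    at least one high, one low, one cub and one adult sample. Rejection
    sampling; deterministic given the seed."""
    n = len(samples)
    if n < k:
        raise ValueError("fewer samples than groups")
    for col, levels in (("rank_class", ("high", "low")),
                        ("age_class", ("cub", "adult"))):
        for lev in levels:
            if (samples[col] == lev).sum() < k:
                raise ValueError(
                    f"constraint unsatisfiable: fewer than {k} samples with "
                    f"{col}={lev!r}")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    base = np.repeat(np.arange(k), sizes)
    rng = np.random.default_rng([int(seed), 11])
    rank = samples["rank_class"].to_numpy()
    age = samples["age_class"].to_numpy()
    for _ in range(max_tries):
        perm = rng.permutation(n)
        groups = np.empty(n, dtype=int)
        groups[perm] = base
        ok = True
        for g in range(k):
            m = groups == g
            if not ({"high", "low"} <= set(rank[m])
                    and {"cub", "adult"} <= set(age[m])):
                ok = False
                break
        if ok:
            assignment = pd.Series(groups, index=samples.index, name="group")
            return SubsetScheme(k=k, assignment=assignment, seed=seed)
    raise RuntimeError(f"no valid partition found in {max_tries} tries")


@dataclass
class SubsetStats:
    """Per-subset refit results at the candidate windows: long DataFrame
    with columns subset, window, logFC, p."""

    table: pd.DataFrame
    k: int

    def cell(self, subset: int, window: str) -> pd.Series:
        m = (self.table["subset"] == subset) & (self.table["window"] == window)
        if not m.any():
            raise KeyError(f"no statistics for subset {subset}, window {window}")
        return self.table[m].iloc[0]

    def pivot(self, value: str) -> pd.DataFrame:
        return self.table.pivot(index="window", columns="subset", values=value)


def refit_subsets(counts: CountMatrix, samples: pd.DataFrame,
                  scheme: SubsetScheme, candidate_windows: list[str],
                  design: DesignSpec = DesignSpec(),
                  prior_df: float = 10.0) -> SubsetStats:
    """Rerun TMM, dispersion estimation and the NB LRT on each leave-one-
    group-out subset; the window set is frozen to the full-data filtered
    windows (no re-filtering), and results are collected at the candidate
    windows."""
    missing = [w for w in candidate_windows if w not in counts.counts.index]
    if missing:
        raise ValueError(f"candidate windows absent from matrix: {missing[:5]}")
    rows = []
    for s_ix, subset in enumerate(scheme.subsets):
        sub = counts.subset_samples(subset)
        sub_samples = samples.loc[subset]
        assert {"high", "low"} <= set(sub_samples["rank_class"]), \
            "subset lost a rank level (scheme invariant violated)"
        assert {"cub", "adult"} <= set(sub_samples["age_class"]), \
            "subset lost an age level (scheme invariant violated)"
        factors = tmm_factors(sub)
        disp = estimate_dispersions(sub, design, factors, sub_samples,
                                    prior_df=prior_df)
        fits = fit_window_models(sub, design, factors, disp, sub_samples)
        tests = lrt_rank(fits)
        sel = tests.loc[candidate_windows]
        for wid, r in sel.iterrows():
            rows.append({"subset": s_ix, "window": wid,
                         "logFC": r["logFC"], "p": r["p"]})
    return SubsetStats(table=pd.DataFrame(rows), k=scheme.k)


@dataclass
class CoherenceReport:
    table: pd.DataFrame            # per DMR: verdict, reasons, logFC range
    alpha: float
    seed: int | None = None

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["verdict"] == "selected"])

    @property
    def excluded(self) -> list[str]:
        return list(self.table.index[self.table["verdict"] == "excluded"])


def coherence_select(full_tests: pd.DataFrame, subset_stats: SubsetStats,
                     candidates: list[DMR], alpha: float = 0.05,
                     require_full_data_sign: bool = True,
                     seed: int | None = None) -> CoherenceReport:
    """Classify every candidate DMR as selected or excluded.

    Selected iff every member window has p <= alpha in every subset and the
    logFC sign is identical across all subsets (and, by default, matches the
    full-data sign). The per-DMR logFC range spans all member windows x
    subsets.
    """
    p_mat = subset_stats.pivot("p")
    fc_mat = subset_stats.pivot("logFC")
    rows = []
    for d in candidates:
        missing = [w for w in d.window_ids if w not in p_mat.index]
        if missing:
            raise ValueError(f"missing subset statistics for windows {missing}")
        p_sub = p_mat.loc[d.window_ids]
        fc_sub = fc_mat.loc[d.window_ids]
        if p_sub.isna().any().any() or fc_sub.isna().any().any():
            raise ValueError(f"missing statistics cell for DMR {d.name}")
        reasons = []
        bad_p = p_sub > alpha
        if bad_p.any().any():
            for wid, row in bad_p.iterrows():
                for s in row.index[row]:
                    reasons.append(f"p>{alpha} (window {wid}, subset {s})")
        signs = np.sign(fc_sub.to_numpy())
        coherent = np.all(signs == signs[0, 0]) and signs[0, 0] != 0
        if not coherent:
            reasons.append("incoherent direction")
        elif require_full_data_sign:
            full_sign = np.sign(full_tests.loc[d.window_ids, "logFC"].to_numpy())
            if not np.all(full_sign == signs[0, 0]):
                reasons.append("direction disagrees with full data")
        rows.append({
            "dmr": d.name,
            "verdict": "excluded" if reasons else "selected",
            "reasons": "; ".join(reasons),
            "logFC_min": float(fc_sub.to_numpy().min()),
            "logFC_max": float(fc_sub.to_numpy().max()),
            "full_mean_logFC": d.mean_logfc,
        })
    table = pd.DataFrame(rows).set_index("dmr")
    return CoherenceReport(table=table, alpha=alpha, seed=seed)
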