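"""Per-window differential-methylation testing and DMR calling.

Each retained window's counts are modelled with a negative-binomial GLM
(log link, offset = log effective library size) with age class and rank
class as fixed effects. Rank is tested with a 1-df likelihood-ratio test
of the full model against the age-only model; p-values are adjusted
genome-wide with the Benjamini-Hochberg step-up procedure, and maximal runs
of adjacent significant windows sharing one effect direction are merged
into differentially methylated regions (DMRs).

Sign convention: the rank coefficient is the effect of being low-ranking
(reference level high), so logFC > 0 means hypermethylated in low-ranking
animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from . import glm
from .counts import CountMatrix, WindowGrid, effective_lib_sizes, parse_window_id

LOG2E = np.log2(np.e)


@dataclass(frozen=True)
class DesignSpec:
    """Factor coding for the window models: intercept + indicator for cubs
    (reference: adult) + indicator for low rank (reference: high). The
    reduced design drops the rank column."""

    age_column: str = "age_class"
    rank_column: str = "rank_class"
    include_age: bool = True

    def matrices(self, samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
        """Return (X_full, X_reduced, rank_coef_index) for the sample table."""
        n = len(samples)
        cols = [np.ones(n)]
        if self.include_age:
            age = samples[self.age_column].to_numpy()
            if not set(age) <= {"cub", "adult"}:
                raise ValueError("age_class must be 'cub' or 'adult'")
            cols.append((age == "cub").astype(float))
        rank = samples[self.rank_column].to_numpy()
        if not set(rank) <= {"high", "low"}:
            raise ValueError("rank_class must be 'high' or 'low'")
        cols.append((rank == "low").astype(float))
        X_full = np.column_stack(cols)
        X_red = X_full[:, :-1]
        if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            raise ValueError("design matrix is not full rank for these samples")
        return X_full, X_red, X_full.shape[1] - 1


@dataclass
class DispersionEstimates:
    common: float
    tagwise: pd.Series
    prior_df: float


@dataclass
class WindowFits:
    """Full and reduced NB fits for every window, on a shared design."""

    window_ids: list[str]
    logfc: np.ndarray          # base-2, rank (low vs high) coefficient
    deviance_full: np.ndarray
    deviance_reduced: np.ndarray
    converged: np.ndarray      # both fits converged
    dispersions: np.ndarray


@dataclass
class DMR:
    contig: str
    start: int
    end: int
    window_ids: list[str]
    direction: str             # 'hyper' or 'hypo' in low-ranking
    mean_logfc: float
    min_q: float

    @property
    def n_windows(self) -> int:
        return len(self.window_ids)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


_PHI_FLOOR = 1e-6


def _offsets(counts: CountMatrix, factors: pd.Series) -> np.ndarray:
    eff = effective_lib_sizes(counts, factors).to_numpy(dtype=float)
    if not np.all(np.isfinite(np.log(eff))):
        raise ValueError("non-finite offsets: check library sizes and factors")
    return np.log(eff)


def estimate_dispersions(counts: CountMatrix, design: DesignSpec,
                         factors: pd.Series, samples: pd.DataFrame,
                         prior_df: float = 10.0,
                         grid_span: float = 8.0, grid_points: int = 15
                         ) -> DispersionEstimates:
    """Empirical-Bayes dispersion estimation.

    The common dispersion maximizes the mean Cox-Reid adjusted profile
    likelihood (APL) over windows. Tagwise dispersions maximize the weighted
    likelihood APL_w(phi) + prior_df * mean-APL(phi), evaluated on a
    log-spaced grid around the common value with quadratic interpolation at
    the maximum: the shared likelihood enters with the weight of
    ``prior_df`` windows, so each window's estimate shrinks toward the
    common value and escapes it only on strong evidence.
    """
    if prior_df <= 0:
        raise ValueError("prior_df must be positive")
    y = counts.counts.to_numpy(dtype=float)
    X, _, _ = design.matrices(samples.loc[counts.samples])
    off = _offsets(counts, factors)
    df_resid = y.shape[1] - X.shape[1]
    if df_resid < 2:
        raise ValueError("need at least 2 residual degrees of freedom")

    def neg_mean_apl(log_phi: float) -> float:
        return -float(np.mean(glm.cox_reid_apl(y, X, off, np.exp(log_phi))))

    res = minimize_scalar(neg_mean_apl, bounds=(np.log(_PHI_FLOOR), np.log(10.0)),
                          method="bounded", options={"xatol": 1e-3})
    common = float(np.exp(res.x))
    if common <= _PHI_FLOOR * 1.5:
        common_report = 0.0
    else:
        common_report = common

    # grid around the common value
    centre = max(common, 1e-3)
    grid = centre * 2.0 ** np.linspace(-grid_span / 2, grid_span / 2, grid_points)
    apl = np.column_stack([glm.cox_reid_apl(y, X, off, g) for g in grid])
    score = apl + prior_df * apl.mean(axis=0)[None, :]

    k = np.argmax(score, axis=1)
    log_grid = np.log(grid)
    tag = log_grid[k].copy()
    interior = (k > 0) & (k < grid_points - 1)
    if np.any(interior):
        ki = k[interior]
        rows = np.flatnonzero(interior)
        s_m = score[rows, ki - 1]
        s_0 = score[rows, ki]
        s_p = score[rows, ki + 1]
        denom = s_m - 2 * s_0 + s_p
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (s_m - s_p) / denom, 0.0)
        step = log_grid[1] - log_grid[0]
        tag[interior] = log_grid[ki] + np.clip(shift, -1, 1) * step
    tagwise = pd.Series(np.exp(tag), index=counts.window_ids, name="dispersion")
    tagwise = tagwise.where(tagwise > _PHI_FLOOR * 1.5, 0.0)
    return DispersionEstimates(common=common_report, tagwise=tagwise,
                               prior_df=prior_df)


def fit_window_models(counts: CountMatrix, design: DesignSpec,
                      factors: pd.Series, dispersions: DispersionEstimates,
                      samples: pd.DataFrame) -> WindowFits:
    """IRLS fits of the full (age + rank) and reduced (age-only) NB GLMs for
    every window, at the tagwise dispersions."""
    y = counts.counts.to_numpy(dtype=float)
    X_full, X_red, rank_ix = design.matrices(samples.loc[counts.samples])
    off = _offsets(counts, factors)
    phi = dispersions.tagwise.reindex(counts.window_ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(phi)):
        raise ValueError("tagwise dispersion missing for some windows")
    beta_f, _, dev_f, conv_f = glm.irls_fit(y, X_full, off, phi)
    _, _, dev_r, conv_r = glm.irls_fit(y, X_red, off, phi)
    return WindowFits(
        window_ids=counts.window_ids,
        logfc=beta_f[:, rank_ix] * LOG2E,
        deviance_full=dev_f,
        deviance_reduced=dev_r,
        converged=conv_f & conv_r,
        dispersions=phi,
    )


def lrt_rank(fits: WindowFits, neg_tol: float = 1e-4) -> pd.DataFrame:
    """1-df likelihood-ratio test of the rank effect per window.

    Returns a DataFrame indexed by window id with columns logFC, lr_stat, p.
    Windows whose fits did not converge carry NaN p.
    """
    lr = fits.deviance_reduced - fits.deviance_full
    if np.any(lr < -neg_tol):
        worst = float(np.min(lr))
        raise ValueError(f"negative LR statistic ({worst:.3g}): "
                         "full/reduced fit inconsistency")
    lr = np.maximum(lr, 0.0)
    p = chi2.sf(lr, df=1)
    p = np.where(fits.converged, p, np.nan)
    return pd.DataFrame({"logFC": fits.logfc, "lr_stat": lr, "p": p},
                        index=pd.Index(fits.window_ids, name="window"))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1.
    NaN entries propagate as NaN and do not enter the adjustment."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if np.any(ok):
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def add_q(tests: pd.DataFrame) -> pd.DataFrame:
    out = tests.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def call_dmrs(tests: pd.DataFrame, grid: WindowGrid,
              q_threshold: float = 0.05) -> list[DMR]:
    """Merge grid-adjacent significant windows sharing one effect direction.

    ``tests`` must contain columns logFC and q, indexed by window id on the
    grid. A window is significant if q <= q_threshold; adjacency means
    consecutive grid windows on the same contig (a filtered-out window in
    between breaks a run); windows with logFC exactly 0 join neither
    direction. Output sorted by (contig, start).
    """
    idx = grid.index_of()
    sig = tests[(tests["q"] <= q_threshold) & (tests["logFC"] != 0)
                & tests["q"].notna()]
    if sig.empty:
        return []
    rows = []
    for wid, row in sig.iterrows():
        contig, start, end = parse_window_id(wid)
        if wid not in idx:
            raise ValueError(f"window {wid!r} not on the supplied grid")
        rows.append((contig, start, end, idx[wid], wid,
                     float(row["logFC"]), float(row["q"])))
    rows.sort(key=lambda r: r[3])
    dmrs: list[DMR] = []
    run: list[tuple] = []

    def flush(run):
        if not run:
            return
        logfcs = [r[5] for r in run]
        dmrs.append(DMR(
            contig=run[0][0], start=run[0][1], end=run[-1][2],
            window_ids=[r[4] for r in run],
            direction="hyper" if logfcs[0] > 0 else "hypo",
            mean_logfc=float(np.mean(logfcs)),
            min_q=float(min(r[6] for r in run)),
        ))

    for r in rows:
        if run and r[0] == run[-1][0] and r[3] == run[-1][3] + 1 \
                and (r[5] > 0) == (run[-1][5] > 0):
            run.append(r)
        else:
            flush(run)
            run = [r]
    flush(run)
    dmrs.sort(key=lambda d: (d.contig, d.start))
    return dmrs


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": d.name, "contig": d.contig, "start": d.start, "end": d.end,
        "n_windows": d.n_windows, "length": d.length, "direction": d.direction,
        "mean_logFC": d.mean_logfc, "min_q": d.min_q,
        "window_ids": ",".join(d.window_ids),
    } for d in dmrs])


def write_dmr_bed(dmrs: list[DMR], path: str) -> None:
    """BED6: name = direction, score = -10*log10(min_q) capped at 1000."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = min(1000, int(round(-10 * np.log10(max(d.min_q, 1e-100)))))
            fh.write(f"{d.contig}\t{d.start}\t{d.end}\t{d.direction}\t{score}\t.\n")


def run_methylation_analysis(counts: CountMatrix, samples: pd.DataFrame,
                             grid: WindowGrid | None = None,
                             design: DesignSpec = DesignSpec(),
                             fdr: float = 0.05, prior_df: float = 10.0,
                             factors: pd.Series | None = None):
    """Full window-level analysis: TMM -> dispersions -> fits -> LRT -> BH
    -> (optionally) DMR calling.

    Returns (tests DataFrame with q, dmrs list or None, factors,
    dispersions).
    """
    from .counts import tmm_factors
    if factors is None:
        factors = tmm_factors(counts)
    disp = estimate_dispersions(counts, design, factors, samples,
                                prior_df=prior_df)
    fits = fit_window_models(counts, design, factors, disp, samples)
    tests = add_q(lrt_rank(fits))
    dmrs = call_dmrs(tests, grid, q_threshold=fdr) if grid is not None else None
    return tests, dmrs, factors, disp
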