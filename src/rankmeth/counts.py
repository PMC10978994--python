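"""Window grids, count matrices, filtering and TMM normalization.

The substrate of the pipeline is a window x sample matrix of methylation-
capture read counts: more reads over a window means more methylated DNA
captured there. Between-sample normalization uses the trimmed mean of
M-values (TMM), which estimates a composition-bias factor per sample from
trimmed, precision-weighted log-ratios against a reference sample, so that
fold-changes between samples are minimized for the bulk of windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

_WINDOW_RE = re.compile(r"^(.+):(\d+)-(\d+)$")


def window_id(contig: str, start: int, end: int) -> str:
    return f"{contig}:{start}-{end}"


def parse_window_id(wid: str) -> tuple[str, int, int]:
    m = _WINDOW_RE.match(wid)
    if not m:
        raise ValueError(f"malformed window id {wid!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


@dataclass
class WindowGrid:
    """Complete fixed-width tiling of a set of contigs.

    Windows are 0-based half-open, consecutive within a contig starting at 0;
    the terminal window of a contig may be shorter than ``window_width``.
    """

    windows: list[tuple[str, int, int]]
    window_width: int

    @property
    def ids(self) -> list[str]:
        return [window_id(*w) for w in self.windows]

    def __len__(self) -> int:
        return len(self.windows)

    def index_of(self) -> dict[str, int]:
        return {window_id(*w): i for i, w in enumerate(self.windows)}

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.windows:
                fh.write(f"{c}\t{s}\t{e}\n")


def tile_windows(contigs: list[tuple[str, int]], width: int) -> WindowGrid:
    """Tile each contig into consecutive windows of ``width`` bp.

    The last window is truncated at the contig end (and kept), so window
    lengths sum exactly to the contig length.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    windows = []
    for name, length in contigs:
        if length <= 0:
            raise ValueError(f"contig {name!r} must have positive length")
        for start in range(0, length, width):
            windows.append((name, start, min(start + width, length)))
    return WindowGrid(windows=windows, window_width=width)


@dataclass
class CountMatrix:
    """Window (or gene) x sample integer counts with per-sample library sizes.

    ``lib_sizes`` are the column totals recorded at construction, before any
    filtering, and are preserved thereafter: filtering windows must not
    redefine sequencing depth.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series = field(default=None)

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if arr.size and (np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(np.int64)
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
        if self.lib_sizes.isna().any():
            raise ValueError("lib_sizes missing for some samples")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def window_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)],
                           self.lib_sizes.loc[list(sample_ids)])

    def subset_windows(self, window_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(window_ids)], self.lib_sizes)

    def write_tsv(self, path: str) -> None:
        out = self.counts.copy()
        out.index.name = "window"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str, lib_sizes: pd.Series | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(np.int64), lib_sizes)


@dataclass(frozen=True)
class FilterSpec:
    """Low-information window filter: keep windows with at least
    ``min_total_reads`` summed over samples and at least
    ``min_positive_samples`` samples with a positive count (both inclusive).
    """

    min_total_reads: int = 10
    min_positive_samples: int = 10

    def __post_init__(self):
        if self.min_total_reads < 0 or self.min_positive_samples < 0:
            raise ValueError("filter thresholds must be >= 0")


def filter_windows(counts: CountMatrix, spec: FilterSpec = FilterSpec()) -> CountMatrix:
    total = counts.counts.sum(axis=1)
    npos = (counts.counts > 0).sum(axis=1)
    keep = (total >= spec.min_total_reads) & (npos >= spec.min_positive_samples)
    return CountMatrix(counts.counts.loc[keep], counts.lib_sizes)


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    # per-sample p-quantile of counts scaled by library size (R type-7 quantile)
    return np.quantile(counts, p, axis=0, method="linear") / lib


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Trimmed, precision-weighted mean of M-values for one sample against the
    reference; returns the scaling factor 2^(weighted mean M)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))            # M
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2  # A
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rr = rankdata(log_r)
    ra = rankdata(abs_e)
    keep = (rr >= lo_l) & (rr <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not np.any(keep):
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: CountMatrix, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> pd.Series:
    """TMM normalization factors, geometric-mean centred to product 1.

    Reference sample: the one whose library-size-scaled 75th percentile is
    closest to the mean of those percentiles. For each other sample, M-values
    (log2 ratio of depth-scaled proportions) are trimmed 30% two-sided, the
    A-values 5%, and the retained M averaged with inverse delta-method
    variance weights.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    col_pos = (mat > 0).any(axis=0)
    if not col_pos.all():
        bad = [s for s, ok in zip(counts.samples, col_pos) if not ok]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    mat = mat[mat.sum(axis=1) > 0]  # drop all-zero windows
    lib = counts.lib_sizes.to_numpy(dtype=float)
    f75 = _quantile_factor(mat, lib)
    if np.median(f75) < 1e-20:
        ref_idx = int(np.argmax(np.sqrt(mat).sum(axis=0)))
    else:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = mat[:, ref_idx]
    n_ref = lib[ref_idx]
    factors = np.array([
        1.0 if j == ref_idx else
        _tmm_pair(mat[:, j], ref, lib[j], n_ref, logratio_trim, sum_trim)
        for j in range(mat.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="tmm_factor")


def effective_lib_sizes(counts: CountMatrix, factors: pd.Series) -> pd.Series:
    missing = [s for s in counts.samples if s not in factors.index]
    if missing:
        raise ValueError(f"normalization factor missing for sample(s): {missing}")
    return counts.lib_sizes * factors.loc[counts.samples]


def cpm(counts: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts per million of effective (TMM-adjusted) library size:
    CPM_wi = Y_wi / (L_i f_i) * 1e6. No pseudo-count is added."""
    eff = effective_lib_sizes(counts, factors)
    return counts.counts / eff.to_numpy() * 1e6


def mean_methylation_per_sample(counts: CountMatrix, factors: pd.Series) -> pd.Series:
    """Per-sample normalized library size used as the 'mean DNA methylation'
    covariate: the sum of counts over all windows divided by the sample's
    normalization factor."""
    missing = [s for s in counts.samples if s not in factors.index]
    if missing:
        raise ValueError(f"normalization factor missing for sample(s): {missing}")
    return counts.counts.sum(axis=0) / factors.loc[counts.samples]
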