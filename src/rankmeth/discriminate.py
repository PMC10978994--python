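"""Discriminative power of DMR methylation via random-forest oob error.

Four covariate sets mirror the classifiers of interest: all candidate
DMRs, the coherence-selected ones, the excluded ones, and the single
per-sample mean-methylation value; each model also receives the age class.
Out-of-bag (oob) error — the misclassification rate of samples judged only
by trees whose bootstrap bags excluded them — is the proxy for
discriminative power. A matched-size random-location control samples
pseudo-DMRs uniformly from the window pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .counts import (CountMatrix, effective_lib_sizes,
                     mean_methylation_per_sample, parse_window_id)
from .diffmeth import DMR


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 2000
    n_repetitions: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.n_repetitions < 1:
            raise ValueError("n_trees and n_repetitions must be >= 1")


@dataclass
class RFReport:
    label: str
    errors: np.ndarray  # one oob error per repetition

    @property
    def error_range(self) -> tuple[float, float]:
        return float(self.errors.min()), float(self.errors.max())

    @property
    def mean_error(self) -> float:
        return float(self.errors.mean())

    def summary(self) -> dict:
        lo, hi = self.error_range
        return {"variable_set": self.label, "oob_min": lo, "oob_max": hi,
                "oob_mean": self.mean_error,
                "n_repetitions": int(self.errors.size)}


def build_feature_table(counts: CountMatrix, factors: pd.Series,
                        dmrs: list[DMR] | str, samples: pd.DataFrame,
                        per_window: bool = False) -> pd.DataFrame:
    """Per-sample feature table: age indicator + one CPM column per DMR
    (counts summed over the DMR's member windows, then CPM-scaled), or a
    single mean-methylation column when ``dmrs == "mean"``. With
    ``per_window`` each member window contributes its own CPM column
    instead of the summed aggregate. The rank label is attached as column
    ``rank_class``."""
    feats = pd.DataFrame(index=counts.samples)
    feats["age_cub"] = (samples.loc[counts.samples, "age_class"] == "cub"
                        ).astype(float)
    if isinstance(dmrs, str):
        if dmrs != "mean":
            raise ValueError("dmrs must be a DMR list or the string 'mean'")
        feats["mean_methylation"] = mean_methylation_per_sample(counts, factors)
    else:
        if not dmrs:
            raise ValueError("empty DMR list")
        eff = effective_lib_sizes(counts, factors)
        for d in dmrs:
            if per_window:
                for w in d.window_ids:
                    feats[w] = counts.counts.loc[w] / eff * 1e6
            else:
                summed = counts.counts.loc[d.window_ids].sum(axis=0)
                feats[d.name] = summed / eff * 1e6
    feats["rank_class"] = samples.loc[counts.samples, "rank_class"]
    if feats.drop(columns="rank_class").isna().any().any():
        raise ValueError("feature table contains missing values")
    return feats


def oob_error_range(table: pd.DataFrame, config: RFConfig) -> RFReport:
    """Repeatedly grow a forest on bootstrap bags and record the oob error,
    one error per repetition; each repetition uses a fresh RNG stream
    derived from (seed, repetition index)."""
    y = table["rank_class"].to_numpy()
    classes, counts_per = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts_per.min() < 2:
        raise ValueError("need at least 2 samples in each class")
    X = table.drop(columns="rank_class").to_numpy(dtype=float)
    errors = np.empty(config.n_repetitions)
    for rep in range(config.n_repetitions):
        rs = np.random.default_rng([int(config.seed), rep]).integers(2**31 - 1)
        rf = RandomForestClassifier(
            n_estimators=config.n_trees, max_features="sqrt",
            bootstrap=True, oob_score=True, random_state=int(rs), n_jobs=1)
        rf.fit(X, y)
        errors[rep] = 1.0 - rf.oob_score_
    return RFReport(label="", errors=errors)


def rf_report(table: pd.DataFrame, config: RFConfig, label: str) -> RFReport:
    rep = oob_error_range(table, config)
    rep.label = label
    return rep


def random_location_control(counts: CountMatrix, factors: pd.Series,
                            samples: pd.DataFrame, sizes: list[int],
                            config: RFConfig,
                            exclude_windows: list[str] | None = None
                            ) -> list[RFReport]:
    """For each requested feature count, draw that many windows uniformly
    without replacement as single-window pseudo-DMRs and compute the oob
    report. ``exclude_windows`` removes e.g. truly planted windows from the
    pool."""
    pool = [w for w in counts.window_ids
            if not exclude_windows or w not in set(exclude_windows)]
    rng = np.random.default_rng([int(config.seed), 13])
    out = []
    for s_ix, size in enumerate(sizes):
        if size > len(pool):
            raise ValueError(f"requested {size} windows but pool has {len(pool)}")
        chosen = list(rng.choice(pool, size=size, replace=False))
        pseudo = [DMR(*parse_window_id(w), window_ids=[w], direction="hyper",
                      mean_logfc=0.0, min_q=1.0) for w in chosen]
        table = build_feature_table(counts, factors, pseudo, samples)
        rep = oob_error_range(table, RFConfig(config.n_trees,
                                              config.n_repetitions,
                                              seed=config.seed + 1000 + s_ix))
        rep.label = f"control_{size}"
        out.append(rep)
    return out


def chance_band(labels: pd.Series | np.ndarray, k_se: float = 3.0
                ) -> tuple[float, float]:
    """Chance-level oob band from the class proportions: the error rate of a
    label-independent classifier voting by class frequency, 2p(1-p) for two
    classes, +/- k_se binomial standard errors at the cohort size.

    This baseline, rather than the majority-class error, brackets the oob
    behavior of forests grown on pure-noise features: with unbalanced
    classes each out-of-bag sample's bags underrepresent its own class, so
    noise predictions land near (and slightly above) proportional guessing.
    """
    y = np.asarray(labels)
    n = y.size
    _, counts_per = np.unique(y, return_counts=True)
    props = counts_per / n
    p0 = 1.0 - float(np.sum(props**2))
    se = np.sqrt(p0 * (1 - p0) / n)
    return max(0.0, p0 - k_se * se), min(1.0, p0 + k_se * se)
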