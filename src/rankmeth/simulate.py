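"""Synthetic cohorts, genomes and count matrices with planted DMRs.

The generator emulates capture-based (MBD-Seq) methylation count data for a
two-factor cohort of rank class {high, low} x age class {cub, adult}. Window
counts are negative-binomial with mean

    mu_wi = lambda_w * (L_i / 1e6) * 2^(beta_w [rank_i = low] + gamma_w [age_i = cub])

and variance mu + phi mu^2, where lambda_w is a per-window baseline capture
propensity (log-normal, fixed across samples), L_i a per-sample library-size
target (log-uniform, fixed), beta_w the planted rank effect (nonzero only in
planted DMR windows; positive = hypermethylated in low-ranking) and gamma_w
an optional window-specific age effect. Windows on a mitochondrial contig
get lambda_w scaled by ``mito_multiplier``, emulating the elevated abundance
of mitochondrial DNA and RNA.

Each output matrix uses its own PRNG stream derived from (seed, role
offset), so adding the expression simulation never perturbs the methylation
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountMatrix, WindowGrid, tile_windows
from .genome import Contig, Gene, GeneModelSet

RANKS = ("high", "low")
AGES = ("cub", "adult")

_ROLE_COHORT = 1
_ROLE_GENOME = 2
_ROLE_METH = 3
_ROLE_EXPR = 4

DEFAULT_CELLS = {("high", "cub"): 9, ("high", "adult"): 9,
                 ("low", "cub"): 15, ("low", "adult"): 9}


@dataclass(frozen=True)
class PlantedDMR:
    """A contiguous run of windows carrying a rank effect."""

    contig: str
    first_window_index: int
    n_windows: int
    log2_effect: float

    def __post_init__(self):
        if self.n_windows < 1:
            raise ValueError("planted DMR needs at least one window")
        if self.log2_effect == 0:
            raise ValueError("planted DMR effect must be nonzero")


@dataclass
class SimConfig:
    seed: int = 0
    n_per_cell: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    contigs: list[tuple[str, int, bool]] = field(
        default_factory=lambda: [("chr1", 600_000, False), ("chrM", 17_000, True)])
    window_width: int = 300
    baseline_log2_abundance: tuple[float, float] = (5.0, 1.0)  # mean, sd
    dispersion: float = 0.2
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    age_log2_effect_sd: float = 0.0
    mito_multiplier: float = 8.0

    def __post_init__(self):
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if any(l <= 0 for _, l, _ in self.contigs):
            raise ValueError("contig lengths must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.libsize_range
        if lo > hi or lo <= 0:
            raise ValueError("libsize_range must satisfy 0 < min <= max")
        if self.mito_multiplier <= 0:
            raise ValueError("mito_multiplier must be positive")
        self._check_planted()

    def _check_planted(self):
        grid = self.window_grid()
        n_per_contig: dict[str, int] = {}
        for c, _, _ in grid.windows:
            n_per_contig[c] = n_per_contig.get(c, 0) + 1
        seen: dict[str, list[tuple[int, int]]] = {}
        for d in self.planted_dmrs:
            if d.contig not in n_per_contig:
                raise ValueError(f"planted DMR on unknown contig {d.contig!r}")
            if d.first_window_index < 0 or \
                    d.first_window_index + d.n_windows > n_per_contig[d.contig]:
                raise ValueError(f"planted DMR out of contig bounds: {d}")
            span = (d.first_window_index, d.first_window_index + d.n_windows)
            for a, b in seen.setdefault(d.contig, []):
                if span[0] < b and a < span[1]:
                    raise ValueError("planted DMRs overlap")
            seen[d.contig].append(span)

    def window_grid(self) -> WindowGrid:
        return tile_windows([(n, l) for n, l, _ in self.contigs],
                            self.window_width)

    def rng(self, role: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), role])


@dataclass
class SimTruth:
    """Machine-readable ledger of the planted signal."""

    dmrs: pd.DataFrame           # contig, start, end, n_windows, log2_effect
    window_effects: pd.Series    # per grid window, 0 where nothing planted

    def write(self, bed_path: str, json_path: str) -> None:
        with open(bed_path, "w") as fh:
            for _, r in self.dmrs.iterrows():
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\tplanted\n")
        self.dmrs.to_json(json_path, orient="records", indent=2)


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """One sample row per configured rank x age slot, ids h01.., l01.. by
    rank. Deterministic given the config."""
    for (rank, age), n in config.n_per_cell.items():
        if rank not in RANKS or age not in AGES:
            raise ValueError(f"unknown cell {(rank, age)}")
        if n < 1:
            raise ValueError(f"cell {(rank, age)} must have at least one sample "
                             "(both factor levels are required downstream)")
    for rank in RANKS:
        if not any(r == rank for r, _ in config.n_per_cell):
            raise ValueError(f"rank level {rank!r} absent from design")
    for age in AGES:
        if not any(a == age for _, a in config.n_per_cell):
            raise ValueError(f"age level {age!r} absent from design")
    rows = []
    counter = {"high": 0, "low": 0}
    for rank in RANKS:
        for age in AGES:
            for _ in range(config.n_per_cell.get((rank, age), 0)):
                counter[rank] += 1
                rows.append({"sample_id": f"{rank[0]}{counter[rank]:02d}",
                             "rank_class": rank, "age_class": age})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_gene_model(config: SimConfig, genes_per_contig: int = 8,
                        exons_per_gene: int = 3) -> GeneModelSet:
    """A simple synthetic gene model: equally spaced genes per contig, each
    with ``exons_per_gene`` exons, alternating strand. Mitochondrial contigs
    inherit their flag from the config."""
    rng = config.rng(_ROLE_GENOME)
    contigs = [Contig(n, l, m) for n, l, m in config.contigs]
    genes = []
    for c in contigs:
        slot = c.length // genes_per_contig
        for i in range(genes_per_contig):
            g_start = i * slot + slot // 10
            g_len = max(6 * exons_per_gene, int(slot * 0.6))
            g_end = min(g_start + g_len, c.length)
            exon_len = max(2, (g_end - g_start) // (2 * exons_per_gene))
            exons = []
            pos = g_start
            for _ in range(exons_per_gene):
                exons.append((pos, min(pos + exon_len, g_end)))
                pos += 2 * exon_len
                if pos >= g_end:
                    break
            strand = "+" if (i + rng.integers(0, 2)) % 2 == 0 else "-"
            genes.append(Gene(gene_id=f"{c.name}_g{i + 1}", contig=c.name,
                              start=g_start, end=g_end, strand=strand,
                              exons=exons))
    return GeneModelSet(contigs=contigs, genes=genes)


def _draw_libsizes(config: SimConfig, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.libsize_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def _window_effect_vectors(config: SimConfig, grid: WindowGrid):
    """Per-window rank (beta) and age (gamma) log2 effects on the grid."""
    idx = {}
    per_contig_offset: dict[str, int] = {}
    for i, (c, _, _) in enumerate(grid.windows):
        per_contig_offset.setdefault(c, i)
    beta = np.zeros(len(grid))
    for d in config.planted_dmrs:
        base = per_contig_offset[d.contig] + d.first_window_index
        beta[base:base + d.n_windows] = d.log2_effect
    return beta


def simulate_methylation_counts(config: SimConfig, genome: GeneModelSet | None,
                                samples: pd.DataFrame
                                ) -> tuple[CountMatrix, SimTruth]:
    """NB window counts over the config's window grid with planted rank
    effects; returns the matrix and the truth ledger."""
    grid = config.window_grid()
    rng = config.rng(_ROLE_METH)
    mito = {n for n, _, m in config.contigs if m}
    if genome is not None:
        mito |= genome.mitochondrial_contigs
    n = len(samples)
    mean_l2, sd_l2 = config.baseline_log2_abundance
    lam = 2.0 ** rng.normal(mean_l2, sd_l2, size=len(grid))
    is_mito = np.array([c in mito for c, _, _ in grid.windows])
    lam = lam * np.where(is_mito, config.mito_multiplier, 1.0)
    # terminal truncated windows capture proportionally less
    widths = np.array([e - s for _, s, e in grid.windows], dtype=float)
    lam = lam * widths / config.window_width

    beta = _window_effect_vectors(config, grid)
    if config.age_log2_effect_sd > 0:
        gamma = rng.normal(0.0, config.age_log2_effect_sd, size=len(grid))
    else:
        gamma = np.zeros(len(grid))

    lib = _draw_libsizes(config, n, rng)
    low = (samples["rank_class"].to_numpy() == "low").astype(float)
    cub = (samples["age_class"].to_numpy() == "cub").astype(float)
    mu = (lam[:, None] * (lib[None, :] / 1e6)
          * 2.0 ** (beta[:, None] * low[None, :] + gamma[:, None] * cub[None, :]))
    counts = _nb_draw(rng, mu, config.dispersion)
    mat = pd.DataFrame(counts, index=grid.ids, columns=samples.index)
    cm = CountMatrix(mat)

    rows = []
    for d in config.planted_dmrs:
        contig_windows = [(s, e) for c, s, e in grid.windows if c == d.contig]
        start = contig_windows[d.first_window_index][0]
        end = contig_windows[d.first_window_index + d.n_windows - 1][1]
        rows.append({"contig": d.contig, "start": start, "end": end,
                     "n_windows": d.n_windows, "log2_effect": d.log2_effect})
    truth = SimTruth(
        dmrs=pd.DataFrame(rows, columns=["contig", "start", "end",
                                         "n_windows", "log2_effect"]),
        window_effects=pd.Series(beta, index=grid.ids, name="log2_effect"),
    )
    return cm, truth


def simulate_expression_counts(config: SimConfig, genome: GeneModelSet,
                               samples: pd.DataFrame) -> CountMatrix:
    """NB expression counts, one row per gene; the gene's region is its exon
    union (region length = summed exon length). Per-gene abundance lambda is
    drawn independently of transcript length; mitochondrial genes share the
    config's mito_multiplier."""
    if not genome.genes:
        raise ValueError("gene model contains no genes")
    rng = config.rng(_ROLE_EXPR)
    n = len(samples)
    mean_l2, sd_l2 = config.baseline_log2_abundance
    lam = 2.0 ** rng.normal(mean_l2, sd_l2, size=len(genome.genes))
    mult = np.array([config.mito_multiplier if genome.is_mitochondrial_gene(g)
                     else 1.0 for g in genome.genes])
    lam = lam * mult
    lib = _draw_libsizes(config, n, rng)
    mu = lam[:, None] * (lib[None, :] / 1e6)
    counts = _nb_draw(rng, mu, config.dispersion)
    mat = pd.DataFrame(counts, index=[g.gene_id for g in genome.genes],
                       columns=samples.index)
    return CountMatrix(mat)


def plant_random_dmrs(config_contigs: list[tuple[str, int, bool]],
                      window_width: int, n_dmrs: int,
                      windows_per_dmr: int | list[int],
                      log2_effect: float, seed: int,
                      exclude_mito: bool = True,
                      balanced_directions: bool = True) -> list[PlantedDMR]:
    """Place ``n_dmrs`` non-overlapping, non-adjacent planted DMRs of
    ``windows_per_dmr`` windows each, uniformly over the nuclear contigs.

    With ``balanced_directions`` (default) the effect sign alternates
    between DMRs, emulating a mixture of hyper- and hypomethylated regions
    that leaves overall library composition rank-neutral — the regime the
    trimmed-mean normalization assumes. Set False to plant one-sided
    effects. ``windows_per_dmr`` may be a list of sizes, cycled through.
    """
    sizes = ([windows_per_dmr] if isinstance(windows_per_dmr, int)
             else list(windows_per_dmr))
    rng = np.random.default_rng([int(seed), 97])
    pool = []
    for name, length, mito in config_contigs:
        if exclude_mito and mito:
            continue
        n_windows = -(-length // window_width)
        pool.append((name, n_windows))
    if not pool:
        raise ValueError("no eligible contigs to plant on")
    placed: dict[str, list[tuple[int, int]]] = {}
    out = []
    tries = 0
    while len(out) < n_dmrs:
        tries += 1
        if tries > 100_000:
            raise RuntimeError("could not place the requested planted DMRs")
        size = sizes[len(out) % len(sizes)]
        name, n_windows = pool[rng.integers(len(pool))]
        if n_windows < size:
            continue
        first = int(rng.integers(0, n_windows - size + 1))
        span = (first - 1, first + size + 1)  # keep a 1-window gap
        if any(span[0] < b and a < span[1] for a, b in placed.get(name, [])):
            continue
        placed.setdefault(name, []).append(span)
        sign = -1.0 if balanced_directions and len(out) % 2 else 1.0
        out.append(PlantedDMR(name, first, size, sign * log2_effect))
    out.sort(key=lambda d: (d.contig, d.first_window_index))
    return out
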