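import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rankmeth as rm
from rankmeth.simulate import plant_random_dmrs

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    return rm.simulate_cohort(rm.SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_pipeline_run():
    """A modest planted-effect simulation run through the full window-level
    analysis once, shared across tests: 2,000 windows x 42 samples, 50
    planted 4-window DMRs at |log2 effect| = 2, NB dispersion 0.2."""
    contigs = [("chr1", 600_000, False)]
    cfg = rm.SimConfig(
        seed=42, contigs=contigs,
        planted_dmrs=plant_random_dmrs(contigs, 300, 50, 4, 2.0, seed=42))
    samples = rm.simulate_cohort(cfg)
    counts, truth = rm.simulate_methylation_counts(cfg, None, samples)
    filtered = rm.filter_windows(counts)
    tests, dmrs, factors, disp = rm.run_methylation_analysis(
        filtered, samples, grid=cfg.window_grid())
    return dict(config=cfg, samples=samples, counts=counts, truth=truth,
                filtered=filtered, tests=tests, dmrs=dmrs, factors=factors,
                dispersions=disp)


@pytest.fixture()
def toy_counts():
    """4 windows x 3 samples with hand-checkable values."""
    mat = pd.DataFrame(
        [[10, 20, 30],
         [5, 10, 15],
         [100, 10, 20],
         [8, 16, 24]],
        index=["c1:0-300", "c1:300-600", "c1:600-900", "c1:900-1200"],
        columns=["s1", "s2", "s3"])
    return rm.CountMatrix(mat)
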