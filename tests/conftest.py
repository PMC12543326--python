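import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from enhancerstate.intervals import GenomicInterval, IntervalSet


def random_intervals(rng, n, chroms=("chrA", "chrB"), max_coord=5000, max_len=300):
    """Small random intervals suitable for the per-base oracles."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_coord))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One shared small simulated experiment for pipeline-level tests."""
    from enhancerstate.simulate import SimulationConfig, simulate_experiment

    cfg = SimulationConfig(
        genome={"chrS1": 2_000_000, "chrS2": 2_000_000},
        n_promoters=40,
        n_poised=40,
        n_active_with_k4me1=40,
        n_active_no_k4me1=40,
        n_differential={m: (12, 12) for m in
                        ("H3K4me3", "H3K27me3", "H3K4me1", "H3K27ac")},
        bivalent_overlap=6,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("small_sim")
    manifest = simulate_experiment(cfg, outdir)
    return cfg, outdir, manifest
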