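"""Shared fixtures: small seeded synthetic datasets and toy genomes."""

import numpy as np
import pytest

from cistrokit.intervals import GenomicInterval, PeakSet
from cistrokit.simulate import SimulationConfig, generate


def small_config(**overrides) -> SimulationConfig:
    """A desk-scale config small enough for per-module tests."""
    kwargs = dict(
        n_chroms=2,
        chrom_length=2_000_000,
        n_shared=30,
        n_a_specific=20,
        n_b_specific=40,
        n_genes=150,
        frac_genes_linked={"shared": 0.1, "A_specific": 0.1, "B_specific": 0.1},
        starr_base_rate=20.0,
        starr_background_fragments=4_000,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_ds():
    """A complete small synthetic bundle (seed 7)."""
    return generate(small_config(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_peakset(rng, n, chrom="chr1", length=10_000, max_width=400, label=""):
    starts = rng.integers(0, length - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return PeakSet(
        (
            GenomicInterval(chrom, int(s), int(s + w))
            for s, w in zip(starts, widths)
        ),
        label=label,
    )


def occupancy(peaks: PeakSet, chrom: str, length: int) -> np.ndarray:
    """Per-base boolean occupancy — the brute-force overlap oracle."""
    occ = np.zeros(length, dtype=bool)
    for iv in peaks:
        if iv.chrom == chrom:
            occ[iv.start: iv.end] = True
    return occ
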