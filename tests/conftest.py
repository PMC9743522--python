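"""Shared fixtures: toy genomes, anchors, and simulated cohorts.

All fixtures are generated programmatically with fixed seeds; nothing
is read from data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import fusion4c as f4c
from fusion4c.genome import GenomicInterval, SVEvent


@pytest.fixture(scope="session")
def toy_reference():
    """Two-chromosome toy genome used across the suite."""
    return [("chr7", 6_000_000), ("chr3", 4_000_000)]


@pytest.fixture(scope="session")
def toy_anchors():
    """BRAF-like anchor partition on the toy chr7 (10 kb aligned)."""
    return f4c.AnchorSet(
        gene="GENE",
        c_terminal=GenomicInterval("chr7", 3_900_000, 3_980_000),
        n_terminal=GenomicInterval("chr7", 3_980_000, 4_120_000),
        background=GenomicInterval("chr7", 3_900_000, 4_120_000),
    )


@pytest.fixture(scope="session")
def centered_anchors():
    """Viewpoint centered on a 10 Mb chromosome (symmetric flanks)."""
    return f4c.AnchorSet(
        gene="GENE",
        c_terminal=GenomicInterval("chr7", 4_900_000, 4_980_000),
        n_terminal=GenomicInterval("chr7", 4_980_000, 5_120_000),
        background=GenomicInterval("chr7", 4_900_000, 5_120_000),
    )


def tandem_dup_event():
    """Canonical-type fusion: duplication joining partner 5' to gene C-term."""
    return SVEvent(
        "tandem_duplication",
        (GenomicInterval("chr7", 2_000_000, 3_980_000),),
        name="dup_fusion",
    )


def insertion_event():
    """TOP2B-like fusion: N-terminal loss replaced by a trans segment."""
    return SVEvent(
        "insertion_translocation",
        (
            GenomicInterval("chr7", 3_980_000, 4_120_000),
            GenomicInterval("chr3", 1_000_000, 1_140_000),
        ),
        name="ins_fusion",
    )


def simulate_cohort(
    reference,
    anchors,
    seed,
    fusion_events=None,
    n_samples=6,
    depth=1_000_000.0,
    coarse_factor=5,
):
    """One cohort of virtual-4C profiles; sample 0 carries the fusion."""
    rng = np.random.default_rng(seed)
    profiles = []
    for s in range(n_samples):
        events = list(fusion_events or []) if s == 0 else []
        cfg = f4c.SimulationConfig(
            bin_size=10_000, depth=depth, seed=int(rng.integers(2**31))
        )
        matrix, _ = f4c.simulate_sample(reference, events, cfg, sample=f"S{s}")
        profiles.append(
            f4c.extract_profile(
                matrix, anchors, coarse_factor=coarse_factor, sample=f"S{s}"
            )
        )
    return profiles


@pytest.fixture(scope="session")
def fusion_cohort(toy_reference, toy_anchors):
    """6-sample cohort, sample 0 with the planted tandem-duplication fusion."""
    return simulate_cohort(
        toy_reference, toy_anchors, seed=11, fusion_events=[tandem_dup_event()]
    )


@pytest.fixture(scope="session")
def small_matrix():
    """A small event-free simulated matrix (single chromosome, 100 bins)."""
    cfg = f4c.SimulationConfig(bin_size=10_000, depth=200_000, seed=3)
    matrix, _ = f4c.simulate_sample([("chr1", 1_000_000)], [], cfg)
    return matrix
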