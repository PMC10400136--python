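from __future__ import annotations

import numpy as np
import pytest

from hrdscar.genome import GenomeModel
from hrdscar.segments import Segment, SegmentedCopyNumberProfile

MB = 1_000_000


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    """Four metacentric chromosomes, 150 Mb each (600 Mb interrogated)."""
    return GenomeModel(
        tuple((f"chr{i}", 75 * MB, 75 * MB) for i in range(1, 5))
    )


@pytest.fixture(scope="session")
def round_genome() -> GenomeModel:
    """Ten 300 Mb chromosomes: a 3000 Mb interrogated genome for clean
    fraction arithmetic."""
    return GenomeModel(
        tuple((f"chr{i}", 150 * MB, 150 * MB) for i in range(1, 11))
    )


def make_profile(genome: GenomeModel, overrides: list[Segment], sample_id="S0"):
    """Tile every arm as diploid-heterozygous except for override segments.

    Overrides must each lie within one arm and not overlap each other.
    """
    segs: list[Segment] = []
    for arm in genome.arms():
        local = sorted(
            (o for o in overrides if o.chrom == arm.chrom
             and arm.start <= o.start < arm.end),
            key=lambda s: s.start,
        )
        cursor = arm.start
        for o in local:
            if o.start > cursor:
                segs.append(Segment(arm.chrom, cursor, o.start, 2, 1))
            segs.append(o)
            cursor = o.end
        if cursor < arm.end:
            segs.append(Segment(arm.chrom, cursor, arm.end, 2, 1))
    return SegmentedCopyNumberProfile(sample_id, segs, genome)


def random_profile(genome: GenomeModel, rng: np.random.Generator,
                   max_breaks_per_arm: int = 4, sample_id="R0"):
    """Random valid profile: random within-arm breakpoints and copy states."""
    states = [(2, 1), (2, 0), (1, 0), (3, 1), (4, 2), (3, 0), (0, 0), (4, 1)]
    segs = []
    for arm in genome.arms():
        k = int(rng.integers(0, max_breaks_per_arm + 1))
        cuts = np.unique(rng.integers(1, arm.length, size=k))
        bounds = [arm.start] + [arm.start + int(c) for c in cuts] + [arm.end]
        for s, e in zip(bounds, bounds[1:]):
            total, minor = states[int(rng.integers(0, len(states)))]
            segs.append(Segment(arm.chrom, s, e, total, minor))
    return SegmentedCopyNumberProfile(sample_id, segs, genome)
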