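"""Allele-specific copy-number segments and segmented profiles.

A profile is an ordered list of segments that tiles every chromosome arm of
its genome model exactly (contiguous, non-overlapping, never crossing an arm
boundary), in 0-based half-open coordinates.  Copy-number states:

* LOH segment: ``minor_cn == 0 and total_cn >= 1``
* deep deletion: ``total_cn == 0``
* allelic imbalance: major != minor, i.e. ``2 * minor_cn != total_cn``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomeModel, default_genome

SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]


class ProfileValidationError(ValueError):
    """A segment list violates sortedness, tiling or copy-number invariants."""


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ProfileValidationError(f"{self} has end <= start")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ProfileValidationError(f"{self} has negative copy number")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ProfileValidationError(
                f"{self}: minor_cn exceeds major allele count"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0 and self.total_cn >= 1

    @property
    def is_deep_deletion(self) -> bool:
        return self.total_cn == 0

    @property
    def is_imbalanced(self) -> bool:
        """Allelic imbalance: the two allele counts differ."""
        return 2 * self.minor_cn != self.total_cn

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.minor_cn)


@dataclass
class SegmentedCopyNumberProfile:
    """Per-sample allele-specific segments on a chromosome-arm genome."""

    sample_id: str
    segments: list[Segment]
    genome: GenomeModel = field(default_factory=default_genome)

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (_chrom_rank(self.genome, s.chrom), s.start)
        )

    def segments_of(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]

    def segment_at(self, chrom: str, pos: int) -> Segment:
        """Segment containing position ``pos`` (0-based)."""
        for s in self.segments:
            if s.chrom == chrom and s.start <= pos < s.end:
                return s
        raise KeyError(f"position {chrom}:{pos} not covered by profile "
                       f"{self.sample_id}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.sample_id, s.chrom, s.start, s.end, s.total_cn, s.minor_cn)
                for s in self.segments
            ],
            columns=SEG_COLUMNS,
        )


def _chrom_rank(genome: GenomeModel, chrom: str) -> int:
    for i, (name, _, _) in enumerate(genome.chromosomes):
        if name == chrom:
            return i
    raise ProfileValidationError(f"chromosome {chrom!r} not in genome model")


def validate_profile(profile: SegmentedCopyNumberProfile) -> SegmentedCopyNumberProfile:
    """Check sortedness, arm tiling and per-segment invariants.

    Returns the profile unchanged if clean; raises
    :class:`ProfileValidationError` naming the first offending segment(s).
    """
    genome = profile.genome
    by_chrom: dict[str, list[Segment]] = {}
    for seg in profile.segments:
        _chrom_rank(genome, seg.chrom)
        by_chrom.setdefault(seg.chrom, []).append(seg)

    covered = set(by_chrom)
    expected = {name for name, _, _ in genome.chromosomes}
    if covered != expected:
        missing = sorted(expected - covered)
        raise ProfileValidationError(
            f"profile {profile.sample_id} does not cover chromosomes: {missing}"
        )

    for chrom, segs in by_chrom.items():
        arms = genome.arms_of(chrom)
        prev: Segment | None = None
        for seg in segs:
            if prev is not None:
                if seg.start < prev.end:
                    raise ProfileValidationError(
                        f"overlapping segments: {prev} and {seg}"
                    )
                if seg.start > prev.end:
                    raise ProfileValidationError(
                        f"gap between segments: {prev} and {seg}"
                    )
            # a segment may not straddle the centromere (arm boundary)
            for arm in arms:
                if seg.start < arm.end < seg.end:
                    raise ProfileValidationError(
                        f"segment {seg} crosses arm boundary at {arm.end}"
                    )
            prev = seg
        if segs[0].start != 0:
            raise ProfileValidationError(
                f"{chrom}: first segment starts at {segs[0].start}, not 0"
            )
        if segs[-1].end != genome.chrom_length(chrom):
            raise ProfileValidationError(
                f"{chrom}: last segment ends at {segs[-1].end}, expected "
                f"{genome.chrom_length(chrom)}"
            )
    return profile


def diploid_profile(sample_id: str, genome: GenomeModel | None = None) -> SegmentedCopyNumberProfile:
    """All-diploid-heterozygous profile: one (2,1) segment per arm."""
    genome = genome or default_genome()
    segs = [Segment(a.chrom, a.start, a.end, 2, 1) for a in genome.arms()]
    return SegmentedCopyNumberProfile(sample_id, segs, genome)


def write_seg(profiles: list[SegmentedCopyNumberProfile], path) -> None:
    """Write profiles as SEG-like TSV (sample, chrom, start, end, total_cn, minor_cn)."""
    frames = [p.to_frame() for p in profiles]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SEG_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False)


def read_seg(path, genome: GenomeModel | None = None) -> list[SegmentedCopyNumberProfile]:
    """Read a SEG-like TSV into validated profiles (order of first appearance)."""
    genome = genome or default_genome()
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        segs = [
            Segment(r.chrom, int(r.start), int(r.end), int(r.total_cn), int(r.minor_cn))
            for r in grp.itertuples()
        ]
        profiles.append(
            validate_profile(SegmentedCopyNumberProfile(str(sample), segs, genome))
        )
    return profiles
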