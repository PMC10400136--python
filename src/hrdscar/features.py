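"""Genomic scar features from segmented allele-specific copy-number profiles.

HRD leaves a characteristic footprint of unrepaired double-strand-break
damage in the tumour copy-number profile.  This module computes the
established scar canon plus microhomology-deletion indel features:

* ``gloh`` — genome-wide focal LOH: fraction of the interrogated genome in
  LOH, excluding near-whole-arm (>=90% of arm) LOH events.
* ``n_loh_interstitial`` — count of LOH regions >15 Mb but smaller than the
  whole chromosome (the classic HRD-LOH score).
* ``n_lst`` — large-scale state transitions: breakpoints between two long
  (>=10 Mb) segments after smoothing out segments <3 Mb.
* ``n_tai`` — telomeric allelic imbalance: imbalanced regions reaching a
  telomere without crossing the centromere.
* ``n_breakpoints`` — copy-state transitions per arm, summed.
* ``mh_del_count`` / ``mh_del_fraction`` / ``median_del_len`` — deletions
  >=5 bp with flanking microhomology >=1 bp, their fraction of all
  deletions, and the median deletion length (microhomology-mediated
  end-joining is the backup repair pathway under HRD).

All coordinates are 0-based half-open; lengths are ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from statistics import median

import pandas as pd

from .segments import Segment, SegmentedCopyNumberProfile, validate_profile
from .variants import ShortVariant

MB = 1_000_000

#: Stable feature order fed to the classifier.
FEATURE_NAMES = [
    "gloh",
    "n_loh_interstitial",
    "n_lst",
    "n_tai",
    "n_breakpoints",
    "mh_del_count",
    "mh_del_fraction",
    "median_del_len",
]

WHOLE_ARM_FRACTION = 0.9


@dataclass(frozen=True)
class GlohValue:
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"gLOH {self.value} outside [0, 1]")


@dataclass(frozen=True)
class ScarFeatureVector:
    sample_id: str
    gloh: float
    n_loh_interstitial: int
    n_lst: int
    n_tai: int
    n_breakpoints: int
    mh_del_count: int
    mh_del_fraction: float
    median_del_len: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {f.name: getattr(self, f.name) for f in fields(self) if f.name != "sample_id"},
            name=self.sample_id,
        )[FEATURE_NAMES]


def compute_gloh(profile: SegmentedCopyNumberProfile) -> GlohValue:
    """Genome-wide focal LOH fraction.

    Sums the lengths of LOH segments (minor_cn = 0, total_cn >= 1),
    excluding any LOH segment spanning >=90% of its chromosome arm, and
    divides by the interrogated genome length.
    """
    validate_profile(profile)
    genome = profile.genome
    total = 0
    for seg in profile.segments:
        if not seg.is_loh:
            continue
        arm = genome.arm_at(seg.chrom, seg.start)
        if seg.length >= WHOLE_ARM_FRACTION * arm.length:
            continue
        total += seg.length
    return GlohValue(total / genome.interrogated_length)


def _merge_same_state(segs: list[Segment]) -> list[Segment]:
    """Merge adjacent segments with identical (total_cn, minor_cn)."""
    merged: list[Segment] = []
    for seg in segs:
        if merged and merged[-1].state == seg.state and merged[-1].end == seg.start:
            prev = merged.pop()
            seg = Segment(seg.chrom, prev.start, seg.end, seg.total_cn, seg.minor_cn)
        merged.append(seg)
    return merged


def count_interstitial_loh(profile: SegmentedCopyNumberProfile, min_len: int = 15 * MB) -> int:
    """LOH regions longer than ``min_len`` but smaller than the whole chromosome.

    Adjacent LOH segments (including across the centromere) are merged into
    maximal LOH runs before measuring.
    """
    genome = profile.genome
    count = 0
    for chrom, _, _ in genome.chromosomes:
        segs = profile.segments_of(chrom)
        run_start = None
        run_end = None
        runs: list[tuple[int, int]] = []
        for seg in segs:
            if seg.is_loh:
                if run_start is None:
                    run_start, run_end = seg.start, seg.end
                else:
                    run_end = seg.end
            else:
                if run_start is not None:
                    runs.append((run_start, run_end))
                run_start = None
        if run_start is not None:
            runs.append((run_start, run_end))
        chrom_len = genome.chrom_length(chrom)
        for s, e in runs:
            if e - s > min_len and e - s < chrom_len:
                count += 1
    return count


def count_lst(
    profile: SegmentedCopyNumberProfile,
    min_seg: int = 10 * MB,
    smooth_below: int = 3 * MB,
) -> int:
    """Large-scale state transitions, counted per arm.

    Within each arm: merge adjacent same-state segments, drop segments
    shorter than ``smooth_below``, re-merge, then count adjacent pairs in
    which both segments are >= ``min_seg`` (their states necessarily differ
    after merging).
    """
    count = 0
    for arm in profile.genome.arms():
        segs = [
            s for s in profile.segments_of(arm.chrom) if arm.start <= s.start < arm.end
        ]
        merged = _merge_same_state(segs)
        kept = [s for s in merged if s.length >= smooth_below]
        # dropping short segments can make equal states adjacent again
        smoothed: list[tuple[tuple[int, int], int]] = []  # (state, length)
        for s in kept:
            if smoothed and smoothed[-1][0] == s.state:
                smoothed[-1] = (s.state, smoothed[-1][1] + s.length)
            else:
                smoothed.append((s.state, s.length))
        for (_, len_a), (_, len_b) in zip(smoothed, smoothed[1:]):
            if len_a >= min_seg and len_b >= min_seg:
                count += 1
    return count


def count_tai(profile: SegmentedCopyNumberProfile) -> int:
    """Telomeric allelic-imbalance regions.

    Per arm: the maximal run of allelically imbalanced segments touching the
    arm's telomere counts once, unless it spans the entire arm (a whole-arm
    event reaches the centromere and is not a telomeric scar).
    """
    count = 0
    for arm in profile.genome.arms():
        segs = [
            s for s in profile.segments_of(arm.chrom) if arm.start <= s.start < arm.end
        ]
        if not segs:
            continue
        ordered = segs if arm.name == "p" else list(reversed(segs))
        # ordered[0] is the telomeric segment of the arm
        run_len = 0
        for s in ordered:
            if s.is_imbalanced:
                run_len += s.length
            else:
                break
        if 0 < run_len < arm.length:
            count += 1
    return count


def count_breakpoints(profile: SegmentedCopyNumberProfile) -> int:
    """Copy-state transitions between merged adjacent segments, per arm."""
    count = 0
    for arm in profile.genome.arms():
        segs = [
            s for s in profile.segments_of(arm.chrom) if arm.start <= s.start < arm.end
        ]
        merged = _merge_same_state(segs)
        count += max(0, len(merged) - 1)
    return count


def indel_features(variants: list[ShortVariant]) -> tuple[int, float, float]:
    """(mh_del_count, mh_del_fraction, median_del_len) over deletion indels.

    With no deletions, the fraction and median are defined as 0.
    """
    dels = [v for v in variants if v.is_deletion]
    if not dels:
        return 0, 0.0, 0.0
    mh = sum(v.is_mh_deletion for v in dels)
    return mh, mh / len(dels), float(median(v.del_length for v in dels))


def extract_features(
    profile: SegmentedCopyNumberProfile, variants: list[ShortVariant]
) -> ScarFeatureVector:
    """Full scar feature vector for one sample."""
    validate_profile(profile)
    for v in variants:
        if v.sample_id != profile.sample_id:
            raise ValueError(
                f"variant sample {v.sample_id!r} does not match profile "
                f"{profile.sample_id!r}"
            )
    mh_count, mh_frac, med_len = indel_features(variants)
    return ScarFeatureVector(
        sample_id=profile.sample_id,
        gloh=compute_gloh(profile).value,
        n_loh_interstitial=count_interstitial_loh(profile),
        n_lst=count_lst(profile),
        n_tai=count_tai(profile),
        n_breakpoints=count_breakpoints(profile),
        mh_del_count=mh_count,
        mh_del_fraction=mh_frac,
        median_del_len=med_len,
    )


def features_frame(
    profiles: list[SegmentedCopyNumberProfile],
    variants: list[ShortVariant],
) -> pd.DataFrame:
    """Feature matrix (rows = samples, columns = FEATURE_NAMES)."""
    by_sample: dict[str, list[ShortVariant]] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    rows = [
        extract_features(p, by_sample.get(p.sample_id, [])).to_series()
        for p in profiles
    ]
    if not rows:
        return pd.DataFrame(columns=FEATURE_NAMES)
    df = pd.DataFrame(rows)
    df.index.name = "sample"
    return df
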