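"""Scar-feature extraction: forced arithmetic, properties, oracle parity."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import MB, make_profile, random_profile
from _oracles import breakpoints_oracle, interstitial_loh_oracle, lst_oracle

from hrdscar.features import (
    compute_gloh,
    count_breakpoints,
    count_interstitial_loh,
    count_lst,
    count_tai,
    extract_features,
    indel_features,
)
from hrdscar.segments import (
    ProfileValidationError,
    Segment,
    SegmentedCopyNumberProfile,
    diploid_profile,
    validate_profile,
)
from hrdscar.variants import ShortVariant


def _dv(sample, del_length, mh_len):
    return ShortVariant(sample, "intergenic", "indel", False,
                        del_length=del_length, microhomology_len=mh_len)


class TestGloh:
    def test_no_loh_is_zero(self, round_genome):
        assert compute_gloh(diploid_profile("S0", round_genome)).value == 0.0

    def test_single_focal_segment_fraction(self, round_genome):
        # 30 Mb LOH out of a 3000 Mb interrogated genome
        prof = make_profile(
            round_genome, [Segment("chr1", 10 * MB, 40 * MB, 2, 0)]
        )
        assert compute_gloh(prof).value == pytest.approx(0.01)

    def test_whole_arm_loh_excluded(self, round_genome):
        # 95% of the 150 Mb p arm: excluded by the >=90%-of-arm rule
        prof = make_profile(
            round_genome, [Segment("chr1", 0, int(142.5 * MB), 2, 0)]
        )
        assert compute_gloh(prof).value == 0.0

    def test_deep_deletion_is_not_loh(self, round_genome):
        prof = make_profile(round_genome, [Segment("chr1", 0, 30 * MB, 0, 0)])
        assert compute_gloh(prof).value == 0.0

    def test_monotone_in_added_focal_loh(self, round_genome):
        base = make_profile(round_genome, [Segment("chr2", 10 * MB, 30 * MB, 2, 0)])
        more = make_profile(
            round_genome,
            [
                Segment("chr2", 10 * MB, 30 * MB, 2, 0),
                Segment("chr3", 200 * MB, 220 * MB, 1, 0),
            ],
        )
        assert compute_gloh(more).value > compute_gloh(base).value

    def test_growing_segment_past_arm_threshold_drops_contribution(self, round_genome):
        focal = make_profile(round_genome, [Segment("chr1", 0, 100 * MB, 2, 0)])
        whole = make_profile(round_genome, [Segment("chr1", 0, 140 * MB, 2, 0)])
        assert compute_gloh(focal).value > 0
        assert compute_gloh(whole).value == 0.0


class TestValidation:
    def test_clean_profile_returned(self, small_genome):
        prof = diploid_profile("S0", small_genome)
        assert validate_profile(prof) is prof

    def test_overlap_rejected(self, small_genome):
        segs = [Segment(a.chrom, a.start, a.end, 2, 1) for a in small_genome.arms()]
        segs.append(Segment("chr1", 10 * MB, 20 * MB, 2, 1))
        with pytest.raises(ProfileValidationError, match="overlap"):
            validate_profile(SegmentedCopyNumberProfile("S0", segs, small_genome))

    def test_gap_rejected(self, small_genome):
        segs = [Segment(a.chrom, a.start, a.end, 2, 1) for a in small_genome.arms()]
        segs[0] = Segment("chr1", 0, 50 * MB, 2, 1)  # leaves (50,75) uncovered
        with pytest.raises(ProfileValidationError, match="gap|ends"):
            validate_profile(SegmentedCopyNumberProfile("S0", segs, small_genome))

    def test_minor_exceeding_major_rejected(self):
        with pytest.raises(ProfileValidationError, match="minor"):
            Segment("chr1", 0, 10, 2, 2)

    def test_centromere_crossing_rejected(self, small_genome):
        segs = [
            Segment(a.chrom, a.start, a.end, 2, 1)
            for a in small_genome.arms()
            if a.chrom != "chr1"
        ]
        segs.append(Segment("chr1", 0, 150 * MB, 2, 1))
        with pytest.raises(ProfileValidationError, match="arm boundary"):
            validate_profile(SegmentedCopyNumberProfile("S0", segs, small_genome))


class TestCounts:
    def test_single_segment_arms_have_no_lst(self, small_genome):
        assert count_lst(diploid_profile("S0", small_genome)) == 0

    def test_two_long_segments_one_lst(self, small_genome):
        prof = make_profile(small_genome, [Segment("chr1", 0, 40 * MB, 3, 1)])
        # p arm: 40 Mb (3,1) + 35 Mb (2,1) -> one transition, both >= 10 Mb
        assert count_lst(prof) == 1

    def test_short_segment_smoothed_away(self, small_genome):
        prof = make_profile(small_genome, [Segment("chr1", 30 * MB, 32 * MB, 3, 1)])
        # a 2 Mb interruption inside a diploid arm is smoothed out
        assert count_lst(prof) == 0

    def test_three_interstitial_loh_of_20mb(self, small_genome):
        prof = make_profile(
            small_genome,
            [
                Segment("chr1", 10 * MB, 30 * MB, 2, 0),
                Segment("chr2", 10 * MB, 30 * MB, 2, 0),
                Segment("chr3", 10 * MB, 30 * MB, 1, 0),
            ],
        )
        assert count_interstitial_loh(prof) == 3

    def test_fifteen_mb_boundary_is_exclusive(self, small_genome):
        prof = make_profile(small_genome, [Segment("chr1", 0, 15 * MB, 2, 0)])
        assert count_interstitial_loh(prof) == 0

    def test_tai_telomeric_vs_interstitial(self, small_genome):
        telomeric = make_profile(small_genome, [Segment("chr1", 0, 20 * MB, 3, 1)])
        interstitial = make_profile(
            small_genome, [Segment("chr1", 20 * MB, 40 * MB, 3, 1)]
        )
        assert count_tai(telomeric) == 1
        assert count_tai(interstitial) == 0

    def test_whole_arm_imbalance_not_tai(self, small_genome):
        prof = make_profile(small_genome, [Segment("chr1", 0, 75 * MB, 3, 1)])
        assert count_tai(prof) == 0

    def test_q_arm_telomere_anchoring(self, small_genome):
        prof = make_profile(
            small_genome, [Segment("chr1", 130 * MB, 150 * MB, 3, 1)]
        )
        assert count_tai(prof) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_counting_features_match_bruteforce_oracles(self, small_genome, seed):
        rng = np.random.default_rng(seed)
        prof = random_profile(small_genome, rng, max_breaks_per_arm=5)
        validate_profile(prof)
        assert count_lst(prof) == lst_oracle(prof)
        assert count_interstitial_loh(prof) == interstitial_loh_oracle(prof)
        assert count_breakpoints(prof) == breakpoints_oracle(prof)


class TestExtractFeatures:
    def test_all_diploid_no_variants_is_zero_vector(self, small_genome):
        fv = extract_features(diploid_profile("S0", small_genome), [])
        assert fv.gloh == 0.0
        assert fv.n_loh_interstitial == fv.n_lst == fv.n_tai == 0
        assert fv.n_breakpoints == 0
        assert fv.mh_del_count == 0
        assert fv.mh_del_fraction == 0.0  # defined as 0 with no deletions
        assert fv.median_del_len == 0.0

    def test_microhomology_deletion_fraction(self, small_genome):
        variants = [
            _dv("S0", 8, 2),
            _dv("S0", 12, 1),
            _dv("S0", 6, 3),
            _dv("S0", 9, 0),
        ]
        fv = extract_features(diploid_profile("S0", small_genome), variants)
        assert fv.mh_del_count == 3
        assert fv.mh_del_fraction == pytest.approx(0.75)

    def test_short_or_unflanked_deletions_not_counted(self):
        # <5 bp or no microhomology: excluded from the count, kept in fraction
        mh, frac, med = indel_features([_dv("S0", 4, 2), _dv("S0", 10, 0)])
        assert mh == 0
        assert frac == 0.0
        assert med == 7.0

    def test_sample_mismatch_rejected(self, small_genome):
        with pytest.raises(ValueError, match="does not match"):
            extract_features(
                diploid_profile("S0", small_genome), [_dv("OTHER", 8, 2)]
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_segment_order_invariance(self, small_genome, seed):
        rng = np.random.default_rng(100 + seed)
        prof = random_profile(small_genome, rng)
        shuffled_segs = list(prof.segments)
        rng.shuffle(shuffled_segs)
        shuffled = SegmentedCopyNumberProfile(prof.sample_id, shuffled_segs,
                                              small_genome)
        assert extract_features(prof, []) == extract_features(shuffled, [])
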