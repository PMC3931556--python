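"""Cross-correlation engine, peak location, NSC/RSC and QC-tag mapping."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from strandqc import (
    AlignedTags,
    CrossCorrelationProfile,
    UndefinedMetricError,
    ValidationError,
    assign_qc_tag,
    compute_nsc_rsc,
    cross_correlation_profile,
    locate_peaks,
    smooth_profile,
)
from helpers import brute_force_profile

# brute-force oracle output for the 12-tag toy library (conftest.toy_tags)
# on grid 0..40 step 4, frozen from an independent dense-vector computation
TOY_CC = [
    -0.026681339948, -0.027240852361, -0.027824333746, -0.028433358038,
    -0.029069640066, 0.862316498503, -0.030431640107, -0.031161649067,
    -0.029056184088, -0.029786011524, -0.030553446958,
]


class TestProfile:
    def test_default_grid_has_201_points(self, toy_tags):
        profile = cross_correlation_profile(toy_tags)
        assert len(profile.shifts) == 201
        assert profile.shifts[0] == 0 and profile.shifts[-1] == 400
        assert np.all(np.diff(profile.shifts) == 2)

    def test_mirrored_strands_correlate_perfectly_at_zero_shift(self):
        pos = np.array([10, 25, 60, 61, 90])
        tags = AlignedTags(
            chrom_sizes={"chr1": 120},
            plus_positions={"chr1": pos},
            minus_positions={"chr1": pos.copy()},
            read_length=30,
        )
        profile = cross_correlation_profile(tags, 0, 2, 40)
        assert profile.cc[0] == pytest.approx(1.0, abs=1e-12)

    def test_toy_library_matches_frozen_oracle_values(self, toy_tags):
        profile = cross_correlation_profile(toy_tags, 0, 4, 40)
        np.testing.assert_allclose(profile.cc, TOY_CC, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_small_libraries(self, seed):
        rng = np.random.default_rng(seed)
        from conftest import random_tags

        tags = random_tags(rng, n_tags=40)
        profile = cross_correlation_profile(tags, 0, 3, 60)
        expected = brute_force_profile(tags, profile.shifts)
        np.testing.assert_allclose(profile.cc, expected, atol=1e-9)

    def test_chromosome_additivity(self, toy_tags):
        split = AlignedTags(
            chrom_sizes={"a": 200, "b": 200},
            plus_positions={
                "a": toy_tags.plus_positions["chr1"],
                "b": toy_tags.plus_positions["chr1"].copy(),
            },
            minus_positions={
                "a": toy_tags.minus_positions["chr1"],
                "b": toy_tags.minus_positions["chr1"].copy(),
            },
            read_length=36,
        )
        one = cross_correlation_profile(toy_tags, 0, 4, 40)
        two = cross_correlation_profile(split, 0, 4, 40)
        np.testing.assert_allclose(one.cc, two.cc, atol=1e-9)

    def test_shift_invariance_under_translation(self, toy_tags):
        k = 17
        shifted = AlignedTags(
            chrom_sizes={"chr1": 200},
            plus_positions={"chr1": toy_tags.plus_positions["chr1"] + k},
            minus_positions={"chr1": toy_tags.minus_positions["chr1"] + k},
            read_length=36,
        )
        base = cross_correlation_profile(toy_tags, 0, 2, 10)
        moved = cross_correlation_profile(shifted, 0, 2, 10)
        np.testing.assert_allclose(base.cc, moved.cc, atol=1e-9)

    def test_single_strand_library_is_undefined(self):
        tags = AlignedTags(
            chrom_sizes={"chr1": 100},
            plus_positions={"chr1": np.array([10, 20])},
            read_length=36,
        )
        with pytest.raises(UndefinedMetricError, match="minus-strand"):
            cross_correlation_profile(tags)

    def test_bad_grid_rejected(self, toy_tags):
        with pytest.raises(ValidationError):
            cross_correlation_profile(toy_tags, 10, 2, 10)


class TestSmoothing:
    def test_bandwidth_one_is_identity(self):
        cc = np.array([0.3, -0.1, 0.5, 0.2])
        np.testing.assert_array_equal(smooth_profile(cc, 1), cc)

    def test_spike_spreads_over_window(self):
        np.testing.assert_allclose(
            smooth_profile(np.array([0, 0, 3, 0, 0], float), 3), [0, 1, 1, 1, 0]
        )

    def test_matches_windowed_mean_oracle(self):
        rng = np.random.default_rng(3)
        cc = rng.normal(size=25)
        got = smooth_profile(cc, 3)
        for i in range(len(cc)):
            window = cc[max(0, i - 1): i + 2]
            assert got[i] == pytest.approx(window.mean(), abs=1e-12)

    @pytest.mark.parametrize("bandwidth", [0, 2, 4])
    def test_even_or_zero_bandwidth_rejected(self, bandwidth):
        with pytest.raises(ValidationError):
            smooth_profile(np.zeros(9), bandwidth)

    def test_bandwidth_larger_than_grid_rejected(self):
        with pytest.raises(ValidationError):
            smooth_profile(np.zeros(3), 5)


def _synthetic_profile(peak_shift, peak_cc=0.5, base=0.1, shifts=None):
    shifts = np.arange(0, 401, 2) if shifts is None else shifts
    cc = np.full(len(shifts), base, float)
    width = 20
    bump = np.clip(1 - np.abs(shifts - peak_shift) / width, 0, None)
    cc = cc + (peak_cc - base) * bump
    return CrossCorrelationProfile(shifts=shifts, cc=cc)


class TestPeakLocation:
    def test_unique_maximum_found(self):
        profile = _synthetic_profile(180)
        out = locate_peaks(profile, read_length=36)
        assert out.fragment_peak_shift == 180
        assert out.phantom_peak_shift == 36
        assert out.baseline_cc == pytest.approx(0.1)

    def test_phantom_dominant_profile_flagged_and_excluded(self):
        profile = _synthetic_profile(36, peak_cc=0.9)
        out = locate_peaks(profile, read_length=36, exclusion_halfwidth=10)
        assert "phantom_dominant" in out.flags
        assert abs(out.fragment_peak_shift - 36) > 10

    def test_all_grid_points_excluded_is_config_error(self):
        profile = _synthetic_profile(36, shifts=np.arange(30, 43, 2))
        with pytest.raises(ValidationError, match="exclusion"):
            locate_peaks(profile, read_length=36, exclusion_halfwidth=10)

    def test_multi_peaked_profile_flagged(self):
        shifts = np.arange(0, 401, 2)
        profile = _synthetic_profile(150)
        extra = _synthetic_profile(300)
        profile = dataclasses.replace(
            profile, cc=np.maximum(profile.cc, extra.cc)
        )
        out = locate_peaks(profile, read_length=36)
        assert "multi_peaked" in out.flags

    def test_fragment_near_read_length_flagged(self):
        profile = _synthetic_profile(50)
        out = locate_peaks(profile, read_length=36)
        assert "fragment_near_read_length" in out.flags


class TestMetrics:
    def _profile(self, frag, phantom, base):
        return CrossCorrelationProfile(
            shifts=np.arange(0, 11, 2),
            cc=np.zeros(6),
            fragment_peak_shift=8,
            fragment_peak_cc=frag,
            phantom_peak_shift=2,
            phantom_peak_cc=phantom,
            baseline_cc=base,
        )

    def test_direct_substitution(self):
        out = compute_nsc_rsc(self._profile(0.40, 0.20, 0.10))
        assert out.nsc == pytest.approx(4.0)
        assert out.rsc == pytest.approx(3.0)

    def test_flat_profile_gives_zero_rsc_with_flag(self):
        out = compute_nsc_rsc(self._profile(0.10, 0.10, 0.10))
        assert out.rsc == 0.0
        assert "degenerate_rsc" in out.flags

    def test_equal_fragment_and_phantom_peaks_give_unit_rsc(self):
        out = compute_nsc_rsc(self._profile(0.30, 0.30, 0.10))
        assert out.rsc == pytest.approx(1.0)

    def test_requires_located_peaks(self):
        with pytest.raises(ValidationError):
            compute_nsc_rsc(CrossCorrelationProfile(np.arange(3), np.zeros(3)))


class TestQCTag:
    @pytest.mark.parametrize(
        "rsc,tag",
        [(0.1, -2), (0.3, -1), (0.7, 0), (1.2, 1), (1.6, 2),
         (0.0, -2), (0.25, -1), (0.5, 0), (1.0, 1), (1.5, 2)],
    )
    def test_published_mapping_with_rightward_boundaries(self, rsc, tag):
        assert assign_qc_tag(rsc) == tag

    def test_negative_rsc_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert assign_qc_tag(-0.3) == -2

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_non_finite_rsc_rejected(self, bad):
        with pytest.raises(ValidationError):
            assign_qc_tag(bad)

    @given(st.floats(0, 10, allow_nan=False), st.floats(0, 10, allow_nan=False))
    def test_mapping_is_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert assign_qc_tag(lo) <= assign_qc_tag(hi)
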