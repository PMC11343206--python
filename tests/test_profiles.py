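"""Metaplot extraction, co-orientation, and the profile transformations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import resectseq as rs
from resectseq.io import DataError
from resectseq.profiles import hann_kernel, pooled_decile_codes

from conftest import make_profile


def track_from_points(chrom_sizes, points):
    """points: list of (chrom, pos, strand) singles."""
    import pandas as pd
    from resectseq.io import endpoints_from_alignments

    df = pd.DataFrame([(c, p, s, 60) for c, p, s in points],
                      columns=["chrom", "pos", "strand", "mapq"])
    return endpoints_from_alignments(df, chrom_sizes)


def one_hotspot(chrom="chr1", center=50_000, strength=1.0):
    return rs.HotspotSet(np.array([chrom]), np.array([center]),
                         np.array([strength]), np.array(["hs0"]))


class TestExtractOrientedMatrix:
    def test_top_count_right_of_center_maps_to_positive_offset(self, chrom_sizes):
        track = track_from_points(chrom_sizes, [("chr1", 50_500, "+")])
        mat = rs.extract_oriented_matrix(track, one_hotspot())
        oriented = mat.oriented()
        nz = np.flatnonzero(oriented.sum(axis=0))
        assert mat.positions[nz].tolist() == [500]

    def test_bottom_count_left_of_center_reflects_to_positive_offset(
            self, chrom_sizes):
        track = track_from_points(chrom_sizes, [("chr1", 49_500, "-")])
        mat = rs.extract_oriented_matrix(track, one_hotspot())
        # raw bottom row peaks at -500; the oriented stack sees +500
        assert mat.positions[np.argmax(mat.bottom[0])] == -500
        oriented = mat.oriented()
        nz = np.flatnonzero(oriented.sum(axis=0))
        assert mat.positions[nz].tolist() == [500]

    def test_mirror_symmetric_strands_give_identical_observations(
            self, chrom_sizes):
        points = [("chr1", 50_000 + d, "+") for d in (-120, 300, 1500)]
        points += [("chr1", 50_000 - d, "-") for d in (-120, 300, 1500)]
        track = track_from_points(chrom_sizes, points)
        mat = rs.extract_oriented_matrix(track, one_hotspot())
        np.testing.assert_array_equal(mat.top[0], mat.bottom[0][::-1])

    def test_edge_hotspots_skipped_and_logged(self, chrom_sizes):
        hs = rs.HotspotSet(np.array(["chr1", "chr1"]), np.array([100, 50_000]),
                           np.array([1.0, 1.0]), np.array(["edge", "ok"]))
        track = track_from_points(chrom_sizes, [("chr1", 50_100, "+")])
        mat = rs.extract_oriented_matrix(track, hs)
        assert mat.skipped == ["edge"]
        assert mat.n_hotspots == 1

    def test_all_skipped_is_an_error(self, chrom_sizes):
        hs = one_hotspot(center=10)
        track = track_from_points(chrom_sizes, [("chr1", 500, "+")])
        with pytest.raises(DataError, match="crossed"):
            rs.extract_oriented_matrix(track, hs)

    def test_empty_hotspot_set_is_an_error(self, chrom_sizes):
        track = track_from_points(chrom_sizes, [("chr1", 500, "+")])
        empty = rs.HotspotSet(np.array([], dtype=object), np.array([], dtype=int),
                              np.array([]), np.array([], dtype=object))
        with pytest.raises(DataError, match="empty"):
            rs.extract_oriented_matrix(track, empty)


class TestAverageProfile:
    def test_identical_hotspots_average_to_the_common_row(self, chrom_sizes):
        hs = rs.HotspotSet(np.array(["chr1", "chr2"]), np.array([50_000, 25_000]),
                           np.array([1.0, 1.0]), np.array(["a", "b"]))
        points = [("chr1", 50_200, "+"), ("chr2", 25_200, "+")]
        track = track_from_points(chrom_sizes, points)
        prof = rs.average_profile(rs.extract_oriented_matrix(track, hs))
        assert prof.values[prof.index(200)] == pytest.approx(0.5)  # 2 of 4 obs
        assert prof.values.sum() == pytest.approx(0.5)

    def test_column_mean_against_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        top = rng.random((10, 5001))
        bottom = rng.random((10, 5001))
        mat = rs.StrandMatrices(top, bottom, np.arange(-2500, 2501),
                                np.array([f"h{i}" for i in range(10)]),
                                np.ones(10))
        prof = rs.average_profile(mat)
        stacked = np.vstack([top, bottom[:, ::-1]])
        oracle = np.array([sum(stacked[i, j] for i in range(20)) / 20.0
                           for j in range(5001)])
        np.testing.assert_allclose(prof.values, oracle, atol=1e-12)

    def test_strength_weighting(self):
        top = np.zeros((2, 11))
        top[0, 5] = 1.0  # strong hotspot signal
        mat = rs.StrandMatrices(top, np.zeros((2, 11)), np.arange(-5, 6),
                                np.array(["a", "b"]), np.array([3.0, 1.0]))
        prof = rs.average_profile(mat, weighting="strength")
        assert prof.values[5] == pytest.approx(3.0 / 8.0)


class TestSubtractBackground:
    def test_constant_profile_becomes_zero(self):
        prof = make_profile(np.full(5001, 2.5))
        out = rs.subtract_background(prof)
        assert out.background == pytest.approx(2.5)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_delta_on_zero_baseline_unchanged(self, delta_profile_factory):
        prof = delta_profile_factory([(1000, 4.0)], background=None)
        out = rs.subtract_background(prof)
        assert out.background == 0.0
        np.testing.assert_array_equal(out.values, prof.values)

    def test_additive_constant_recovered(self):
        rng = np.random.default_rng(3)
        signal = np.zeros(5001)
        signal[2600:3400] = rng.random(800)  # signal away from the bg window
        prof = make_profile(signal + 0.3)
        out = rs.subtract_background(prof)
        np.testing.assert_allclose(out.values, signal, atol=1e-12)

    def test_halfwidth_zero_is_single_position(self):
        values = np.zeros(5001)
        values[-1] = 7.0  # position +2500 exactly
        out = rs.subtract_background(make_profile(values), bg_halfwidth=0)
        assert out.background == pytest.approx(7.0)

    def test_bg_window_outside_profile_errors(self):
        prof = make_profile(np.zeros(1001), start=-500)
        with pytest.raises(DataError, match="outside"):
            rs.subtract_background(prof)


class TestHannSmooth:
    def test_window_three_is_identity(self):
        x = np.random.default_rng(1).random(100)
        np.testing.assert_allclose(rs.hann_smooth(x, 3), x, atol=1e-15)

    def test_impulse_window_five_kernel(self):
        x = np.zeros(11)
        x[5] = 1.0
        out = rs.hann_smooth(x, 5)
        np.testing.assert_allclose(out[3:8], [0.0, 0.25, 0.5, 0.25, 0.0],
                                   atol=1e-15)

    def test_interior_total_conserved(self):
        rng = np.random.default_rng(2)
        x = np.zeros(2000)
        x[200:1800] = rng.random(1600)  # support >= window from the edges
        out = rs.hann_smooth(x, 151)
        assert out.sum() == pytest.approx(x.sum(), abs=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            rs.hann_smooth(np.zeros(10), 4)

    def test_profile_metadata_updated(self, small_profile):
        out = rs.hann_smooth(small_profile, 151)
        assert out.smoothing == 151


class TestNormalizeProfile:
    def test_peak_mode_sets_range_max_to_one(self, delta_profile_factory):
        prof = delta_profile_factory([(900, 4.0), (-50, 9.0)], background=0.0)
        out = rs.normalize_profile(prof, "peak")
        assert out.values[out.index(900)] == pytest.approx(1.0)
        assert out.slice(100, 2500, inclusive=True).max() == pytest.approx(1.0)
        # the central signal may exceed 1: normalizer is the resection peak
        assert out.values[out.index(-50)] == pytest.approx(9.0 / 4.0)

    def test_auc_mode_constant_profile(self):
        prof = make_profile(np.full(5001, 2.0))
        out = rs.normalize_profile(prof, "auc")
        # area over [-1000, 2500] (3501 positions) becomes 1
        assert out.values[0] == pytest.approx(1.0 / 3501.0)
        assert out.slice(-1000, 2500, inclusive=True).sum() == pytest.approx(1.0)

    def test_zero_profile_errors_naming_range(self):
        with pytest.raises(DataError, match=r"\[100, 2500\]"):
            rs.normalize_profile(make_profile(np.zeros(5001)), "peak")


class TestClampNegatives:
    def test_elementwise_clamp(self):
        prof = make_profile([-1.0, 0.0, 2.0], start=0)
        np.testing.assert_array_equal(rs.clamp_negatives(prof).values,
                                      [0.0, 0.0, 2.0])

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=25)
    def test_idempotent_and_identity_on_nonnegative(self, values):
        prof = make_profile(values, start=0)
        once = rs.clamp_negatives(prof)
        twice = rs.clamp_negatives(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert np.all(once.values >= 0)


class TestHeatmap:
    def make_matrices(self, top, bottom=None, strengths=None):
        n = top.shape[0]
        return rs.StrandMatrices(
            top, np.zeros_like(top) if bottom is None else bottom,
            np.arange(-2500, 2501),
            np.array([f"h{i}" for i in range(n)]),
            np.ones(n) if strengths is None else np.asarray(strengths, float))

    def test_single_loaded_bin_gets_value_one_and_top_decile(self):
        top = np.zeros((1, 5001))
        top[0, 2500 + 80: 2500 + 120] = 2.0  # exactly one 40-bp bin ([+80,+120))
        heat = rs.heatmap_normalize(self.make_matrices(top))["top"]
        loaded = np.flatnonzero(heat.values[0])
        assert loaded.size == 1
        assert heat.values[0, loaded[0]] == pytest.approx(1.0)
        assert heat.deciles[0, loaded[0]] == 10

    def test_populated_rows_sum_to_one(self, small_dataset):
        _, hotspots, track, _ = small_dataset
        mat = rs.extract_oriented_matrix(track, hotspots)
        for strand in ("top", "bottom"):
            heat = rs.heatmap_normalize(mat)[strand]
            sums = heat.values[~heat.empty_rows].sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_decile_classes_match_sort_oracle(self, small_dataset):
        _, hotspots, track, _ = small_dataset
        mat = rs.extract_oriented_matrix(track, hotspots)
        heat = rs.heatmap_normalize(mat)["top"]
        nz = heat.values[heat.values > 0]
        codes = heat.deciles[heat.values > 0]
        # oracle: sort the pooled nonzero values; class sizes within 1 of n/10
        counts = np.bincount(codes, minlength=11)[1:]
        n = nz.size
        assert counts.sum() == n
        assert np.all(np.abs(counts - n / 10) <= 1)
        # codes are monotone in value up to ties
        order = np.argsort(nz, kind="stable")
        assert np.all(np.diff(codes[order]) >= 0)

    def test_row_scale_invariance(self):
        rng = np.random.default_rng(5)
        top = rng.integers(0, 5, size=(6, 5001)).astype(float)
        heat1 = rs.heatmap_normalize(self.make_matrices(top))["top"]
        top_scaled = top.copy()
        top_scaled[2] *= 17.0
        heat2 = rs.heatmap_normalize(self.make_matrices(top_scaled))["top"]
        np.testing.assert_allclose(heat1.values, heat2.values, atol=1e-12)

    def test_rows_ordered_by_descending_strength(self):
        top = np.zeros((3, 5001))
        top[:, 2500] = [1, 2, 3]
        heat = rs.heatmap_normalize(
            self.make_matrices(top, strengths=[2.0, 9.0, 4.0]))["top"]
        assert heat.ids.tolist() == ["h1", "h2", "h0"]

    def test_bin_larger_than_window_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            rs.heatmap_normalize(self.make_matrices(np.zeros((1, 5001))),
                                 bin=5000, window=4001)


class TestPipelineProperties:
    def test_full_pipeline_peak_is_exactly_one(self, small_dataset):
        """average -> subtract -> smooth -> peak-normalize has range-max 1."""
        _, hotspots, track, _ = small_dataset
        mat = rs.extract_oriented_matrix(track, hotspots)
        prof = rs.normalize_profile(
            rs.hann_smooth(rs.subtract_background(rs.average_profile(mat)), 151),
            "peak")
        assert prof.slice(100, 2500, inclusive=True).max() == pytest.approx(1.0)

    def test_reflection_invariance(self, chrom_sizes):
        """Mirroring the genome and swapping strands leaves the profile fixed."""
        rng = np.random.default_rng(11)
        L = chrom_sizes["chr1"]
        center = 50_000
        offsets = rng.integers(-2000, 2001, size=200)
        strands = np.where(rng.random(200) < 0.5, "+", "-")
        points = [("chr1", center + o, s) for o, s in zip(offsets, strands)]
        track = track_from_points(chrom_sizes, points)
        prof = rs.average_profile(rs.extract_oriented_matrix(track, one_hotspot()))

        flip = {"+": "-", "-": "+"}
        mirrored = [("chr1", L - 1 - p, flip[s]) for _, p, s in points]
        track_m = track_from_points(chrom_sizes, mirrored)
        hs_m = one_hotspot(center=L - 1 - center)
        prof_m = rs.average_profile(rs.extract_oriented_matrix(track_m, hs_m))
        np.testing.assert_allclose(prof.values, prof_m.values, atol=1e-12)


def test_hann_kernel_normalized_and_symmetric():
    k = hann_kernel(151)
    assert k.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(k, k[::-1], atol=1e-15)
    assert k[0] == 0.0 and k[-1] == 0.0


def test_pooled_decile_codes_zero_stays_zero():
    vals = np.array([[0.0, 0.5], [0.2, 0.0]])
    codes = pooled_decile_codes(vals)
    assert codes[0, 0] == 0 and codes[1, 1] == 0
    assert codes[0, 1] > codes[1, 0] > 0


def test_profile_tsv_round_trip(tmp_path, small_profile):
    prof = rs.hann_smooth(small_profile, 51)
    rs.write_profile(prof, tmp_path / "p.tsv")
    back = rs.read_profile(tmp_path / "p.tsv")
    np.testing.assert_array_equal(back.positions, prof.positions)
    np.testing.assert_array_equal(back.values, prof.values)
    assert back.smoothing == 51
    assert back.background == prof.background
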