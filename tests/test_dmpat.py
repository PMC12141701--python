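"""Distance-pattern encoder: hand-checked codes, brute-force oracle, identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soxfe import dmpat
from soxfe.errors import DimensionError


def brute_force_encode(column):
    """Independent oracle: enumerate all unordered pairs with explicit sqrt."""
    col = np.asarray(column, float)
    nc = len(col)
    best_min, best_max = None, None
    for i in range(nc):
        for j in range(i + 1, nc):
            d = np.sqrt(col[i] ** 2 + col[j] ** 2)
            if best_min is None or d < best_min[0]:
                best_min = (d, i, j)
            if best_max is None or d > best_max[0]:
                best_max = (d, i, j)
    return best_min[1] * nc + best_min[2], best_max[1] * nc + best_max[2]


class TestPairDistance:
    @pytest.mark.parametrize(
        "a,b,expected", [(3, 4, 5.0), (0, 0, 0.0), (-3, 4, 5.0)]
    )
    def test_values(self, a, b, expected):
        assert dmpat.pair_distance(a, b) == pytest.approx(expected)

    def test_symmetry_and_nonfinite(self):
        assert dmpat.pair_distance(2, 7) == dmpat.pair_distance(7, 2)
        with pytest.raises(ValueError):
            dmpat.pair_distance(np.nan, 1.0)


class TestEncodeSample:
    def test_three_channel_hand_example(self):
        # DM(1,2)=5, DM(1,3)=3, DM(2,3)=4 -> min pair (1,3), max pair (1,2)
        val_min, val_max = dmpat.encode_sample([3, 4, 0])
        assert (val_min, val_max) == (2, 1)

    def test_all_equal_ties_break_to_first_pair(self):
        val_min, val_max = dmpat.encode_sample(np.ones(14))
        assert val_min == val_max == 1  # pair (1, 2)

    def test_codes_within_range_for_14_channels(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v1, v2 = dmpat.encode_sample(rng.normal(size=14))
            assert 0 <= v1 <= 195 and 0 <= v2 <= 195

    def test_single_channel_rejected(self):
        with pytest.raises(DimensionError):
            dmpat.encode_sample([1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(2, 5).flatmap(
            lambda nc: st.lists(
                st.floats(-100, 100, allow_nan=False), min_size=nc, max_size=nc
            )
        )
    )
    def test_matches_brute_force_oracle(self, column):
        assert dmpat.encode_sample(column) == brute_force_encode(column)


class TestDecodeCode:
    @pytest.mark.parametrize(
        "val,nc,expected", [(1, 14, (1, 2)), (2, 3, (1, 3)), (195, 14, (14, 14))]
    )
    def test_values(self, val, nc, expected):
        assert dmpat.decode_code(val, nc) == expected

    def test_round_trip_on_encoder_image(self):
        nc = 6
        for a1 in range(1, nc + 1):
            for a2 in range(a1 + 1, nc + 1):
                val = (a1 - 1) * nc + (a2 - 1)
                assert dmpat.decode_code(val, nc) == (a1, a2)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            dmpat.decode_code(196, 14)


class TestEncodeSegment:
    def test_oracle_on_random_segments(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            nc = rng.integers(2, 6)
            length = rng.integers(1, 51)
            seg = rng.normal(size=(nc, length))
            codes = dmpat.encode_segment(seg)
            for t in range(length):
                assert (codes.codes_min[t], codes.codes_max[t]) == brute_force_encode(
                    seg[:, t]
                )

    def test_positive_scaling_leaves_codes_unchanged(self):
        rng = np.random.default_rng(3)
        seg = rng.normal(size=(14, 64))
        base = dmpat.encode_segment(seg)
        scaled = dmpat.encode_segment(seg * 17.3)
        assert np.array_equal(base.codes_min, scaled.codes_min)
        assert np.array_equal(base.codes_max, scaled.codes_max)

    def test_constant_segment_gives_constant_codes(self):
        seg = np.tile(np.array([[3.0], [4.0], [0.0]]), (1, 10))
        codes = dmpat.encode_segment(seg)
        assert set(codes.codes_min) == {2} and set(codes.codes_max) == {1}

    def test_output_length_matches_samples(self):
        seg = np.random.default_rng(0).normal(size=(14, 1920))
        codes = dmpat.encode_segment(seg)
        assert len(codes.codes_min) == len(codes.codes_max) == 1920


class TestHistogramsAndMerge:
    def test_lengths_and_conservation(self):
        seg = np.random.default_rng(1).normal(size=(14, 1920))
        f1, f2 = dmpat.histogram_features(dmpat.encode_segment(seg))
        assert len(f1.values) == len(f2.values) == 196
        assert f1.values.sum() == f2.values.sum() == 1920
        f3 = dmpat.merge_features(f1, f2)
        assert len(f3.values) == 392
        assert np.array_equal(f3.values[:196], f1.values)
        assert np.array_equal(f3.values[196:], f2.values)
        assert f3.values.sum() == 2 * 1920

    def test_degenerate_histogram(self):
        seg = np.tile(np.array([[3.0], [4.0], [0.0]]), (1, 7))
        f1, _ = dmpat.histogram_features(dmpat.encode_segment(seg))
        assert f1.values[2] == 7 and f1.values.sum() == 7

    def test_merge_length_mismatch(self):
        f1, f2 = dmpat.histogram_features(
            dmpat.encode_segment(np.random.default_rng(0).normal(size=(3, 5)))
        )
        f2.values = f2.values[:-1]
        with pytest.raises(DimensionError):
            dmpat.merge_features(f1, f2)


class TestExtractAll:
    def test_shapes_and_determinism(self, small_planted):
        f1, f2, f3 = dmpat.extract_all(small_planted.segments)
        n = len(small_planted)
        assert f1.shape == (n, 196) and f2.shape == (n, 196) and f3.shape == (n, 392)
        g1, _, _ = dmpat.extract_all(small_planted.segments)
        assert np.array_equal(f1, g1)

    def test_feature_matrix_round_trip(self, tmp_path, small_planted):
        f1, _, _ = dmpat.extract_all(small_planted.segments[:4])
        path = tmp_path / "f1.csv"
        dmpat.write_feature_matrix(f1, 14, "min_distance", path)
        assert np.array_equal(dmpat.read_feature_matrix(path), f1)
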