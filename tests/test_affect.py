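import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from affectpipe import affect
from affectpipe.core import BAND_NAMES, CHANNELS, DataError, EpochBandPowers


def bp_from(alpha_left, alpha_right, beta_left=0.0, beta_right=0.0, epoch=0):
    power = np.zeros((5, 4))
    ai, bi = BAND_NAMES.index("alpha"), BAND_NAMES.index("beta")
    li, ri = CHANNELS.index("AF7"), CHANNELS.index("AF8")
    power[ai, li], power[ai, ri] = alpha_left, alpha_right
    power[bi, li], power[bi, ri] = beta_left, beta_right
    return EpochBandPowers("P01", "A", epoch, power, 256.0)


power_tuples = st.tuples(*[st.floats(0.0, 100.0, allow_nan=False) for _ in range(4)])


class TestFormulas:
    def test_arousal_is_left_minus_right_alpha(self):
        assert affect.arousal_raw(bp_from(0.6, 0.4)) == pytest.approx(0.2)
        assert affect.arousal_raw(bp_from(0.5, 0.5)) == 0.0

    def test_valence_is_frontal_beta_over_alpha(self):
        bp = bp_from(0.6, 0.6, beta_left=0.3, beta_right=0.3)
        assert affect.valence_raw(bp) == pytest.approx(0.5)
        bp = bp_from(0.4, 0.4, beta_left=0.4, beta_right=0.4)
        assert affect.valence_raw(bp) == pytest.approx(1.0)

    def test_valence_epsilon_floor_keeps_result_finite(self):
        bp = bp_from(0.0, 0.0, beta_left=1.0, beta_right=1.0)
        assert affect.valence_raw(bp, eps=1e-12) == pytest.approx(1e12)

    def test_aw_is_normalized_right_minus_left(self):
        assert affect.aw_index(bp_from(0.6, 0.4)) == pytest.approx(-0.2, abs=1e-9)
        assert affect.aw_index(bp_from(0.0, 0.7)) == pytest.approx(1.0, abs=1e-9)
        assert affect.aw_index(bp_from(0.5, 0.5)) == pytest.approx(0.0)

    @given(power_tuples)
    @settings(deadline=None)
    def test_arousal_antisymmetric_under_left_right_swap(self, t):
        al, ar, bl, br = t
        assert affect.arousal_raw(bp_from(al, ar, bl, br)) == pytest.approx(
            -affect.arousal_raw(bp_from(ar, al, br, bl))
        )

    @given(power_tuples)
    @settings(deadline=None)
    def test_valence_invariant_under_left_right_swap(self, t):
        al, ar, bl, br = t
        assert affect.valence_raw(bp_from(al, ar, bl, br)) == pytest.approx(
            affect.valence_raw(bp_from(ar, al, br, bl))
        )

    @given(power_tuples)
    @settings(deadline=None)
    def test_aw_bounded_and_antisymmetric(self, t):
        al, ar, bl, br = t
        aw = affect.aw_index(bp_from(al, ar))
        assert -1.0 <= aw <= 1.0
        assert aw == pytest.approx(-affect.aw_index(bp_from(ar, al)), abs=1e-9)

    @given(power_tuples, st.floats(0.01, 100.0))
    @settings(deadline=None)
    def test_scale_invariance(self, t, c):
        al, ar, bl, br = t
        a, b = bp_from(al, ar, bl, br), bp_from(c * al, c * ar, c * bl, c * br)
        assert affect.arousal_raw(b) == pytest.approx(c * affect.arousal_raw(a), rel=1e-9, abs=1e-9)
        if al + ar > 1e-6:
            assert affect.valence_raw(b) == pytest.approx(affect.valence_raw(a), rel=1e-6)
            assert affect.aw_index(b) == pytest.approx(affect.aw_index(a), rel=1e-6, abs=1e-6)


class TestNormalize:
    def test_endpoints_map_to_unit_interval(self):
        values, record = affect.normalize_series([2.0, 4.0, 6.0])
        assert values.tolist() == [-1.0, 0.0, 1.0]
        assert record == (2.0, 6.0)

    def test_constant_series_maps_to_zeros(self):
        values, _ = affect.normalize_series([5.0, 5.0, 5.0])
        assert values.tolist() == [0.0, 0.0, 0.0]

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            affect.normalize_series([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, unique=True))
    @settings(deadline=None)
    def test_output_spans_full_interval_and_inverts(self, values):
        out, (lo, hi) = affect.normalize_series(values)
        assert out.min() == pytest.approx(-1.0)
        assert out.max() == pytest.approx(1.0)
        back = (out + 1.0) / 2.0 * (hi - lo) + lo
        assert back == pytest.approx(np.asarray(values), rel=1e-9, abs=1e-6)


class TestCircumplex:
    @pytest.mark.parametrize(
        "valence,arousal,expected",
        [(1, 1, 45.0), (-1, 1, 135.0), (1, 0, 0.0), (0, 1, 90.0), (-1, -1, -135.0)],
    )
    def test_angle_examples(self, valence, arousal, expected):
        assert affect.circumplex_angle(arousal, valence) == pytest.approx(expected)

    def test_origin_yields_undefined_marker(self):
        assert math.isnan(affect.circumplex_angle(0.0, 0.0))

    def test_angle_range(self, rng):
        for _ in range(1000):
            v, a = rng.uniform(-1, 1, 2)
            theta = affect.circumplex_angle(a, v)
            assert -180.0 < theta <= 180.0

    @pytest.mark.parametrize(
        "valence,arousal,expected",
        [(0.5, 0.5, "HVHA"), (-0.5, 0.5, "LVHA"), (0.0, 0.0, "HVHA"),
         (0.5, -0.5, "HVLA"), (-0.5, -0.5, "LVLA")],
    )
    def test_quadrant_labels(self, valence, arousal, expected):
        assert affect.quadrant_label(valence, arousal) == expected

    def test_quadrant_agrees_with_angle_sector(self, rng):
        # 10,000 random points: the quadrant label must match the angular sector
        sector_of = {
            "HVHA": (0.0, 90.0), "LVHA": (90.0, 180.0),
            "LVLA": (-180.0, -90.0), "HVLA": (-90.0, 0.0),
        }
        for _ in range(10_000):
            v, a = rng.uniform(-1, 1, 2)
            if v == 0 or a == 0:
                continue
            theta = affect.circumplex_angle(a, v)
            lo, hi = sector_of[affect.quadrant_label(v, a)]
            assert lo < theta < hi or (theta == 180.0 and hi == 180.0)

    def test_emotion_sectors_tile_the_circle_exactly_once(self):
        # sweep (-180, 180] on a 0.1-degree grid: every angle maps to exactly
        # one sector, and sector boundaries are left-closed
        angles = np.round(np.arange(-179.9, 180.0001, 0.1), 6)
        labels = [affect.emotion_label(t) for t in angles]
        assert affect.NEUTRAL_LABEL not in labels
        assert len(set(labels)) == 8
        assert affect.emotion_label(45.0) == affect.emotion_label(46.0)  # left-closed
        assert affect.emotion_label(45.0) != affect.emotion_label(44.9)

    def test_emotion_label_periodic(self):
        for theta in (-170.0, -45.0, 0.0, 45.0, 100.0):
            assert affect.emotion_label(theta) == affect.emotion_label(theta + 360.0)

    def test_undefined_angle_is_neutral(self):
        assert affect.emotion_label(math.nan) == affect.NEUTRAL_LABEL


class TestSeries:
    def test_cardinality_preserved(self, rng):
        bps = [
            EpochBandPowers("P01", "A", i, rng.uniform(0.1, 1.0, (5, 4)), 256.0)
            for i in range(600)
        ]
        series = affect.compute_affect_series(bps)
        assert len(series) == 600

    def test_constant_powers_degenerate_to_origin(self):
        bps = [bp_from(0.5, 0.4, 0.3, 0.3, epoch=i) for i in range(5)]
        series = affect.compute_affect_series(bps)
        assert all(s.arousal == 0.0 and s.valence == 0.0 for s in series.samples)
        assert all(s.quadrant == "HVHA" for s in series.samples)
        assert all(s.emotion == affect.NEUTRAL_LABEL for s in series.samples)

    def test_normalization_record_inverts_mapping(self, rng):
        bps = [
            EpochBandPowers("P01", "A", i, rng.uniform(0.1, 1.0, (5, 4)), 256.0)
            for i in range(50)
        ]
        series = affect.compute_affect_series(bps)
        lo, hi = series.normalization["arousal"]
        back = (series.values("arousal") + 1) / 2 * (hi - lo) + lo
        assert back == pytest.approx(series.values("arousal_raw"))

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            affect.compute_affect_series([])
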