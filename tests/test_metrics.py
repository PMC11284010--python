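"""Mixing measures: sampling, SD_t, dilution probability, entropy ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coromix as cm
from coromix.errors import InvalidProtocolError, RangeError, SamplingError
from coromix.metrics import (
    cross_section_sd,
    dilution_probability,
    entropy_ratio,
    raw_mean_entropy,
    sample_grid,
    station_measures,
    time_averaged_temperatures,
)


def _entropy_oracle(p_values, p_star):
    """Naive per-point evaluation of the normalized entropy ratio."""
    total = 0.0
    for p in p_values:
        if p > 0:
            total += -p * np.log(p)
    return (total / len(p_values)) / (-p_star * np.log(p_star))


def _sd_oracle(values):
    mean = sum(values) / len(values)
    return (sum((v - mean) ** 2 for v in values) / len(values)) ** 0.5


class TestSampleGrid:
    def test_default_grid_has_128_points_inside_lumen(self):
        geo = cm.VesselCatheterGeometry.for_catheter(cm.CatheterType.END_HOLE)
        s = sample_grid(geo, 1.2)
        assert s.n_points == 128
        assert np.all(s.r <= geo.vessel_radius)

    def test_central_wire_masks_centermost_ring(self):
        geo = cm.VesselCatheterGeometry.for_catheter(cm.CatheterType.SIDE_HOLE)
        s = sample_grid(geo, 1.2)
        inner = s.r == s.r.min()
        assert s.wire_mask[inner].all()
        # outer rings untouched by a 0.18 mm wire on the axis
        assert not s.wire_mask[s.r > 1.0].any()

    def test_alongside_wire_masks_only_nearby_points(self):
        geo = cm.VesselCatheterGeometry.for_catheter(cm.CatheterType.END_HOLE)
        s = sample_grid(geo, 1.2)
        assert 0 < s.wire_mask.sum() < s.n_points // 4
        x = s.r * np.cos(s.theta)
        y = s.r * np.sin(s.theta)
        wire_x = geo.catheter_radius + geo.wire_radius
        d = np.hypot(x - wire_x, y)
        assert d[s.wire_mask].max() < d[~s.wire_mask].min() + 1.0


class TestCrossSectionSD:
    def test_uniform_section_scores_zero(self):
        assert cross_section_sd([36.5] * 10) == 0.0

    def test_two_point_closed_form(self):
        assert cross_section_sd([36.0, 38.0], 37.0) == pytest.approx(1.0, rel=1e-12)
        assert cross_section_sd([36.0, 38.0], 37.0, method="mad") == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(36, 1, 50)
        assert cross_section_sd(v + 5.0) == pytest.approx(cross_section_sd(v), rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(SamplingError):
            cross_section_sd([36.0])


class TestDilutionProbability:
    def test_endpoints(self):
        assert dilution_probability(37.0, 37.0, 29.0) == 0.0
        assert dilution_probability(29.0, 37.0, 29.0) == 1.0

    def test_perfect_mix_value(self):
        assert dilution_probability(36.2727272727, 37.0, 29.0) == pytest.approx(
            15.0 / 165.0, abs=1e-9
        )

    def test_out_of_range_clamped(self):
        assert dilution_probability(38.0, 37.0, 29.0) == 0.0
        assert dilution_probability(28.0, 37.0, 29.0) == 1.0

    def test_inverted_contrast_rejected(self):
        with pytest.raises(InvalidProtocolError):
            dilution_probability(30.0, 29.0, 37.0)


class TestEntropyRatio:
    def test_perfect_mixing_scores_one(self):
        for p_star in (0.05, 15.0 / 165.0, 0.3):
            assert entropy_ratio([p_star] * 8, p_star) == pytest.approx(1.0, rel=1e-12)

    def test_no_tracer_not_calculable(self):
        assert np.isnan(entropy_ratio([0.0, 0.0, 0.0], 0.09))

    def test_frozen_example(self):
        # direct evaluation oracle of the normalized-entropy formula
        assert _entropy_oracle([0.05, 0.13], 0.09) == pytest.approx(0.9575, abs=5e-5)
        assert entropy_ratio([0.05, 0.13], 0.09) == pytest.approx(0.9575, abs=5e-5)

    def test_log_base_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 64)
        e_ln = entropy_ratio(p, 0.09)
        e_10 = entropy_ratio(p, 0.09, base=10.0)
        assert e_ln == pytest.approx(e_10, rel=1e-12)

    def test_invalid_pstar_rejected(self):
        with pytest.raises(InvalidProtocolError):
            entropy_ratio([0.1, 0.2], 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_oracle_equivalence_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 128)
        p_star = rng.uniform(0.02, 0.4)
        assert entropy_ratio(p, p_star) == pytest.approx(
            _entropy_oracle(p, p_star), rel=1e-12
        )
        v = rng.normal(36, 1, 128)
        assert cross_section_sd(v) == pytest.approx(_sd_oracle(list(v)), rel=1e-12)

    def test_order_and_duplication_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 32)
        shuffled = rng.permutation(p)
        doubled = np.concatenate([p, p])
        assert entropy_ratio(p, 0.1) == pytest.approx(entropy_ratio(shuffled, 0.1), rel=1e-12)
        assert entropy_ratio(p, 0.1) == pytest.approx(entropy_ratio(doubled, 0.1), rel=1e-12)
        v = rng.normal(35, 2, 32)
        assert cross_section_sd(v) == pytest.approx(
            cross_section_sd(np.concatenate([v, v])), rel=1e-12
        )

    def test_raw_mean_entropy_exposed_for_audit(self):
        p = [0.05, 0.13]
        e = entropy_ratio(p, 0.09)
        assert raw_mean_entropy(p) == pytest.approx(e * (-0.09 * np.log(0.09)), rel=1e-12)


class TestTwoLevelField:
    def test_brute_force_matches_vectorized(self):
        """Segregated field: fraction f at Ti, rest at Tb."""
        tb, ti = 37.0, 29.0
        n = 128
        for frac in (0.1, 0.25, 0.5):
            k = int(frac * n)
            temps = np.array([ti] * k + [tb] * (n - k))
            p = dilution_probability(temps, tb, ti)
            assert entropy_ratio(p, 0.09) == pytest.approx(
                _entropy_oracle(list(p), 0.09), rel=1e-12
            )
            assert cross_section_sd(temps) == pytest.approx(
                _sd_oracle(list(temps)), rel=1e-12
            )


class TestFieldMeasures:
    def test_time_average_of_synthetic_oscillation(self, side_med15_field):
        import copy

        f = copy.copy(side_med15_field)
        f.temperature = f.temperature.copy()
        # impose T = 36 + 2 sin(2 pi t / period) uniformly over the lumen
        for m, t in enumerate(f.times):
            val = 36.0 + 2.0 * np.sin(2 * np.pi * t / f.period)
            plane = f.temperature[m]
            plane[~np.isnan(plane)] = val
        s = sample_grid(f.geometry, 1.2)
        t_mk, t_bar = time_averaged_temperatures(f, s)
        assert t_bar == pytest.approx(36.0, abs=0.02)
        assert np.allclose(t_mk, t_bar, atol=1e-9)

    def test_uniform_perfect_mix_field_scores_sd0_e1(self, side_med15_field):
        import copy

        f = copy.copy(side_med15_field)
        f.temperature = f.temperature.copy()
        tmix = cm.perfect_mix_temperature(f.protocol)
        f.temperature[~np.isnan(f.temperature)] = tmix
        measures, settling = cm.longitudinal_profile(f, stations_cm=[0.0, 1.2, 2.4, 4.4])
        for m in measures:
            assert m.sd_t == pytest.approx(0.0, abs=1e-9)
            assert m.entropy_ratio == pytest.approx(1.0, rel=1e-9)
            assert m.calculable
        assert settling == 0.0

    def test_sidehole_sd_settles_by_about_one_cm(self, side_med15_field):
        measures, settling = cm.longitudinal_profile(
            side_med15_field, stations_cm=np.arange(0.0, 4.81, 0.2)
        )
        assert settling <= 1.2
        sd_at_1cm = [m.sd_t for m in measures if m.station_cm >= 1.0]
        assert max(sd_at_1cm) < 0.1

    def test_station_outside_field_rejected(self, side_med15_field):
        with pytest.raises(RangeError):
            station_measures(side_med15_field, 9.0)
        with pytest.raises(RangeError):
            cm.longitudinal_profile(side_med15_field, stations_cm=[-1.0])
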