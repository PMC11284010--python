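"""Transport solver: waveform, velocity, sources, scalar invariants."""

import numpy as np
import pytest

import coromix as cm
from coromix.design import CatheterType, FlowCategory
from coromix.errors import GeometryError
from coromix.grid import COARSE, LUMEN, SolverResolution
from coromix.transport import (
    coronary_waveform,
    injection_sources,
    velocity_snapshot,
    virtual_pullback,
)


def _protocol(category="MED", rate=15.0, catheter=CatheterType.SIDE_HOLE, **kw):
    cat = FlowCategory(category)
    return cm.FlowProtocol(
        coronary_category=cat,
        coronary_flow_mean=cat.mean_flow_ml_min,
        infusion_rate=rate,
        catheter=catheter,
        **kw,
    )


class TestWaveform:
    def test_zero_pulsatility_is_constant(self):
        t = np.linspace(0, 2, 101)
        assert np.allclose(coronary_waveform(150.0, 1.0, t, pulsatility=0.0), 150.0)

    @pytest.mark.parametrize("mean", [50.0, 150.0, 250.0])
    def test_mean_matches_quadrature(self, mean):
        # trapezoid oracle over one period: mean within 0.1%
        t = np.linspace(0.0, 1.0, 20001)
        q = coronary_waveform(mean, 1.0, t)
        est = np.trapezoid(q, t)
        assert est == pytest.approx(mean, rel=1e-3)

    @pytest.mark.parametrize("mean", [50.0, 150.0, 250.0])
    def test_non_negative_and_periodic(self, mean):
        t = np.linspace(0.0, 1.0, 1001)
        q = coronary_waveform(mean, 1.0, t)
        assert q.min() >= 0.0
        assert np.allclose(
            coronary_waveform(mean, 1.0, t), coronary_waveform(mean, 1.0, t + 3.0)
        )


class TestVelocity:
    def test_flux_contract_downstream_of_outlets(self):
        p = _protocol()
        snap = velocity_snapshot(
            cm.VesselCatheterGeometry.for_catheter(p.catheter), p, t=0.7
        )
        q_t = snap.coronary_flow_ml_min
        i_inj = snap.grid.i_injection
        for plane in (i_inj + 2, snap.grid.nz // 2, snap.grid.nz - 1):
            expected = q_t + p.infusion_rate
            assert snap.plane_flux_ml_min(plane) == pytest.approx(expected, rel=5e-3)
        # upstream of the outlets only the coronary flow passes
        assert snap.plane_flux_ml_min(1) == pytest.approx(q_t, rel=5e-3)

    def test_solid_cells_have_zero_velocity(self):
        p = _protocol(catheter=CatheterType.END_HOLE)
        geo = cm.VesselCatheterGeometry.for_catheter(p.catheter)
        snap = velocity_snapshot(geo, p, t=0.2)
        from coromix.grid import build_mask

        mask = build_mask(snap.grid, geo)
        assert np.all(snap.axial_velocity[mask != LUMEN] == 0.0)

    def test_axisymmetric_geometry_gives_symmetric_profile(self):
        # side-hole topology (wire on the axis) is angularly symmetric
        p = _protocol(catheter=CatheterType.SIDE_HOLE)
        snap = velocity_snapshot(
            cm.VesselCatheterGeometry.for_catheter(p.catheter), p, t=0.0
        )
        u = snap.axial_velocity
        assert np.ptp(u, axis=2).max() <= 1e-9 * abs(u).max()

    def test_degenerate_geometry_rejected(self):
        # a catheter that (nearly) fills the lumen leaves no flow path
        geo = cm.VesselCatheterGeometry(
            vessel_diameter=1.0,
            catheter_outer_diameter=0.98,
            catheter_inner_diameter=0.5,
            wire_diameter=0.36,
            wire_placement=cm.WirePlacement.INSIDE,
        )
        with pytest.raises(GeometryError):
            velocity_snapshot(geo, _protocol(), t=0.0)


class TestInjectionSources:
    def test_side_hole_split(self):
        p = _protocol(rate=15.0)
        srcs = injection_sources(cm.VesselCatheterGeometry.for_catheter(p.catheter), p)
        assert len(srcs) == 4
        assert all(s.flow_ml_min == pytest.approx(3.75) for s in srcs)
        az = sorted(s.azimuth_rad for s in srcs)
        assert np.allclose(np.diff(az), np.pi / 2)

    def test_end_hole_single_source(self):
        p = _protocol(rate=20.0, category="HIGH", catheter=CatheterType.END_HOLE)
        srcs = injection_sources(cm.VesselCatheterGeometry.for_catheter(p.catheter), p)
        assert len(srcs) == 1
        assert srcs[0].flow_ml_min == pytest.approx(20.0)

    @pytest.mark.parametrize("catheter", list(CatheterType))
    def test_total_injected_flow_conserved(self, catheter):
        p = _protocol(catheter=catheter)
        srcs = injection_sources(cm.VesselCatheterGeometry.for_catheter(catheter), p)
        assert sum(s.flow_ml_min for s in srcs) == pytest.approx(p.infusion_rate)


class TestSimulate:
    def test_zero_infusion_stays_at_blood_temperature(self):
        p = _protocol(category="LOW", rate=0.0)
        f = cm.simulate(p, resolution=COARSE)
        lumen = ~np.isnan(f.temperature)
        assert np.allclose(f.temperature[lumen], p.blood_temperature, atol=1e-9)

    def test_scalar_boundedness(self, side_med15_field, end_med15_field):
        for f in (side_med15_field, end_med15_field):
            assert np.nanmin(f.temperature) >= f.protocol.infusate_exit_temperature - 1e-9
            assert np.nanmax(f.temperature) <= f.protocol.blood_temperature + 1e-9

    def test_times_span_the_simulated_cycles(self, side_med15_field):
        f = side_med15_field
        assert f.times[0] == 0.0
        assert f.times[-1] >= (f.n_cycles - 1) * f.period
        assert len(f.last_cycle_indices()) >= 2

    def test_outlet_mixed_cup_matches_energy_balance(self, side_med15_field):
        f = side_med15_field
        tmix = cm.perfect_mix_temperature(f.protocol)
        contrast = f.protocol.blood_temperature - tmix
        assert abs(f.mixed_cup_temperature() - tmix) <= 0.01 * contrast

    def test_determinism(self):
        p = _protocol(category="LOW", rate=8.0)
        res = SolverResolution(n_axial=21, n_radial=6, n_angular=8, snapshots_per_cycle=8)
        f1 = cm.simulate(p, resolution=res)
        f2 = cm.simulate(p, resolution=res)
        assert np.array_equal(
            np.nan_to_num(f1.temperature), np.nan_to_num(f2.temperature)
        )

    def test_grid_refinement_smoke(self, end_med15_field):
        """Halving the grid spacing moves prox SD_t by less than 15%."""
        fine = cm.simulate(end_med15_field.protocol, resolution=COARSE.refined())
        sd_coarse = cm.station_measures(end_med15_field, 1.2).sd_t
        sd_fine = cm.station_measures(fine, 1.2).sd_t
        assert abs(sd_fine - sd_coarse) / sd_coarse < 0.15


class TestVirtualPullback:
    def test_uniform_field_gives_constant_trace(self):
        p = _protocol(category="LOW", rate=0.0)
        f = cm.simulate(p, resolution=COARSE)
        tr = virtual_pullback(f, duration_s=20.0)
        assert np.allclose(tr.temperature, p.blood_temperature, atol=1e-6)

    def test_duration_is_a_reparametrization(self):
        # on a steady (non-pulsatile) field the pullback speed is a pure
        # kinematic reparametrization: 15 s and 30 s recordings normalize
        # to the same temperature-vs-position profile
        from coromix.pullback import resample_to_n

        f = cm.simulate(_protocol(), resolution=COARSE, pulsatility=0.0)
        t15 = virtual_pullback(f, duration_s=15.0, sample_rate_hz=20.0)
        t30 = virtual_pullback(f, duration_s=30.0, sample_rate_hz=20.0)
        a = resample_to_n(t15, 500).temperature
        b = resample_to_n(t30, 500).temperature
        assert np.abs(a - b).max() < 0.02

    def test_end_hole_trace_colder_near_tip(self, end_med15_field):
        tr = virtual_pullback(end_med15_field, duration_s=20.0, radial_offset_mm=0.0)
        near_tip = tr.temperature[tr.position_cm < 0.5].mean()
        distal = tr.temperature[tr.position_cm > 5.0].mean()
        assert near_tip < distal - 1.0

    def test_path_outside_lumen_rejected(self, side_med15_field):
        with pytest.raises(GeometryError):
            virtual_pullback(side_med15_field, radial_offset_mm=2.5)

    def test_noise_is_seeded(self, side_med15_field):
        a = virtual_pullback(side_med15_field, noise_sd=0.05, seed=7)
        b = virtual_pullback(side_med15_field, noise_sd=0.05, seed=7)
        c = virtual_pullback(side_med15_field, noise_sd=0.05, seed=8)
        assert np.array_equal(a.temperature, b.temperature)
        assert not np.array_equal(a.temperature, c.temperature)
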