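"""Quemada rheology, Rabinowitsch-Mooney inversion, waveforms, WSS series."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import graftgauge as gg
from graftgauge import hemodynamics as hd
from graftgauge import mesh_geometry as mg


class TestQuemadaViscosity:
    def test_zero_hematocrit_gives_plasma_viscosity(self):
        rheo = hd.RheologyParams(hematocrit=0.0)
        for rate in (0.0, 1.0, 1e4):
            assert hd.quemada_viscosity(rate, rheo) == pytest.approx(1.2e-3)

    def test_equal_intrinsic_viscosities_are_newtonian(self):
        rheo = hd.RheologyParams(k0=2.0, k_inf=2.0, hematocrit=0.4)
        expected = 1.2e-3 / (1 - 0.4) ** 2
        for rate in (0.1, 10.0, 1e5):
            assert hd.quemada_viscosity(rate, rheo) == pytest.approx(expected)

    def test_high_shear_limit(self):
        rheo = hd.RheologyParams()
        limit = rheo.plasma_viscosity * (1 - 0.5 * rheo.k_inf * rheo.hematocrit) ** -2
        assert hd.quemada_viscosity(1e6 * rheo.gamma_c, rheo) == pytest.approx(
            limit, rel=5e-3
        )

    @given(
        lo=st.floats(min_value=0.01, max_value=1e3),
        factor=st.floats(min_value=1.01, max_value=100.0),
    )
    def test_shear_thinning_is_strictly_decreasing(self, lo, factor):
        rheo = hd.RheologyParams()
        assert hd.quemada_viscosity(lo * factor, rheo) < hd.quemada_viscosity(lo, rheo)

    def test_invalid_rheology_rejected(self):
        with pytest.raises(hd.HemodynamicsError):
            hd.RheologyParams(k_inf=5.5, k0=6.0, hematocrit=0.4).validate()
        with pytest.raises(hd.HemodynamicsError):
            hd.RheologyParams(hematocrit=1.2).validate()


class TestWallShearSolver:
    def test_newtonian_limit_matches_poiseuille(self, newtonian_rheology):
        mu = hd.quemada_viscosity(1.0, newtonian_rheology)
        q, radius = 1e-5, 0.01
        expected = 4 * mu * q / (np.pi * radius**3)
        assert hd.wall_shear_stress_tube(q, radius, newtonian_rheology) == pytest.approx(
            expected, rel=5e-3
        )

    def test_zero_flow_gives_zero_stress(self):
        assert hd.wall_shear_stress_tube(0.0, 0.01) == 0.0

    def test_power_law_matches_closed_form(self):
        consistency, exponent = 0.01, 0.7
        fluid = hd.PowerLawFluid(consistency, exponent)
        q, radius = 1e-5, 0.01
        expected = consistency * (
            (3 * exponent + 1) / (4 * exponent) * 4 * q / (np.pi * radius**3)
        ) ** exponent
        assert hd.wall_shear_stress_tube(q, radius, fluid) == pytest.approx(
            expected, rel=0.01
        )

    @given(q=st.floats(min_value=1e-8, max_value=1e-3))
    def test_stress_increases_with_flow(self, q):
        low = hd.wall_shear_stress_tube(q, 0.01)
        high = hd.wall_shear_stress_tube(2.0 * q, 0.01)
        assert high > low

    @given(c=st.floats(min_value=1.0, max_value=50.0))
    def test_shear_thinning_sublinear_scaling(self, c):
        base = hd.wall_shear_stress_tube(1e-5, 0.01)
        scaled = hd.wall_shear_stress_tube(c * 1e-5, 0.01)
        assert scaled <= c * base * (1 + 1e-9)

    def test_negative_flow_rejected(self):
        with pytest.raises(hd.HemodynamicsError):
            hd.wall_shear_stress_tube(-1e-5, 0.01)


class TestWaveforms:
    def test_flat_is_constant_at_peak(self):
        wf = hd.make_waveform("flat", peak_velocity=0.4)
        assert np.all(wf.velocities == 0.4)

    def test_sharp_duty_cycle_bounds_the_mean(self):
        wf = hd.make_waveform("sharp", peak_velocity=0.4, n_samples=512)
        assert wf.velocities.max() == pytest.approx(0.4, rel=1e-3)
        assert wf.velocities.mean() < 0.4 * 0.5

    def test_real_has_exactly_one_reverse_interval(self):
        wf = hd.make_waveform("real", n_samples=512)
        negative = wf.velocities < 0
        starts = np.sum(negative[1:] & ~negative[:-1]) + int(negative[0])
        assert starts == 1

    def test_unknown_kind_rejected(self):
        with pytest.raises(hd.HemodynamicsError):
            hd.make_waveform("square")

    def test_period_property(self):
        wf = hd.make_waveform("flat", period=0.8, n_samples=64)
        assert wf.period == pytest.approx(0.8)


class TestTubeReduction:
    def test_cylinder_radii(self):
        mesh = gg.make_cylinder_mesh(10.0, 100.0, segments=(96, 32))
        tube = hd.tube_from_mesh(mesh, n_stations=10)
        assert tube.radii == pytest.approx(10.0, rel=0.01)
        assert tube.inlet_radius == pytest.approx(10.0, rel=0.01)

    def test_aaa_sac_radius_recovered(self, anatomy):
        tube = hd.tube_from_mesh(gg.make_aaa_mesh(anatomy), n_stations=41)
        mid = np.argmin(np.abs(tube.stations - anatomy.sac_center_frac * anatomy.height))
        assert tube.radii[mid] == pytest.approx(anatomy.sac_radius, rel=0.02)

    def test_bifurcated_equivalent_radius_sums_limb_areas(self, anatomy):
        from dataclasses import replace

        params = replace(anatomy, limb_radius=7.0, neck_radius=10.0, sac_radius=27.5)
        mesh = gg.make_stentgraft_mesh(params, "short")
        tube = hd.tube_from_mesh(mesh, n_stations=30)
        bottom = tube.radii[-1]
        assert bottom == pytest.approx(np.sqrt(2) * 7.0, rel=0.02)


class TestWSSSeries:
    def test_flat_waveform_on_uniform_tube_is_constant(self, newtonian_rheology):
        tube = hd.CenterlineTube(
            stations=np.linspace(0, 100, 20), radii=np.full(20, 10.0), inlet_radius=10.0
        )
        series = hd.wss_series(tube, hd.make_waveform("flat"), newtonian_rheology)
        assert np.ptp(series.wss) <= 1e-12 * series.wss.max()
        single = hd.wall_shear_stress_tube(
            0.5 * np.pi * 0.01**2, 0.01, newtonian_rheology
        )
        assert series.wss[0] == pytest.approx(single, rel=1e-6)

    def test_aneurysm_lowers_mean_wss_vs_neck_cylinder(self, anatomy, newtonian_rheology):
        aaa_tube = hd.tube_from_mesh(gg.make_aaa_mesh(anatomy), n_stations=30)
        neck = gg.make_cylinder_mesh(anatomy.neck_radius, anatomy.height, (96, 32))
        neck_tube = hd.tube_from_mesh(neck, n_stations=30)
        wf = hd.make_waveform("flat")
        wss_aaa = hd.wss_total(hd.wss_series(aaa_tube, wf, newtonian_rheology))
        wss_neck = hd.wss_total(hd.wss_series(neck_tube, wf, newtonian_rheology))
        assert wss_aaa < wss_neck

    def test_newtonian_series_is_linear_in_velocity(self, anatomy, newtonian_rheology):
        tube = hd.tube_from_mesh(gg.make_aaa_mesh(anatomy), n_stations=20)
        low = hd.wss_series(tube, hd.make_waveform("sharp", peak_velocity=0.3), newtonian_rheology)
        high = hd.wss_series(tube, hd.make_waveform("sharp", peak_velocity=0.6), newtonian_rheology)
        assert high.wss == pytest.approx(2.0 * low.wss, rel=1e-6)

    def test_reverse_flow_enters_as_magnitude(self, newtonian_rheology):
        tube = hd.CenterlineTube(
            stations=np.linspace(0, 100, 5), radii=np.full(5, 10.0), inlet_radius=10.0
        )
        series = hd.wss_series(tube, hd.make_waveform("real"), newtonian_rheology)
        assert np.all(series.wss >= 0)
        assert series.wss[np.abs(hd.make_waveform("real").velocities).argmax()] > 0


class TestAggregation:
    def test_constant_series_average(self):
        series = hd.WSSSeries(times=np.arange(8) * 0.1, wss=np.full(8, 5.0), dt=0.1)
        assert hd.wss_total(series) == 5.0

    def test_two_step_mean(self):
        series = hd.WSSSeries(times=np.array([0.0, 0.5]), wss=np.array([2.0, 4.0]), dt=0.5)
        assert hd.wss_total(series) == pytest.approx(3.0)

    def test_matches_trapezoid_time_integral(self):
        n = 512
        t = np.arange(n) / n
        wss = 3.0 + 2.0 * (1 - np.cos(2 * np.pi * t)) / 2
        series = hd.WSSSeries(times=t, wss=wss, dt=1.0 / n)
        t_closed = np.append(t, 1.0)
        wss_closed = np.append(wss, wss[0])  # periodic closure
        oracle = np.trapezoid(wss_closed, t_closed) / 1.0
        assert hd.wss_total(series) == pytest.approx(oracle, rel=1e-3)

    def test_drag_force_unit_conversion(self):
        series = hd.WSSSeries(times=np.arange(8) * 0.1, wss=np.full(8, 1.0), dt=0.1)
        assert hd.drag_force(series, 1e6) == pytest.approx(1.0)  # 1 Pa x 1 m^2
        series300 = hd.WSSSeries(times=np.arange(8) * 0.1, wss=np.full(8, 300.0), dt=0.1)
        assert hd.drag_force(series300, 1e4) == pytest.approx(3.0)  # 0.01 m^2

    def test_zero_flow_series_zero_force(self, newtonian_rheology):
        tube = hd.CenterlineTube(
            stations=np.linspace(0, 10, 5), radii=np.full(5, 10.0), inlet_radius=10.0
        )
        wf = hd.VelocityWaveform(
            times=np.arange(8) * 0.125, velocities=np.zeros(8), kind="custom"
        )
        series = hd.wss_series(tube, wf, newtonian_rheology)
        assert hd.drag_force(series, 100.0) == 0.0
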