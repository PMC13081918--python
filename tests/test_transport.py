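import math

import numpy as np
import pytest
from scipy.special import erfc, erfcx

from organoflow import (
    ChamberGeometry,
    FluidProperties,
    PulseProtocol,
    TransportParams,
    advance,
    build_grid,
    default_chamber_rois,
    extract_roi_timeseries,
    inlet_concentration,
    mass_balance_report,
    peclet_number,
    pump_active,
    run_chamber_simulation,
    simulate_transport,
    solve_flow,
    stability_limits,
)
from organoflow.errors import GeometryError, StabilityError
from organoflow.rois import Disc, ROISet
from organoflow.transport import ConcentrationHistory

from helpers import channel_grid, closed_box_grid, plug_flow, zero_flow


class TestPulseProtocol:
    def test_default_schedule_concentrations(self):
        # 50 nM held while the pump runs, clean chamber (0) in between
        params = TransportParams(pulse_duration=14.0)
        proto = PulseProtocol.from_params(params)
        assert inlet_concentration(5.0, proto) == 50.0       # inside first pulse
        assert inlet_concentration(15.0, proto) == 0.0       # pump off
        assert inlet_concentration(300.0, proto) == 50.0     # second pulse begins
        assert pump_active(5.0, proto) and not pump_active(15.0, proto)

    def test_event_count_covers_run(self):
        proto = PulseProtocol.from_params(TransportParams())
        assert len(proto.events) == math.ceil(4000.0 / 300.0)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError):
            PulseProtocol(((0.0, 20.0, 50.0), (10.0, 20.0, 50.0)))

    def test_negative_time_rejected(self):
        proto = PulseProtocol.from_params(TransportParams())
        with pytest.raises(ValueError):
            inlet_concentration(-1.0, proto)


class TestStabilityLimits:
    def test_pure_diffusion_limit_formula(self):
        # u = 0, uniform D -> dt_max = h^2 / (2 d D) with d = 2 dimensions
        h, D = 1e-4, 4e-10
        grid = closed_box_grid(16, 16, h)
        params = TransportParams(D_medium=D, D_organoid=D)
        dt = stability_limits(grid, zero_flow(grid), params)
        assert dt == pytest.approx(h**2 / (4 * D), rel=1e-9)

    def test_doubling_spacing_quadruples_diffusive_limit(self):
        params = TransportParams()
        g1 = closed_box_grid(16, 16, 1e-4)
        g2 = closed_box_grid(16, 16, 2e-4)
        r = stability_limits(g2, zero_flow(g2), params) / stability_limits(
            g1, zero_flow(g1), params)
        assert r == pytest.approx(4.0, rel=1e-9)

    def test_larger_speed_never_increases_dt(self):
        grid = channel_grid(32, 8, 2e-3, 0.5e-3)
        params = TransportParams()
        dts = [stability_limits(grid, plug_flow(grid, u), params)
               for u in (0.0, 1e-4, 1e-3, 1e-2)]
        assert all(a >= b for a, b in zip(dts, dts[1:]))

    def test_advance_rejects_unstable_dt(self):
        grid = closed_box_grid(16, 16, 1e-4)
        params = TransportParams()
        dt = stability_limits(grid, zero_flow(grid), params)
        with pytest.raises(StabilityError):
            advance(np.zeros((16, 16)), grid, zero_flow(grid), params, dt * 2)


class TestAdvance:
    def test_uniform_field_pure_diffusion_unchanged(self):
        grid = closed_box_grid(16, 12, 1e-4)
        params = TransportParams()
        c0 = np.full((16, 12), 7.5)
        dt = 0.5 * stability_limits(grid, zero_flow(grid), params)
        c1 = advance(c0, grid, zero_flow(grid), params, dt)
        assert np.array_equal(c0, c1)

    def test_closed_box_mass_conserved_over_1000_steps(self):
        grid = closed_box_grid(24, 24, 1e-4)
        D = 1e-9
        params = TransportParams(D_medium=D, D_organoid=D, c_inlet=0.0,
                                 flow_gated=False)
        flow = zero_flow(grid)
        dt = 0.9 * stability_limits(grid, flow, params)
        x = (np.arange(24) + 0.5) / 24
        c = 10.0 * np.exp(-((x[:, None] - 0.3) ** 2 + (x[None, :] - 0.6) ** 2) / 0.02)
        m0 = c.sum()
        for _ in range(1000):
            c = advance(c, grid, flow, params, dt)
        assert abs(c.sum() - m0) / m0 <= 1e-6
        assert c.min() >= 0.0

    def test_mirror_symmetry_under_pure_diffusion(self):
        grid = closed_box_grid(32, 24, 1e-4)
        D = 1e-9
        params = TransportParams(D_medium=D, D_organoid=D, c_inlet=0.0,
                                 flow_gated=False, t_end=1.0)
        x = (np.arange(32) + 0.5) / 32
        y = (np.arange(24) + 0.5) / 24
        init = np.exp(-((x[:, None] - 0.5) ** 2 + (y[None, :] - 0.3) ** 2) / 0.01)
        init = init + init[::-1, :]  # mirror-symmetric in x
        dt = 0.9 * stability_limits(grid, zero_flow(grid), params)
        c = init.copy()
        for _ in range(200):
            c = advance(c, grid, zero_flow(grid), params, dt)
        assert np.abs(c - c[::-1, :]).max() <= 1e-10

    def test_front_matches_closed_form_advection_diffusion(self):
        # 1D step released into a uniform stream vs the erfc solution
        nx, ny = 128, 8
        L = 2e-3
        grid = channel_grid(nx, ny, L, L * ny / nx)
        u0, D, c0, t_end = 2e-4, 1e-8, 50.0, 4.0
        params = TransportParams(D_medium=D, D_organoid=D, c_inlet=c0,
                                 pulse_period=2 * t_end, pulse_duration=2 * t_end,
                                 t_end=t_end, flow_gated=False)
        proto = PulseProtocol(((0.0, 2 * t_end, c0),))
        hist = simulate_transport(grid, plug_flow(grid, u0), params, proto,
                                  store_every=t_end)
        num = hist.fields[-1][:, ny // 2]
        x = (np.arange(nx) + 0.5) * grid.hx
        s = 2 * np.sqrt(D * t_end)
        z = (x + u0 * t_end) / s
        exact = 0.5 * c0 * (erfc((x - u0 * t_end) / s)
                            + erfcx(z) * np.exp(u0 * x / D - z * z))
        err = np.linalg.norm(num - exact) / np.linalg.norm(exact)
        assert err <= 0.05


@pytest.fixture(scope="module")
def small_setup():
    geo = ChamberGeometry(organoid_center=(1.3e-3, 2.5e-3))
    grid = build_grid(geo, 28)
    flow = solve_flow(grid, FluidProperties(), 5e-3,
                      out_of_plane_depth=geo.well_diameter)
    return geo, grid, flow


class TestSimulateTransport:
    def test_zero_inlet_concentration_keeps_field_zero(self, small_setup):
        _, grid, flow = small_setup
        params = TransportParams(c_inlet=0.0, t_end=300.0)
        hist = simulate_transport(grid, flow, params, store_every=100.0)
        assert not hist.fields.any()

    def test_snapshot_cadence_matches_request(self, small_setup):
        _, grid, flow = small_setup
        params = TransportParams(t_end=1200.0)
        hist = simulate_transport(grid, flow, params, store_every=600.0)
        assert list(hist.times) == [0.0, 600.0, 1200.0]

    def test_fields_respect_maximum_principle(self, small_setup):
        _, grid, flow = small_setup
        params = TransportParams(t_end=900.0)
        hist = simulate_transport(grid, flow, params, store_every=300.0)
        assert hist.fields.min() >= 0.0
        assert hist.fields.max() <= 50.0 * (1 + 1e-9)

    def test_mass_balance_closure(self, small_setup):
        _, grid, flow = small_setup
        params = TransportParams(t_end=900.0)
        hist = simulate_transport(grid, flow, params, store_every=300.0)
        assert mass_balance_report(hist, flow, params) <= 0.01

    def test_no_pulses_zero_initial_field_stays_empty(self, small_setup):
        _, grid, flow = small_setup
        params = TransportParams(t_end=100.0)
        proto = PulseProtocol(((0.0, 1e-6, 0.0),))
        hist = simulate_transport(grid, flow, params, proto, store_every=50.0)
        assert hist.total_mass(-1) == 0.0
        assert mass_balance_report(hist, flow, params) == 0.0

    def test_grid_convergence_of_roi_means(self, chamber_run, chamber_series):
        # halving the spacing changes late-run ROI means by <= 5%
        coarse = run_chamber_simulation(resolution=56)
        ts_c = extract_roi_timeseries(coarse.history, coarse.rois)
        for name in ("Top", "Right", "Middle", "Left", "Bottom"):
            a = ts_c.late_mean(name, 3000.0)
            b = chamber_series.late_mean(name, 3000.0)
            assert abs(a - b) / abs(b) <= 0.05


class TestROIExtraction:
    def make_history(self, field):
        nx, ny = field.shape
        grid = closed_box_grid(nx, ny, 1e-4)
        return ConcentrationHistory(grid=grid, times=np.array([0.0, 1.0]),
                                    fields=np.stack([field, field]))

    def test_uniform_field_means(self):
        hist = self.make_history(np.full((40, 40), 3.25))
        rois = ROISet({"a": Disc(2e-3, 2e-3, 0.5e-3)})
        ts = extract_roi_timeseries(hist, rois)
        assert np.allclose(ts.means["a"], 3.25)
        assert ts.mins["a"] == ts.maxs["a"] == 3.25

    def test_linear_field_mean_equals_centroid_value(self):
        nx = ny = 40
        h = 1e-4
        x = (np.arange(nx) + 0.5) * h
        slope = 2.0e4
        field = np.broadcast_to(slope * x[:, None], (nx, ny)).copy()
        hist = self.make_history(field)
        rois = ROISet({"a": Disc(1.2e-3, 2.0e-3, 0.4e-3),
                       "b": Disc(2.9e-3, 1.1e-3, 0.4e-3)})
        ts = extract_roi_timeseries(hist, rois)
        assert ts.means["a"][0] == pytest.approx(slope * 1.2e-3, abs=slope * h)
        assert ts.means["b"][0] == pytest.approx(slope * 2.9e-3, abs=slope * h)

    def test_roi_outside_domain_rejected(self):
        hist = self.make_history(np.zeros((40, 40)))
        with pytest.raises(GeometryError):
            extract_roi_timeseries(hist, ROISet({"a": Disc(5e-3, 2e-3, 0.5e-3)}))

    def test_default_layout_names(self):
        rois = default_chamber_rois(ChamberGeometry(organoid_center=(1.3e-3, 2.5e-3)))
        assert set(rois) == {"Top", "Bottom", "Left", "Right", "Middle", "Center"}


class TestDimensionlessNumbers:
    def test_peclet_device_value(self):
        # u L / D = 5e-3 * 5.6e-3 / 4e-10 = 7e4: strongly advection-dominated
        pe = peclet_number(TransportParams(), 5.6e-3, 5e-3)
        assert pe == pytest.approx(7.0e4, rel=1e-9)

    def test_peclet_scaling_invariance(self):
        p1 = TransportParams(D_medium=4e-10)
        p2 = TransportParams(D_medium=4e-9)
        assert peclet_number(p1, 1e-3, 1e-3) == pytest.approx(
            peclet_number(p2, 1e-3, 1e-2), rel=1e-12)

    def test_peclet_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            peclet_number(TransportParams(), -1.0, 1.0)
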