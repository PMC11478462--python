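"""Pulsatile flow, bubble properties, radiation force, trapping dynamics."""

import numpy as np
import pytest
import sympy

from sonotrap.mbtrap import (FlowModel, Microbubble, gorkov_factors,
                             mb_density, pulsatile_velocity, radiation_force,
                             simulate_trapping, vessel_antinodes)
from sonotrap.wavesim import PressureField


class TestPulsatile:
    def test_t0_is_1383_vmin(self):
        flow = FlowModel(vmin=0.5, vmax=1.54)
        assert pulsatile_velocity(0.0, flow) == pytest.approx(13.83 * 0.5,
                                                              abs=1e-6)

    def test_term_by_term_symbolic_substitution(self):
        """Every printed term re-evaluated independently through sympy."""
        t = sympy.Float("0.37", 30)
        vmin = sympy.Float("0.5", 30)
        vmax = sympy.Float("1.54", 30)
        s2 = sympy.sin(2 * sympy.pi * t)
        s1 = sympy.sin(sympy.pi * t)
        # round(t - 0.5) = round(-0.13) = 0 under half-away-from-zero
        rounded = sympy.Integer(0)
        expr = (13.83 * vmin + 1.383 * (vmax - vmin) * (
            3 * s2 ** 2 + sympy.Abs(s2) * s2 + s1 ** 2
            + 42 * (s2 + sympy.Abs(s2)) * sympy.exp(-20 * (t - rounded))
            * sympy.Float("1.35", 30) / (1 + sympy.exp(130 * t + 10))))
        want = float(sympy.N(expr, 30))
        got = pulsatile_velocity(0.37, FlowModel(vmin=0.5, vmax=1.54))
        assert got == pytest.approx(want, abs=1e-9)

    def test_periodicity_under_round_convention(self):
        flow = FlowModel()
        t = np.arange(0.0, 2.0, 0.001)
        dev = np.abs(pulsatile_velocity(t, flow)
                     - pulsatile_velocity(t + 1.0, flow))
        assert dev.max() < 1e-3

    def test_normalized_mode_spans_vmin_vmax(self):
        flow = FlowModel(vmin=0.5, vmax=1.54)
        t = np.linspace(0, 1, 2001)
        v = pulsatile_velocity(t, flow, mode="normalized")
        assert v.min() == pytest.approx(0.5, abs=1e-6)
        assert v.max() == pytest.approx(1.54, abs=1e-6)


class TestBubbleProperties:
    def test_density_limits(self):
        assert mb_density(1050.0, 0.0) == 0.0
        assert mb_density(1050.0, 1.0) == 1050.0

    def test_thin_shell_value(self):
        # 50 nm shell on a 10 um bubble
        assert mb_density(1050.0, 0.005) == pytest.approx(15.67, abs=0.01)

    def test_strictly_increasing_in_tau(self):
        taus = np.linspace(0.001, 1.0, 300)
        rho = [mb_density(1050.0, t) for t in taus]
        assert np.all(np.diff(rho) > 0)

    def test_tau_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mb_density(1050.0, 1.2)

    def test_acf_threshold_exactness(self):
        low = Microbubble(radius_um=10.0, shell_thickness_um=0.999)
        high = Microbubble(radius_um=10.0, shell_thickness_um=1.001)
        assert low.tau == pytest.approx(0.0999, abs=1e-6)
        assert low.acf_sign == -1
        assert high.acf_sign == +1

    def test_default_bubble_matches_study(self):
        mb = Microbubble()
        assert mb.tau == pytest.approx(0.005)
        assert mb.mean_density == pytest.approx(15.67, abs=0.01)
        assert mb.acf_sign == -1


def standing_wave_field(P=5000.0, lam=1.5, h=0.005, width=12.0, height=1.0):
    """p = P cos(kx), cell-centred so sampling positions are exact."""
    k = 2 * np.pi / lam
    x = np.arange(0, width, h) + h / 2
    y = np.arange(0, height, h) + h / 2
    xx, _ = np.meshgrid(x, y)
    return PressureField((P * np.cos(k * xx)).astype(complex), h, (0.0, 0.0))


class TestRadiationForce:
    def test_matches_standing_wave_closed_form(self):
        lam = 1.5
        k_m = 2 * np.pi / lam * 1e3
        P = 5000.0
        fld = standing_wave_field(P=P, lam=lam)
        mb = Microbubble()
        f1, f2 = gorkov_factors(mb)
        e_ac = P ** 2 / (4 * 1000.0 * 1500.0 ** 2)
        xs = np.array([0.31, 0.94, 1.62, 2.48, 3.05])
        got = np.array([radiation_force(fld, mb, position=(x, 0.5))[0]
                        for x in xs])
        want = (4 * np.pi / 3) * (f1 + 1.5 * f2) * k_m * mb.radius_m ** 3 \
            * e_ac * np.sin(2 * np.pi * 2 * xs / lam)
        assert np.all(np.abs(got - want) <= 0.01 * np.abs(want))

    def test_zero_at_antinode(self):
        fld = standing_wave_field()
        mb = Microbubble()
        f = radiation_force(fld, mb, position=(1.5, 0.5))  # cos peak at x=1.5
        assert abs(f[0]) < 1e-3 * np.abs(
            radiation_force(fld, mb, position=(1.2, 0.5))[0])

    def test_negative_acf_pulled_back_to_antinode(self):
        fld = standing_wave_field()
        mb = Microbubble()          # tau = 0.005 < 0.10
        assert mb.acf_sign == -1
        # antinode at x = 1.5 (cos(k x) extremum); displaced slightly right
        f = radiation_force(fld, mb, position=(1.7, 0.5))
        assert f[0] < 0

    def test_positive_acf_seeks_node(self):
        fld = standing_wave_field()
        thick = Microbubble(radius_um=10.0, shell_thickness_um=2.0)
        assert thick.acf_sign == +1
        f = radiation_force(fld, thick, position=(1.7, 0.5))
        assert f[0] > 0

    def test_outside_field_rejected(self):
        fld = standing_wave_field()
        with pytest.raises(ValueError, match="outside"):
            radiation_force(fld, Microbubble(), position=(50.0, 0.5))


class TestSimulateTrapping:
    def test_field_off_pure_advection(self):
        flow = FlowModel()
        res = simulate_trapping(None, flow, 5, dt=1e-3, t_end=0.05, seed=2,
                                vessel_y=10.0, x_range=(0.0, 1.0),
                                gravity=False)
        dy = res.positions[-1][:, 1] - res.positions[0][:, 1]
        dx = res.positions[-1][:, 0] - res.positions[0][:, 0]
        assert np.allclose(dy, 0.0)
        assert np.all(dx > 0)

    def test_seeded_determinism(self):
        flow = FlowModel()
        runs = [simulate_trapping(None, flow, 6, dt=1e-3, t_end=0.03, seed=9,
                                  vessel_y=5.0, x_range=(0.0, 1.0))
                for _ in range(2)]
        assert np.array_equal(runs[0].positions, runs[1].positions)

    def test_unstable_step_aborts(self):
        # strong standing wave + large dt: displacement > vessel/10
        fld = standing_wave_field(P=50000.0)
        flow = FlowModel()
        with pytest.raises(RuntimeError, match="unstable"):
            simulate_trapping(fld, flow, 3, dt=0.05, t_end=0.5, seed=0,
                              vessel_y=0.5, x_range=(0.3, 2.7))

    def test_overdamped_settling_with_flow_off(self):
        """Field on, flow off: bubbles come to rest at antinodes."""
        fld = standing_wave_field(P=8000.0)
        quiet = FlowModel(vmin=1e-9, vmax=1e-9)
        res = simulate_trapping(fld, quiet, 6, dt=1e-4, t_end=0.3, seed=4,
                                vessel_y=0.5, x_range=(0.8, 2.2),
                                gravity=False)
        late_step = np.abs(res.positions[-1] - res.positions[-2]).max()
        early_step = np.abs(res.positions[1] - res.positions[0]).max()
        assert late_step < 0.01 * early_step
        # settled positions are antinodes of cos(kx): x = 0.75k ... 1.5, 2.25
        final_x = res.positions[-1][:, 0]
        nearest = np.round(final_x / 0.75) * 0.75
        assert np.all(np.abs(final_x - nearest) < 0.02)

    def test_trajectory_dataframe_schema(self):
        flow = FlowModel()
        res = simulate_trapping(None, flow, 3, dt=1e-3, t_end=0.02, seed=1,
                                vessel_y=2.0, x_range=(0.0, 1.0))
        df = res.to_dataframe()
        assert list(df.columns) == ["time_s", "bubble_id", "x_um", "y_um"]
        assert df["time_s"].min() == 0.0
        assert set(df["bubble_id"]) == {0, 1, 2}


class TestVesselAntinodes:
    def test_standing_wave_antinodes(self):
        fld = standing_wave_field()
        an = vessel_antinodes(fld, 0.5, x_range=(0.3, 5.7))
        # |cos(kx)| maxima every lambda/2 = 0.75 mm
        assert np.allclose(np.diff(an[:, 0]), 0.75, atol=0.02)
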