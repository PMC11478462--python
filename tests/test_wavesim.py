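"""Forward model: eikonal travel times, amplitudes, field synthesis."""

import numpy as np
import pytest

from sonotrap.phantom import build_layered_phantom, place_array
from sonotrap.wavesim import (FieldSynthesizer, SimulationConfig, amplitude_at,
                              collect_sample, load_field, peak_pick,
                              save_field, tof_map)

from .oracles import dijkstra_tof, quadrature_attenuation_db


@pytest.fixture()
def big_water():
    return build_layered_phantom([("water", 100, 1500, 1000, 0)], 0.5,
                                 (100, 100), frequency_mhz=None)


class TestTofMap:
    def test_homogeneous_straight_line(self, big_water):
        tm = tof_map(big_water, (50.0, 10.0))
        # receiver 75 mm away: t = 75 mm / 1.5 mm/us = 50 us
        got = tm.at((50.0, 85.0))[0]
        assert got == pytest.approx(50.0, rel=5e-3)

    def test_monotone_along_ray(self, big_water):
        tm = tof_map(big_water, (50.0, 10.0))
        ys = np.linspace(12, 95, 60)
        times = tm.at(np.column_stack([np.full_like(ys, 50.0), ys]))
        assert np.all(np.diff(times) > 0)

    def test_source_outside_rejected(self, big_water):
        with pytest.raises(ValueError, match="outside"):
            tof_map(big_water, (500.0, 10.0))

    def test_two_layer_oblique_vs_dijkstra(self):
        tm = build_layered_phantom([("a", 20, 1500, 1000, 0),
                                    ("b", 20, 1600, 1050, 0)],
                                   0.25, (40, 40), frequency_mhz=None)
        src = (8.0, 4.0)
        receivers = np.array([[32.0, 36.0], [20.0, 38.0], [36.0, 22.0]])
        sol = tof_map(tm, src)
        got = sol.at(receivers)
        want = dijkstra_tof(tm, src, receivers)
        assert np.all(np.abs(got - want) / want < 0.01)

    def test_reciprocity(self):
        tm = build_layered_phantom([("a", 15, 1500, 1000, 0),
                                    ("b", 15, 1580, 1050, 0)],
                                   0.1, (30, 30), frequency_mhz=None)
        a, b = (6.0, 5.0), (24.0, 27.0)
        t_ab = tof_map(tm, a).at(b)[0]
        t_ba = tof_map(tm, b).at(a)[0]
        # bound: the measured first-order solver tolerance on 0.1 mm grids
        assert abs(t_ab - t_ba) < 5e-3


class TestAmplitude:
    def test_cylindrical_spreading_ratio(self, big_water):
        cfg = SimulationConfig(spreading_exponent=0.5)
        a1 = amplitude_at(big_water, (50, 10), (50, 20), 1000.0, cfg)
        a4 = amplitude_at(big_water, (50, 10), (50, 50), 1000.0, cfg)
        assert a1 / a4 == pytest.approx(2.0, rel=1e-6)

    def test_db_definition_over_100mm(self):
        tm = build_layered_phantom([("t", 110, 1500, 1000, 0.5)], 0.5,
                                   (30, 110), frequency_mhz=None)
        cfg = SimulationConfig(spreading_exponent=0.0)
        a = amplitude_at(tm, (15, 2), (15, 102), 1.0, cfg)
        assert a == pytest.approx(10 ** (-5 / 20), rel=1e-6)

    def test_piecewise_alpha_matches_fine_quadrature(self):
        tm = build_layered_phantom([("a", 12, 1500, 1000, 0.35),
                                    ("b", 12, 1500, 1000, 0.9),
                                    ("c", 16, 1500, 1000, 0.5)],
                                   0.2, (40, 40), frequency_mhz=None)
        src, rec = (5.0, 3.0), (35.0, 37.0)
        cfg = SimulationConfig(spreading_exponent=0.0)
        got = amplitude_at(tm, src, rec, 1.0, cfg)
        db = quadrature_attenuation_db(tm, src, rec, 1.0, n_steps=5000)
        assert got == pytest.approx(10 ** (-db / 20), rel=1e-3)

    def test_zero_separation_rejected(self, big_water):
        with pytest.raises(ValueError):
            amplitude_at(big_water, (50, 50), (50, 50), 1000.0)

    def test_linearity_in_source_amplitude(self, big_water):
        a = amplitude_at(big_water, (50, 10), (60, 60), 1000.0)
        b = amplitude_at(big_water, (50, 10), (60, 60), 2000.0)
        assert b == pytest.approx(2 * a, rel=1e-12)


class TestCollectSample:
    def test_mirror_symmetry_on_bisector(self, big_water):
        arr = place_array(big_water, 8, 3.7, 0.5, (50, 6), 0.0)
        smp = collect_sample(big_water, arr, (50.0, 50.0))
        assert np.allclose(smp.tof, smp.tof[::-1], atol=2e-2)
        assert np.allclose(smp.amplitude, smp.amplitude[::-1], rtol=1e-6)

    def test_amplitudes_strictly_positive(self, big_water):
        arr = place_array(big_water, 8, 3.7, 0.5, (50, 6), 0.0)
        smp = collect_sample(big_water, arr, (30.0, 45.0))
        assert np.all(smp.amplitude > 0)

    def test_source_amplitude_linearity_tof_invariance(self, big_water):
        arr = place_array(big_water, 8, 3.7, 0.5, (50, 6), 0.0)
        c1 = SimulationConfig(source_amplitude=1000.0)
        c2 = SimulationConfig(source_amplitude=2000.0)
        s1 = collect_sample(big_water, arr, (40.0, 50.0), c1)
        s2 = collect_sample(big_water, arr, (40.0, 50.0), c2)
        assert np.allclose(s2.amplitude, 2 * s1.amplitude, rtol=1e-12)
        assert np.array_equal(s1.tof, s2.tof)

    def test_reciprocity_route_matches_direct(self, big_water):
        arr = place_array(big_water, 4, 3.7, 0.5, (50, 6), 0.0)
        maps = [tof_map(big_water, c) for c in arr.centers]
        direct = collect_sample(big_water, arr, (44.0, 48.0))
        recip = collect_sample(big_water, arr, (44.0, 48.0),
                               element_tof_maps=maps)
        assert np.allclose(direct.tof, recip.tof, atol=3e-2)


class TestPeakPick:
    def test_half_cycle_sine(self):
        dt = 0.005
        t = np.arange(0, 45, dt)
        w = np.where((t >= 40) & (t <= 40.5),
                     3.0 * np.sin(np.pi * (t - 40) / 0.5), 0.0)
        amp, ts = peak_pick(w, dt)
        assert amp == pytest.approx(3.0, abs=1e-3)
        assert ts == pytest.approx(40.25, abs=dt)

    def test_tie_breaks_to_earliest(self):
        amp, ts = peak_pick(np.ones(100), 0.1)
        assert (amp, ts) == (1.0, 0.0)

    def test_time_shift_equivariance(self):
        dt = 0.01
        w = np.exp(-0.5 * ((np.arange(0, 20, dt) - 7.0) / 0.3) ** 2)
        a0, t0 = peak_pick(w, dt)
        a1, t1 = peak_pick(np.concatenate([np.zeros(500), w]), dt)
        assert a1 == a0
        assert t1 == pytest.approx(t0 + 5.0, abs=dt)

    def test_all_zero_flagged(self):
        with pytest.raises(ValueError, match="no arrival"):
            peak_pick(np.zeros(50), 0.1)


class TestSynthField:
    @pytest.fixture()
    def single_element(self, big_water):
        arr = place_array(big_water, 1, 3.7, 0.5, (50, 6), 0.0)
        return FieldSynthesizer(big_water, arr, SimulationConfig(),
                                directivity=False)

    def test_single_element_phase_law(self, single_element):
        # phase at distance r equals 2 pi (r/c)/T modulo 2 pi
        pts = np.array([[50.0, 30.0], [50.0, 51.0], [62.0, 40.0]])
        tr = single_element.transfer_at(pts)[:, 0]
        r = np.linalg.norm(pts - np.array([50.0, 6.0]), axis=1)
        expect = 2 * np.pi * (r / 1.5) / 1.0
        diff = np.angle(tr * np.exp(-1j * expect))
        assert np.all(np.abs(diff) < 2 * np.pi * 0.01 * (r / 1.5))

    def test_linear_scaling_in_theta(self, single_element):
        f1 = single_element.field(np.array([1000.0 + 0j]),
                                  region=(40, 60, 30, 50), cell_size=0.5)
        f10 = single_element.field(np.array([10000.0 + 0j]),
                                   region=(40, 60, 30, 50), cell_size=0.5)
        assert np.allclose(f10.magnitude, 10 * f1.magnitude, rtol=1e-12)

    def test_actuation_length_checked(self, big_water):
        arr = place_array(big_water, 4, 3.7, 0.5, (50, 6), 0.0)
        synth = FieldSynthesizer(big_water, arr)
        with pytest.raises(ValueError, match="length"):
            synth.field(np.ones(3, dtype=complex))

    def test_field_raster_roundtrip(self, tmp_path, single_element):
        fld = single_element.field(np.array([1000.0 + 0j]),
                                   region=(45, 55, 30, 40), cell_size=0.5)
        save_field(fld, tmp_path / "f.npz")
        back = load_field(tmp_path / "f.npz")
        assert np.allclose(back.complex_pressure, fld.complex_pressure)
        assert back.origin == fld.origin

    def test_global_phase_offset_invariance(self, big_water):
        arr = place_array(big_water, 4, 3.7, 0.5, (50, 6), 0.0)
        synth = FieldSynthesizer(big_water, arr)
        psi = 1000.0 * np.exp(1j * np.array([0.3, 2.1, 4.0, 1.2]))
        f0 = synth.field(psi, region=(40, 60, 35, 55), cell_size=0.5)
        f1 = synth.field(psi * np.exp(1j * 1.234),
                         region=(40, 60, 35, 55), cell_size=0.5)
        assert np.allclose(f1.magnitude, f0.magnitude, rtol=1e-10)
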