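"""Corridor widths, crossover times, displaced paths, weighting functional."""

import numpy as np
import pytest

from blochcorridor.corridor import (
    CorridorWidth,
    arbitrary_path,
    containment_check,
    corridor_rates,
    corridor_width,
    crossover_time,
    reference_phase,
    stereographic,
    stereographic_inverse,
    weighting_functional,
)
from blochcorridor.model import Channel, PauliOp
from blochcorridor.redfield import BlochTrajectory


def single_channel(gam_rows):
    return np.atleast_2d(np.asarray(gam_rows, dtype=float))


class TestCorridorWidth:
    def test_direct_substitution(self):
        # one active channel monitoring x with gamma = 4, S = identity
        gam = np.array([[4.0, 4.0], [0.0, 0.0], [0.0, 0.0]])
        w = corridor_width(gam, np.eye(3))
        assert np.allclose(w.delta_eta[:, 0], 0.5)
        assert np.all(np.isinf(w.delta_eta[:, 1:]))

    def test_zero_rates_give_infinite_width(self):
        w = corridor_width(np.zeros((3, 5)), np.eye(3))
        assert np.all(np.isinf(w.delta_eta))

    def test_homogeneity_doubling_rates(self):
        rng = np.random.default_rng(6)
        gam = rng.uniform(0.5, 2.0, size=(3, 7))
        th = 0.7
        S = np.array(
            [[np.cos(th), 0, -np.sin(th)], [0, 1, 0], [np.sin(th), 0, np.cos(th)]]
        )
        w1 = corridor_width(gam, S)
        w2 = corridor_width(2.0 * gam, S)
        assert np.allclose(w2.delta_eta, w1.delta_eta / np.sqrt(2.0))

    def test_non_unitary_s_rejected(self):
        with pytest.raises(ValueError):
            corridor_width(single_channel([[1.0]]), 2.0 * np.eye(3))


class TestCrossoverTime:
    def test_exponential_width_closed_form(self):
        tau, d0, eps = 2.0, 5.0, 0.1
        t = np.linspace(0, 20, 4001)
        w = CorridorWidth(times=t, delta_eta=np.tile(d0 * np.exp(-t / tau), (3, 1)).T)
        res = crossover_time(w, epsilon=eps)
        want = tau * np.log(d0 / (eps * tau))
        assert res.tau_c[0] == pytest.approx(want, abs=0.02)

    def test_constant_width_crosses_immediately(self):
        t = np.linspace(0, 5, 101)
        w = CorridorWidth(times=t, delta_eta=np.full((101, 3), 2.0))
        res = crossover_time(w, epsilon=0.01)
        assert np.all(res.tau_c == 0.0)

    def test_threshold_below_minimum_slope_not_reached(self):
        t = np.linspace(0, 5, 101)
        w = CorridorWidth(times=t, delta_eta=np.tile(10.0 - t, (3, 1)).T)  # slope -1
        res = crossover_time(w, epsilon=1e-3)
        assert not res.reached().any()


class TestArbitraryPath:
    def test_kappa_zero_reproduces_base(self):
        t = np.linspace(0, 5, 101)
        base = np.stack([np.cos(t), np.sin(t), 0 * t], axis=1)
        fam = arbitrary_path((t, base), 0.0)
        assert np.array_equal(fam.displaced, base)

    def test_constant_base_invariant_for_any_kappa(self):
        t = np.linspace(0, 5, 101)
        base = np.tile([0.1, -0.2, 0.9], (101, 1))
        fam = arbitrary_path((t, base), 20.0)
        assert np.allclose(fam.displaced, base)

    def test_circular_path_displacement_magnitude(self):
        om = 2.0
        t = np.linspace(0, 5, 2001)
        dt = t[1] - t[0]
        base = np.stack([np.cos(om * t), np.sin(om * t), 0 * t], axis=1)
        fam = arbitrary_path((t, base), 5.0)
        mag = np.linalg.norm(fam.displaced - base, axis=1)[10:-10]
        assert np.allclose(mag, 5.0 * dt * om, rtol=1e-3)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            arbitrary_path((np.array([0.0, 0.1]), np.zeros((2, 3))), 1.0)


class TestWeightingFunctional:
    @pytest.fixture()
    def path_and_channels(self):
        t = np.linspace(0, 6, 301)
        base = np.stack([np.sin(0.9 * t) * 0.6, 0.3 * np.cos(t), np.cos(0.9 * t)], axis=1)
        chans = [
            Channel("+", 1.0, PauliOp(0.0, np.array([0.4, -0.2j, 0.0]))),
            Channel("z", 0.0, PauliOp(0.0, np.array([0.0, 0.0, 0.8]))),
        ]
        return t, base, chans

    def test_zero_coupling_weight_is_one(self, path_and_channels):
        t, base, chans = path_and_channels
        fam = arbitrary_path((t, base), 10.0)
        w = weighting_functional(fam, chans, np.zeros((2, len(t))))
        assert np.allclose(w.w_abs, 1.0)

    def test_kappa_zero_is_maximal_and_unity(self, path_and_channels):
        t, base, chans = path_and_channels
        gam = np.full((2, len(t)), 1.3)
        w0 = weighting_functional(arbitrary_path((t, base), 0.0), chans, gam)
        assert np.allclose(w0.w_abs, 1.0)
        for kap in (1.0, 5.0, 20.0):
            wk = weighting_functional(arbitrary_path((t, base), kap), chans, gam)
            assert np.all(wk.w_abs <= w0.w_abs + 1e-12)

    def test_weight_monotone_in_kappa_and_time(self, path_and_channels):
        t, base, chans = path_and_channels
        gam = np.full((2, len(t)), 1.3)
        prev = None
        for kap in (0.0, 1.0, 5.0, 10.0, 20.0):
            w = weighting_functional(arbitrary_path((t, base), kap), chans, gam)
            assert np.all(np.diff(w.w_abs) <= 1e-12)  # non-increasing in time
            assert np.all(w.w_abs >= 0) and np.all(w.w_abs <= 1.0 + 1e-12)
            if prev is not None:
                assert np.all(w.w_abs <= prev + 1e-12)
            prev = w.w_abs

    def test_chi_contribution_is_purely_imaginary(self, path_and_channels):
        t, base, chans = path_and_channels
        gam = np.full((2, len(t)), 0.7)
        w = weighting_functional(arbitrary_path((t, base), 5.0), chans, gam)
        assert w.chi_im.shape == (len(t), 2)  # recorded separately; |w| uses zeta only

    def test_mismatched_grid_rejected(self, path_and_channels):
        t, base, chans = path_and_channels
        fam = arbitrary_path((t, base), 1.0)
        with pytest.raises(ValueError):
            weighting_functional(fam, chans, np.zeros((2, len(t) - 1)))


class TestContainment:
    def test_kappa_zero_fully_contained(self):
        t = np.linspace(0, 5, 101)
        base = np.stack([np.cos(t), np.sin(t), 0 * t], axis=1)
        fam = arbitrary_path((t, base), 0.0)
        width = CorridorWidth(times=t, delta_eta=np.full((101, 3), 0.5))
        contained, frac = containment_check(fam, width)
        assert np.all(frac == 1.0)

    def test_constructed_violation_flagged(self):
        t = np.linspace(0, 5, 101)
        base = np.zeros((101, 3))
        fam = arbitrary_path((t, base), 0.0)
        fam.displaced[:, 1] = 1.0  # deviation = 2 * width
        width = CorridorWidth(times=t, delta_eta=np.full((101, 3), 0.5))
        contained, frac = containment_check(fam, width)
        assert frac[1] == 0.0 and frac[0] == 1.0

    def test_fraction_non_increasing_in_kappa(self):
        t = np.linspace(0, 6, 301)
        base = np.stack([np.cos(2 * t), np.sin(2 * t), 0.2 + 0 * t], axis=1)
        width = CorridorWidth(times=t, delta_eta=np.full((301, 3), 0.15))
        fracs = []
        for kap in (0.0, 5.0, 10.0, 20.0):
            fam = arbitrary_path((t, base), kap)
            fracs.append(containment_check(fam, width)[1].mean())
        assert all(b <= a + 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestStereographic:
    def test_named_points(self):
        assert stereographic(np.array([0.0, 0.0, -1.0])) == pytest.approx((0.0, 0.0))
        assert stereographic(np.array([1.0, 0.0, 0.0])) == pytest.approx((1.0, 0.0))

    def test_roundtrip_on_random_unit_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            if n[2] > 0.999:
                continue
            x, y = stereographic(n)
            assert np.abs(stereographic_inverse(x, y) - n).max() < 1e-12

    def test_north_pole_rejected(self):
        with pytest.raises(ValueError):
            stereographic(np.array([0.0, 0.0, 1.0]))


class TestReferencePhase:
    def test_perpendicular_field_accumulates_no_phase(self):
        t = np.linspace(0, 5, 201)
        path = BlochTrajectory(times=t, n_av=np.tile([0.0, 0.0, 1.0], (201, 1)))
        psi = reference_phase(path, np.array([1.0, 0.0, 0.0]))
        assert np.allclose(psi, 1.0)

    def test_parallel_field_closed_form(self):
        om = 1.3
        t = np.linspace(0, 5, 2001)
        path = BlochTrajectory(times=t, n_av=np.tile([0.0, 0.0, 1.0], (2001, 1)))
        psi = reference_phase(path, np.array([0.0, 0.0, om]))
        assert np.abs(psi - np.exp(-0.5j * om * t)).max() < 1e-6

    def test_unit_modulus(self):
        rng = np.random.default_rng(13)
        t = np.linspace(0, 5, 301)
        n = rng.normal(size=(301, 3))
        psi = reference_phase(BlochTrajectory(times=t, n_av=n), rng.normal(size=3), psi0=0.5j)
        assert np.allclose(np.abs(psi), 0.5)
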