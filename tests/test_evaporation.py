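"""Open-evaporation kinetics: Rayleigh behaviour, attractors, mass logs."""

import numpy as np
import pytest

from azeoblend import (
    MassLog,
    composition_vs_released,
    correct_sampling_losses,
    simulate_open_evaporation,
    tga_mass_curve,
)
from azeoblend.errors import DataIntegrityError, DomainError

from .conftest import make_ideal_vle


class TestSimulateOpenEvaporation:
    def test_azeotrope_is_fixed_point(self, reference_vle):
        traj = simulate_open_evaporation(
            reference_vle, x0=0.77, n0=0.05, rate_constant=2e-5, t_end=300.0
        )
        assert np.abs(traj.x_a - 0.77).max() < 1e-6

    def test_rayleigh_closed_form_for_ideal_binary(self):
        # constant relative volatility alpha = P_a / P_b = 2
        vle = make_ideal_vle(p_a=10.0, p_b=5.0)
        traj = simulate_open_evaporation(
            vle, x0=0.4, n0=1.0, rate_constant=1e-3, t_end=60.0, rtol=1e-10
        )
        na, nb = traj.moles_a, traj.moles_b
        keep = (na > 1e-6) & (nb > 1e-6)
        lhs = np.log(na[keep] / na[0])
        rhs = 2.0 * np.log(nb[keep] / nb[0])
        assert np.abs(lhs - rhs).max() < 1e-6

    @pytest.mark.parametrize("x0", [0.40, 0.60, 0.90])
    def test_compositions_approach_attractor_monotonically(self, reference_vle, x0):
        traj = simulate_open_evaporation(
            reference_vle, x0=x0, n0=0.065, rate_constant=2e-5, t_end=1000.0
        )
        gap = np.abs(traj.x_a - 0.77)
        # the distance to the attractor never grows beyond integrator noise
        # (sub-1e-6 wiggles appear right at the mole floor)
        assert np.all(np.diff(gap) < 1e-6)
        assert gap[-1] < 1e-3

    def test_composition_below_positive_azeotrope_drifts_to_pure_b(self, reference_vle):
        traj = simulate_open_evaporation(
            reference_vle, x0=0.05, n0=0.05, rate_constant=2e-5, t_end=1000.0
        )
        assert traj.x_a[-1] < 1e-3

    def test_mass_balance(self, reference_vle):
        traj = simulate_open_evaporation(
            reference_vle, x0=0.5, n0=0.05, rate_constant=2e-5, t_end=100.0
        )
        m = traj.mass
        evaporated = m[0] - m
        assert np.all(evaporated >= -1e-9)
        assert traj.released_fraction[-1] == pytest.approx(
            evaporated[-1] / m[0], abs=1e-12
        )

    def test_tolerance_tightening_invariance(self, reference_vle):
        kwargs = dict(x0=0.55, n0=0.05, rate_constant=2e-5, t_end=400.0)
        loose = simulate_open_evaporation(reference_vle, rtol=1e-8, **kwargs)
        tight = simulate_open_evaporation(reference_vle, rtol=1e-9, **kwargs)
        assert abs(loose.x_a[-1] - tight.x_a[-1]) < 1e-6

    def test_invalid_arguments(self, reference_vle):
        with pytest.raises(DomainError):
            simulate_open_evaporation(reference_vle, 1.2, 1.0, 1e-3, 1.0)
        with pytest.raises(DomainError):
            simulate_open_evaporation(reference_vle, 0.5, -1.0, 1e-3, 1.0)
        with pytest.raises(DomainError):
            simulate_open_evaporation(reference_vle, 0.5, 1.0, 0.0, 1.0)


class TestDerivedTables:
    def test_composition_vs_released_constant_trajectory(self, reference_vle):
        traj = simulate_open_evaporation(
            reference_vle, x0=0.77, n0=0.05, rate_constant=2e-5, t_end=100.0
        )
        table = composition_vs_released(traj)
        assert np.all(np.diff(table["released_fraction"]) > 0)
        assert np.abs(table["x_a"] - 0.77).max() < 1e-6

    def test_composition_vs_released_matches_rayleigh(self):
        vle = make_ideal_vle(p_a=10.0, p_b=5.0)
        traj = simulate_open_evaporation(
            vle, x0=0.4, n0=1.0, rate_constant=1e-3, t_end=50.0, rtol=1e-10
        )
        table = composition_vs_released(traj)
        # closed form: n_a = n_a0 w^alpha, n_b = n_b0 w with w = n_b/n_b0
        w = traj.moles_b / traj.moles_b[0]
        na = traj.moles_a[0] * w**2.0
        mass = na * vle.component_a.molar_mass + traj.moles_b * vle.component_b.molar_mass
        released = 1.0 - mass / mass[0]
        x_expected = np.interp(table["released_fraction"], released, na / (na + traj.moles_b))
        assert np.abs(table["x_a"].to_numpy() - x_expected).max() < 1e-6

    def test_tga_ordering_azeotrope_slowest(self, reference_vle):
        # equal initial masses: the azeotrope retains the most liquid
        m0 = 0.085  # g, TGA-scale charge
        curves = {}
        for x0 in (0.77, 1.0, 0.0):
            mbar = (
                x0 * reference_vle.component_a.molar_mass
                + (1 - x0) * reference_vle.component_b.molar_mass
            )
            traj = simulate_open_evaporation(
                reference_vle, x0=x0, n0=m0 / mbar, rate_constant=2e-7, t_end=48.0
            )
            curves[x0] = tga_mass_curve(traj)
        t = curves[0.77]["time_h"].to_numpy()
        az = curves[0.77]["mass_g"].to_numpy()
        for pure in (0.0, 1.0):
            other = np.interp(t, curves[pure]["time_h"], curves[pure]["mass_g"])
            assert np.all(az[1:] > other[1:])

    def test_tga_near_positive_azeotrope_fast_then_acid_like(self, reference_vle):
        m0 = 0.085
        rate = 2e-7
        curves = {}
        for x0 in (0.09, 1.0, 0.0):
            mbar = (
                x0 * reference_vle.component_a.molar_mass
                + (1 - x0) * reference_vle.component_b.molar_mass
            )
            traj = simulate_open_evaporation(
                reference_vle, x0=x0, n0=m0 / mbar, rate_constant=rate, t_end=60.0,
                n_points=1200,
            )
            curves[x0] = traj
        # early mass-loss rate of the 9 mol% mixture exceeds both pure rates
        def early_rate(traj):
            return (traj.mass[0] - np.interp(1.0, traj.times, traj.mass)) / 1.0

        assert early_rate(curves[0.09]) > early_rate(curves[0.0])
        assert early_rate(curves[0.09]) > early_rate(curves[1.0])
        # late slope approaches the pure-acid slope as the liquid drifts to B
        def slope_at(traj, t):
            m = np.interp([t - 0.5, t + 0.5], traj.times, traj.mass)
            return m[0] - m[1]

        t_late = 30.0
        s_mix = slope_at(curves[0.09], t_late)
        s_acid = slope_at(curves[0.0], t_late)
        assert s_mix == pytest.approx(s_acid, rel=0.15)

    def test_zero_rate_not_allowed_but_tiny_rate_near_constant(self, reference_vle):
        traj = simulate_open_evaporation(
            reference_vle, x0=0.5, n0=0.05, rate_constant=1e-15, t_end=10.0
        )
        assert traj.mass[0] == pytest.approx(traj.mass[-1], rel=1e-8)


class TestCorrectSamplingLosses:
    def test_identity_without_aliquots(self):
        log = MassLog(
            times=[0.0, 1.0, 2.0],
            gross_mass=[10.0, 9.8, 9.5],
            aliquot_mass=[0.0, 0.0, 0.0],
        )
        out = correct_sampling_losses(log)
        assert np.allclose(out["evaporative_loss_g"], [0.0, 0.2, 0.5])

    def test_hand_computed_single_aliquot(self):
        log = MassLog(
            times=[0.0, 1.0],
            gross_mass=[10.000, 9.500],
            aliquot_mass=[0.010, 0.0],
        )
        out = correct_sampling_losses(log)
        assert out["evaporative_loss_g"].iloc[-1] == pytest.approx(0.490)

    def test_conservation_at_every_row(self, rng):
        n = 8
        aliquots = rng.uniform(0.0, 0.02, n)
        evap = np.concatenate([[0.0], np.cumsum(rng.uniform(0.05, 0.3, n - 1))])
        gross = 10.0 - evap - np.concatenate([[0.0], np.cumsum(aliquots)[:-1]])
        log = MassLog(times=np.arange(n, dtype=float), gross_mass=gross,
                      aliquot_mass=aliquots)
        out = correct_sampling_losses(log)
        cum_before = np.concatenate([[0.0], np.cumsum(aliquots)[:-1]])
        total = out["evaporative_loss_g"].to_numpy() + cum_before + gross
        assert np.allclose(total, 10.0)

    def test_negative_loss_raises(self):
        log = MassLog(
            times=[0.0, 1.0],
            gross_mass=[10.0, 10.5],  # gross mass increased: impossible
            aliquot_mass=[0.0, 0.0],
        )
        with pytest.raises(DataIntegrityError):
            correct_sampling_losses(log)
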