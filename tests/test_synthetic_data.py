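"""Generators: speciation chemistry, spectra, oven campaign, assay counts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chisquare

from azeoblend import (
    GeneratorConfig,
    SpeciationModel,
    band_intensity,
    find_azeotropes,
    fit_avrami,
    gen_assay_counts,
    gen_mixture_spectrum,
    gen_oven_experiment,
    make_reference_vle,
    mixing_residual,
    relative_absorbance,
    solve_speciation,
)
from azeoblend.evaporation import correct_sampling_losses
from azeoblend.repellence import SigmoidFit


class TestReferenceFixture:
    def test_exactly_two_azeotropes(self, reference_vle):
        points = find_azeotropes(reference_vle)
        assert len(points) == 2

    def test_negative_root_is_attractor_and_pressure_minimum(self, reference_vle):
        neg = [p for p in find_azeotropes(reference_vle) if p.sign == "negative"]
        assert len(neg) == 1
        assert neg[0].stability == "attractor"
        assert neg[0].pressure < reference_vle.p_sat_a
        assert neg[0].pressure < reference_vle.p_sat_b

    def test_packaged_config_matches_builtin_fixture(self):
        from azeoblend import load_run_config, reference_config_path

        cfg = load_run_config(reference_config_path())
        built = make_reference_vle()
        assert cfg.activity.coefficients == built.activity.coefficients
        assert cfg.component_a.antoine == built.component_a.antoine
        assert cfg.component_b.antoine == built.component_b.antoine
        assert cfg.temperature == built.temperature

    def test_liquid_phase_stable(self, reference_vle):
        assert reference_vle.activity.is_liquid_stable()


class TestSolveSpeciation:
    def test_no_association_identity(self):
        s = solve_speciation(0.3, 0.7, SpeciationModel(0.0, 0.0))
        assert s.acid_monomer == pytest.approx(0.3)
        assert s.free_ir == pytest.approx(0.7)
        assert s.acid_dimer == 0.0 and s.complex == 0.0

    @given(st.floats(0.05, 0.95), st.floats(0.1, 200.0))
    def test_dimer_only_matches_quadratic_closed_form(self, x_acid, kd):
        s = solve_speciation(x_acid, 1.0 - x_acid, SpeciationModel(kd, 0.0))
        a_expected = (-1.0 + np.sqrt(1.0 + 8.0 * kd * x_acid)) / (4.0 * kd)
        assert s.acid_monomer == pytest.approx(a_expected, rel=1e-9)

    @given(st.floats(0.0, 1.0))
    def test_mass_balances_close(self, x_acid):
        s = solve_speciation(x_acid, 1.0 - x_acid, SpeciationModel())
        assert s.acid_monomer + 2 * s.acid_dimer + s.complex == pytest.approx(
            x_acid, abs=1e-10
        )
        assert s.free_ir + s.complex == pytest.approx(1.0 - x_acid, abs=1e-10)

    def test_all_fractions_nonnegative(self):
        for x_acid in np.linspace(0, 1, 21):
            s = solve_speciation(x_acid, 1 - x_acid, SpeciationModel())
            assert min(s.acid_monomer, s.acid_dimer, s.free_ir, s.complex) >= 0


class TestGenMixtureSpectrum:
    def test_pure_ir_endpoint_band_positions(self):
        spec = gen_mixture_spectrum(1.0)
        nu = spec.wavenumbers

        def local_peak(w):
            mask = np.abs(nu - w) < 15
            return spec.absorbance[mask].max()

        assert local_peak(1735) > 0.5
        assert local_peak(1638) > 0.3
        assert band_intensity(spec, (900, 960)) < 1e-6  # no acid dimer band

    def test_seed_determinism(self):
        s1 = gen_mixture_spectrum(0.4, noise_sigma=0.002, seed=9)
        s2 = gen_mixture_spectrum(0.4, noise_sigma=0.002, seed=9)
        assert np.array_equal(s1.absorbance, s2.absorbance)

    def test_mixing_residual_sign_pattern(self):
        pure_ir = gen_mixture_spectrum(1.0)
        pure_acid = gen_mixture_spectrum(0.0)
        mix = gen_mixture_spectrum(0.5)
        resid = mixing_residual(mix, pure_ir, pure_acid, 0.5)
        nu = resid.wavenumbers

        def at(w):
            return resid.absorbance[np.argmin(np.abs(nu - w))]

        assert at(1608) > 0
        assert at(1705) < 0
        assert at(1638) < 0

    def test_dimer_band_flattens_while_composite_keeps_falling(self):
        """The 932 cm^-1 trend levels off at low acid relative to 1705.

        Band intensities are derived from the speciation solver (the
        dimer marker tracks acid-in-dimer, the composite acid carbonyl
        tracks monomer + dimer): at low acid fraction the dimer curve is
        essentially flat near zero while the composite keeps falling.
        """
        model = SpeciationModel()
        rel_dimer, rel_acid = [], []
        for x_acid in (0.2, 0.1):
            sp = solve_speciation(x_acid, 1.0 - x_acid, model)
            rel_dimer.append(
                relative_absorbance(0.45 * 2.0 * sp.acid_dimer, x_acid)
            )
            rel_acid.append(
                relative_absorbance(
                    0.80 * (sp.acid_monomer + 2.0 * sp.acid_dimer), x_acid
                )
            )
        assert rel_dimer[1] < rel_dimer[0]  # both still decreasing
        assert rel_acid[1] < rel_acid[0]
        # ... but the dimer curve has levelled off (smaller change)
        assert abs(rel_dimer[0] - rel_dimer[1]) < abs(rel_acid[0] - rel_acid[1])

    def test_linear_mixture_when_association_off(self):
        ideal = SpeciationModel(0.0, 0.0)
        pure_ir = gen_mixture_spectrum(1.0, model=ideal)
        pure_acid = gen_mixture_spectrum(0.0, model=ideal)
        mix = gen_mixture_spectrum(0.35, model=ideal)
        resid = mixing_residual(mix, pure_ir, pure_acid, 0.35)
        assert np.abs(resid.absorbance).max() < 1e-12


@pytest.fixture(scope="module")
def noise_free_oven(reference_vle):
    cfg = GeneratorConfig(spectral_noise_sigma=0.0, composition_noise_molpct=0.0)
    return gen_oven_experiment(cfg, reference_vle, rng=np.random.default_rng(1))


class TestGenOvenExperiment:
    def test_default_mixture_count(self, noise_free_oven):
        assert len(noise_free_oven.trajectories) == 14
        assert len(noise_free_oven.drift) == 14

    def test_mass_logs_correctable_and_consistent(self, noise_free_oven):
        for log, traj in zip(noise_free_oven.mass_logs, noise_free_oven.trajectories):
            out = correct_sampling_losses(log)
            loss = out["evaporative_loss_g"].to_numpy()
            assert np.all(np.diff(loss) >= 0)
            # corrected loss equals the true evaporative loss of the ODE run
            true_loss = traj.mass[0] - np.interp(
                out["time_h"], traj.times, traj.mass
            )
            assert np.abs(loss - true_loss).max() < 1e-9

    def test_noise_free_recovery_of_attractor(self, noise_free_oven):
        fit = fit_avrami(noise_free_oven.drift, min_x0=40.0)
        assert abs(fit.x_az - 77.0) < 0.1

    def test_each_drift_trajectory_has_enough_points(self, noise_free_oven):
        for t in noise_free_oven.drift.trajectories:
            assert t.released.size >= 4
            assert np.all(np.diff(t.released) > 0)
            assert t.released[-1] < 1.0


class TestGenAssayCounts:
    def test_full_protection_zero_treated_probes(self):
        truth = SigmoidFit(p_max=1.0, t50=100.0, s=1.0, rmse=0.0, flags=frozenset())
        counts = gen_assay_counts(truth, GeneratorConfig(), seed=4)
        assert (counts["treated_probes"] == 0).all()
        assert (counts["control_probes"] > 0).any()

    def test_seed_determinism(self):
        truth = SigmoidFit(p_max=0.9, t50=4.0, s=0.8, rmse=0.0, flags=frozenset())
        t1 = gen_assay_counts(truth, GeneratorConfig(), seed=8)
        t2 = gen_assay_counts(truth, GeneratorConfig(), seed=8)
        assert t1.equals(t2)

    def test_zero_protection_counts_identically_distributed(self):
        """With P = 0 treated and control counts share one distribution."""
        truth = SigmoidFit(p_max=0.0, t50=3.0, s=1.0, rmse=0.0, flags=frozenset())
        cfg = GeneratorConfig(n_subjects=1, assay_times_h=(1.0,))
        treated, control = [], []
        rng = np.random.default_rng(17)
        for _ in range(500):
            tab = gen_assay_counts(truth, cfg, rng=rng)
            treated.extend(tab["treated_probes"])
            control.extend(tab["control_probes"])
        bins = np.arange(-0.5, 21.5)
        h_t, _ = np.histogram(treated, bins=bins)
        h_c, _ = np.histogram(control, bins=bins)
        pooled = h_t + h_c
        keep = pooled >= 10
        expected = pooled[keep] / 2.0
        observed = h_t[keep]
        expected = expected * observed.sum() / expected.sum()
        stat_t = chisquare(observed, expected)
        assert stat_t.pvalue > 0.01

    def test_schema(self):
        truth = SigmoidFit(p_max=0.9, t50=4.0, s=0.8, rmse=0.0, flags=frozenset())
        tab = gen_assay_counts(truth, GeneratorConfig(), seed=1, treatment="blend")
        assert set(tab.columns) == {
            "time_h", "treated_probes", "control_probes", "subject", "treatment",
        }
        assert len(tab) == 4 * 6
        assert tab["treated_probes"].between(0, 20).all()
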