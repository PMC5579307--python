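"""PLS1 inverse calibration: exactness, oracles, LOO selection."""

import warnings

import numpy as np
import pytest

from azeoblend import (
    CalibrationSet,
    GeneratorConfig,
    Spectrum,
    error_metrics,
    fit_pls1,
    gen_calibration_set,
    load_pls_model,
    loo_cv_select,
    predict_composition,
    save_pls_model,
)
from azeoblend.errors import DataIntegrityError, DomainError, GridMismatchError
from azeoblend.synthetic_data import SpeciationModel


def rank2_set(n=10, noise=0.0, rng=None):
    """Spectra that are exact linear mixtures of two basis spectra."""
    nu = np.arange(600.0, 1000.0, 2.0)
    base_a = np.exp(-((nu - 700.0) / 40.0) ** 2)
    base_b = np.exp(-((nu - 900.0) / 60.0) ** 2)
    x = np.linspace(0.0, 1.0, n)
    X = np.outer(x, base_a) + np.outer(1 - x, base_b)
    if noise > 0:
        X = X + rng.normal(0.0, noise, X.shape)
    return CalibrationSet(100.0 * x, X, nu)


class TestFitPLS1:
    def test_exact_on_noise_free_rank2(self):
        cal = rank2_set()
        model = fit_pls1(cal, 2)
        pred = model.predict_matrix(cal.spectra_matrix)
        assert np.abs(pred - cal.compositions_molpct).max() < 1e-10

    def test_zero_components_predicts_training_mean(self):
        cal = rank2_set()
        model = fit_pls1(cal, 2)
        pred = model.predict_matrix(cal.spectra_matrix, n_components=0)
        assert np.allclose(pred, cal.compositions_molpct.mean())

    def test_full_components_match_least_squares_oracle(self, rng):
        X = rng.normal(size=(8, 30))
        y = rng.uniform(10, 90, 8)
        cal = CalibrationSet(y, X, np.linspace(600, 658, 30))
        model = fit_pls1(cal, 7)
        Xc = X - X.mean(axis=0)
        pred_ls = y.mean() + Xc @ np.linalg.pinv(Xc) @ (y - y.mean())
        assert np.abs(model.predict_matrix(X) - pred_ls).max() < 1e-8

    def test_agreement_with_independent_pls_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        for trial in range(3):
            X = rng.normal(size=(12, 40))
            y = rng.uniform(0, 100, 12)
            cal = CalibrationSet(y, X, np.linspace(600, 678, 40))
            for k in (1, 3, 5):
                ours = fit_pls1(cal, k).predict_matrix(X)
                theirs = (
                    sklearn.PLSRegression(n_components=k, scale=False)
                    .fit(X, y)
                    .predict(X)
                    .ravel()
                )
                assert np.abs(ours - theirs).max() < 1e-6

    def test_offset_invariance(self, rng):
        X = rng.normal(size=(9, 25))
        y = rng.uniform(0, 100, 9)
        nu = np.linspace(600, 648, 25)
        base = fit_pls1(CalibrationSet(y, X, nu), 4).predict_matrix(X)
        shifted = fit_pls1(CalibrationSet(y, X + 5.0, nu), 4).predict_matrix(X + 5.0)
        assert np.abs(base - shifted).max() < 1e-8

    def test_training_rmse_monotone_in_components(self, rng):
        X = rng.normal(size=(12, 30))
        y = rng.uniform(0, 100, 12)
        cal = CalibrationSet(y, X, np.linspace(600, 658, 30))
        model = fit_pls1(cal, 10)
        rmses = []
        for k in range(0, 11):
            pred = model.predict_matrix(X, n_components=k)
            rmses.append(np.sqrt(np.mean((pred - y) ** 2)))
        assert all(b <= a + 1e-9 for a, b in zip(rmses, rmses[1:]))

    def test_rank_bound_enforced(self):
        cal = rank2_set(n=5)
        with pytest.raises(DomainError):
            fit_pls1(cal, 5)  # > n_samples - 1


class TestLooCvSelect:
    def test_report_has_requested_rows(self):
        cal = gen_calibration_set(GeneratorConfig(), rng=np.random.default_rng(5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = loo_cv_select(cal, 15)
        assert len(report.table) == 15
        assert list(report.table["n_components"]) == list(range(1, 16))

    def test_noise_free_rank2_chooses_few_and_is_exact(self):
        cal = rank2_set(n=12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = loo_cv_select(cal, 8)
        assert report.chosen <= 2
        assert report.mean_error_at_chosen < 1e-6

    def test_noisy_selection_stable_and_beats_one_component(self):
        results = []
        for _ in range(2):
            rng = np.random.default_rng(1)
            cal = rank2_set(n=24, noise=0.002, rng=rng)
            report = loo_cv_select(cal, 10)
            results.append(report)
        assert results[0].chosen == results[1].chosen
        table = results[0].table
        err1 = float(
            table[table["n_components"] == 1]["mean_abs_error_molpct"].iloc[0]
        )
        assert results[0].mean_error_at_chosen <= err1

    def test_chosen_minimizes_mean_error(self):
        cal = rank2_set(n=15, noise=0.005, rng=np.random.default_rng(2))
        report = loo_cv_select(cal, 8)
        means = report.table["mean_abs_error_molpct"]
        assert report.mean_error_at_chosen == pytest.approx(means.min())


class TestPredictComposition:
    def test_training_spectrum_recovered(self):
        cal = rank2_set()
        model = fit_pls1(cal, 2)
        spec = Spectrum(cal.wavenumbers, cal.spectra_matrix[3])
        pred = predict_composition(model, spec)
        assert pred.molpct == pytest.approx(cal.compositions_molpct[3], abs=1e-8)
        assert not pred.clipped

    def test_mean_spectrum_predicts_mean_composition(self):
        cal = rank2_set()
        model = fit_pls1(cal, 2)
        spec = Spectrum(cal.wavenumbers, cal.spectra_matrix.mean(axis=0))
        pred = predict_composition(model, spec)
        assert pred.molpct == pytest.approx(cal.compositions_molpct.mean(), abs=1e-8)

    def test_noisy_unknown_within_three_loo_errors(self):
        rng = np.random.default_rng(6)
        gen = GeneratorConfig()
        cal = gen_calibration_set(gen, rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = loo_cv_select(cal, 15)
        model = fit_pls1(cal, report.chosen)
        from azeoblend import gen_mixture_spectrum

        unknown = gen_mixture_spectrum(
            0.30, model=SpeciationModel(), noise_sigma=gen.spectral_noise_sigma, rng=rng
        )
        pred = predict_composition(model, unknown)
        tol = max(3.0 * report.mean_error_at_chosen, 0.5)
        assert abs(pred.molpct - 30.0) < tol

    def test_grid_mismatch_raises(self):
        cal = rank2_set()
        model = fit_pls1(cal, 2)
        other = Spectrum(np.arange(700.0, 1100.0, 2.0), np.zeros(200))
        with pytest.raises(GridMismatchError):
            predict_composition(model, other)

    def test_clipping_flagged(self):
        cal = rank2_set()
        model = fit_pls1(cal, 2)
        wild = Spectrum(cal.wavenumbers, 50.0 * cal.spectra_matrix[-1])
        pred = predict_composition(model, wild)
        assert pred.clipped
        assert 0.0 <= pred.molpct <= 100.0


class TestErrorMetricsAndSerialization:
    def test_identical_sequences(self):
        assert error_metrics([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        max_abs, mean_abs = error_metrics([10.0, 20.0], [12.0, 20.0])
        assert (max_abs, mean_abs) == (2.0, 1.0)

    def test_max_at_least_mean(self, rng):
        pred = rng.uniform(0, 100, 24)
        truth = rng.uniform(0, 100, 24)
        max_abs, mean_abs = error_metrics(pred, truth)
        assert max_abs >= mean_abs

    def test_length_mismatch(self):
        with pytest.raises(DataIntegrityError):
            error_metrics([1.0], [1.0, 2.0])

    def test_model_round_trip(self, tmp_path):
        cal = rank2_set()
        model = fit_pls1(cal, 2)
        path = tmp_path / "model.txt"
        save_pls_model(model, path)
        loaded = load_pls_model(path)
        spec = Spectrum(cal.wavenumbers, cal.spectra_matrix[4])
        direct = predict_composition(model, spec)
        via_file = predict_composition(loaded, spec)
        assert via_file.molpct == pytest.approx(direct.molpct, abs=1e-12)
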