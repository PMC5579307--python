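"""Seeded generators for every input the analysis pipeline consumes.

The study system is a binary blend of the insect repellent IR3535
(ethyl butylacetylaminopropionate, component A) and nonanoic acid
(component B).  No public data accompany the study, so this module
fabricates statistically faithful stand-ins:

* a reference vapour-liquid equilibrium whose equilibrium curve crosses
  the diagonal at exactly 10 and 77 mol% IR3535 (positive and negative
  azeotrope) with the negative azeotrope at the global bubble-pressure
  minimum;
* FTIR spectra whose band intensities follow mass-action speciation
  (acid dimerisation and a 1:1 acid-amide complex), so the nonlinear
  intensity-versus-composition trends emerge from chemistry rather than
  ad-hoc scaling;
* oven evaporation experiments (composition drift, aliquot-corrected
  mass logs, paired spectra) and cup-on-arm probing counts.

Every generator is a pure function of its parameters and a seed (or an
explicit ``numpy.random.Generator``); no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .azeofit import DriftDataset, DriftTrajectory
from .errors import DomainError, FitError
from .evaporation import MassLog, Trajectory, simulate_open_evaporation
from .repellence import SigmoidFit
from .spectra import Band, Spectrum
from .vle import ActivityModel, BinaryVLE, Component

__all__ = [
    "SpeciationModel",
    "SpeciesFractions",
    "GeneratorConfig",
    "OvenExperiment",
    "DEFAULT_BAND_LIBRARY",
    "default_wavenumber_grid",
    "make_reference_vle",
    "solve_speciation",
    "gen_mixture_spectrum",
    "gen_calibration_set",
    "gen_oven_experiment",
    "gen_assay_counts",
]

# ---------------------------------------------------------------------------
# reference vapour-liquid equilibrium fixture
# ---------------------------------------------------------------------------

#: liquid densities at 50 degC used to convert volumes to moles, g/mL
DENSITY_IR3535 = 0.97
DENSITY_NONANOIC = 0.906
MOLAR_MASS_IR3535 = 215.29
MOLAR_MASS_NONANOIC = 158.24

# Redlich-Kister coefficients of the reference excess-Gibbs model at
# 323.15 K.  They were calibrated by writing dg/dx - ln(P_B/P_A) as
# (x - 0.10)(x - 0.77) s(x) with a polynomial s > 0 -- which pins the two
# diagonal crossings exactly at 10 and 77 mol% A -- and solving a linear
# program for s that maximises the crossing slope at the attractor
# subject to g(1) = 0 and the single-liquid stability condition
# 1 + x(1-x) g'' >= 0.08 everywhere.  The steep crossing (dy/dx ~ 5 at
# 77 mol%) makes the attractor strongly convergent, as the drift data
# require.
REFERENCE_RK_COEFFICIENTS = (
    -0.73743208192254,
    -3.100245621979251,
    -2.4464596367993163,
    -1.7890781107881342,
    2.9756389620395813,
    5.005819494359955,
    0.8388248134438583,
    -1.9773316846750202,
)
#: ln-form Antoine (A, B, C): ln P[Pa] = A - B/(T + C); pinned so that at
#: 323.15 K the acid (11.6 Pa) is more volatile than IR3535 (8.0 Pa) and
#: its pure-component TGA mass-loss rate is the larger of the two.
REFERENCE_ANTOINE_IR3535 = (30.54919243135955, 9200.0, 0.0)
REFERENCE_ANTOINE_NONANOIC = (28.754579289664232, 8500.0, 0.0)
REFERENCE_TEMPERATURE = 323.15


def make_reference_vle() -> BinaryVLE:
    """The shipped IR3535 / nonanoic acid equilibrium at 50 degC.

    By construction it has exactly two azeotropes, at 10.0 and 77.0 mol%
    IR3535; the one at 77 mol% is the attractor and the global
    bubble-pressure minimum (below both pure components).
    """
    return BinaryVLE(
        component_a=Component(
            name="IR3535",
            molar_mass=MOLAR_MASS_IR3535,
            antoine=REFERENCE_ANTOINE_IR3535,
            t_range=(290.0, 400.0),
        ),
        component_b=Component(
            name="nonanoic acid",
            molar_mass=MOLAR_MASS_NONANOIC,
            antoine=REFERENCE_ANTOINE_NONANOIC,
            t_range=(290.0, 400.0),
        ),
        activity=ActivityModel(REFERENCE_RK_COEFFICIENTS),
        temperature=REFERENCE_TEMPERATURE,
    )


# ---------------------------------------------------------------------------
# speciation model behind the synthetic FTIR spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciationModel:
    """Mass-action equilibria shaping the carbonyl region.

    ``K_dimer`` governs ``2 acid <-> (acid)_2`` and ``K_complex`` the 1:1
    acid-amide association ``acid + IR3535 <-> complex``, both on a
    mole-fraction basis.  The defaults make the dimer and the complex the
    dominant acid forms at low acid fraction, as inferred from the
    carbonyl-band trends of the mixtures.
    """

    k_dimer: float = 50.0
    k_complex: float = 200.0

    def __post_init__(self) -> None:
        if self.k_dimer < 0 or self.k_complex < 0:
            raise DomainError("equilibrium constants must be non-negative")


@dataclass(frozen=True)
class SpeciesFractions:
    """Mole-fraction amounts of each absorbing species."""

    acid_monomer: float
    acid_dimer: float
    free_ir: float
    complex: float

    def as_weights(self, x_acid: float, x_ir: float) -> dict[str, float]:
        return {
            "monomer": self.acid_monomer,
            "dimer": self.acid_dimer,
            "acid_in_dimer": 2.0 * self.acid_dimer,
            "uncomplexed_acid": self.acid_monomer + 2.0 * self.acid_dimer,
            "free_ir": self.free_ir,
            "complex": self.complex,
            "total_acid": x_acid,
            "total_ir": x_ir,
        }


def solve_speciation(
    x_acid_total: float, x_ir_total: float, model: SpeciationModel
) -> SpeciesFractions:
    """Solve the two mass-action balances for the species amounts.

    With monomer ``a``, dimer ``d = K_d a^2``, free IR ``f`` and complex
    ``c = K_c a f`` the balances are ``a + 2d + c = x_acid`` and
    ``f + c = x_ir``; they reduce to one scalar equation in ``a`` solved
    by bracketed root finding to a residual below 1e-10.
    """
    if abs(x_acid_total + x_ir_total - 1.0) > 1e-9:
        raise DomainError("species totals must sum to 1")
    kd, kc = model.k_dimer, model.k_complex
    if x_acid_total <= 0:
        return SpeciesFractions(0.0, 0.0, x_ir_total, 0.0)

    def balance(a):
        f = x_ir_total / (1.0 + kc * a)
        return a + 2.0 * kd * a**2 + kc * a * f - x_acid_total

    if balance(x_acid_total) < 0:  # pure-acid edge with kd = kc = 0
        a = x_acid_total
    else:
        try:
            a = brentq(balance, 0.0, x_acid_total, xtol=1e-16, rtol=8.9e-16)
        except ValueError as exc:  # pragma: no cover - defensive
            raise FitError(f"speciation solve failed: {exc}") from exc
    f = x_ir_total / (1.0 + kc * a)
    c = kc * a * f
    d = kd * a**2
    residual = abs(a + 2.0 * d + c - x_acid_total)
    if residual > 1e-10:
        raise FitError(f"speciation residual {residual:.2e} exceeds 1e-10")
    return SpeciesFractions(acid_monomer=a, acid_dimer=d, free_ir=f, complex=c)


# ---------------------------------------------------------------------------
# synthetic FTIR spectra
# ---------------------------------------------------------------------------

#: (band, species key, extinction scale): peak height is scale * species
#: amount.  Carbonyl assignments: ester 1735 (all IR3535), free amide
#: 1638, composite acid C=O 1705 (monomer + dimer), acid-amide complex
#: 1608, acid-dimer marker 932 cm^-1; the remainder are unspecific C-H /
#: skeletal bands giving the spectra a realistic overall shape.
DEFAULT_BAND_LIBRARY: tuple[tuple[Band, str, float], ...] = (
    (Band(1735.0, 18.0, 0.3, assignment="ester C=O"), "total_ir", 0.90),
    (Band(1638.0, 20.0, 0.3, assignment="amide C=O (free IR3535)"), "free_ir", 0.70),
    (Band(1705.0, 20.0, 0.3, assignment="acid C=O (all acid forms)"), "uncomplexed_acid", 0.80),
    (Band(1608.0, 26.0, 0.3, assignment="acid-amide H-bonded C=O"), "complex", 0.60),
    (Band(932.0, 10.0, 0.3, assignment="acid dimer OH wag"), "acid_in_dimer", 0.45),
    (Band(2930.0, 46.0, 0.4, assignment="CH stretch"), "total_ir", 0.55),
    (Band(2922.0, 50.0, 0.4, assignment="CH stretch"), "total_acid", 0.50),
    (Band(1465.0, 20.0, 0.5, assignment="CH2 scissor"), "total_ir", 0.25),
    (Band(1413.0, 18.0, 0.5, assignment="C-O-H bend"), "total_acid", 0.20),
    (Band(1185.0, 34.0, 0.5, assignment="C-O stretch"), "total_ir", 0.40),
    (Band(1280.0, 30.0, 0.5, assignment="C-O stretch"), "total_acid", 0.30),
)


def default_wavenumber_grid(resolution: float = 2.0) -> np.ndarray:
    """Uniform ascending grid over 600-4000 cm^-1."""
    return np.arange(600.0, 4000.0 + 0.5 * resolution, resolution)


def gen_mixture_spectrum(
    x_ir: float,
    model: SpeciationModel | None = None,
    bands: tuple[tuple[Band, str, float], ...] = DEFAULT_BAND_LIBRARY,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    wavenumbers: np.ndarray | None = None,
) -> Spectrum:
    """Synthesise a mixture spectrum from speciation-weighted bands.

    Absorbance is the sum of species-amount-weighted pseudo-Voigt bands
    plus i.i.d. Gaussian noise of standard deviation ``noise_sigma``.
    Pure-component calls (``x_ir`` of 0 or 1, zero noise) reproduce the
    parent spectra used in mixing residuals.
    """
    if not 0.0 <= x_ir <= 1.0:
        raise DomainError(f"x_ir outside [0, 1]: {x_ir}")
    if model is None:
        model = SpeciationModel()
    if wavenumbers is None:
        wavenumbers = default_wavenumber_grid()
    species = solve_speciation(1.0 - x_ir, x_ir, model)
    weights = species.as_weights(1.0 - x_ir, x_ir)
    absorbance = np.zeros_like(wavenumbers, dtype=float)
    for band, key, scale in bands:
        w = weights[key]
        if w > 0:
            absorbance += band.evaluate(wavenumbers, amplitude=scale * w)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sigma, absorbance.size)
    return Spectrum(wavenumbers, absorbance)


# ---------------------------------------------------------------------------
# experiment-level generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition constants and noise levels for all generators.

    Defaults mirror the laboratory protocol: 14 oven mixtures of
    13.5 mL at 50 degC sampled with 10 uL aliquots, a 24-mixture FTIR
    calibration set at 2 cm^-1 resolution, and cup-on-arm assays with 20
    mosquitoes per cup on 4 subjects, hourly for 6 h.
    """

    seed: int = 42
    spectral_noise_sigma: float = 0.002  # absorbance units
    composition_noise_molpct: float = 0.5
    probing_overdispersion: float | None = None  # beta-binomial rho, optional
    n_oven_mixtures: int = 14
    oven_initial_molpct: tuple[float, ...] = tuple(np.linspace(5.0, 95.0, 14))
    oven_volume_ml: float = 13.5
    aliquot_volume_ul: float = 10.0
    oven_rate_constant: float = 2e-5  # mol / (Pa h)
    oven_t_end_h: float = 1000.0
    oven_sampling_times_h: tuple[float, ...] = (
        6.0, 12.0, 24.0, 48.0, 72.0, 120.0, 168.0, 240.0,
        312.0, 384.0, 456.0, 528.0, 600.0, 672.0,
    )
    n_calibration_mixtures: int = 24
    spectral_resolution: float = 2.0
    n_mosquitoes: int = 20
    p_bite: float = 0.8
    n_subjects: int = 4
    assay_times_h: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)

    def __post_init__(self) -> None:
        if self.n_oven_mixtures != len(self.oven_initial_molpct):
            raise DomainError("n_oven_mixtures does not match the composition list")
        for name in ("n_oven_mixtures", "n_calibration_mixtures", "n_mosquitoes",
                     "n_subjects"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.spectral_noise_sigma < 0 or self.composition_noise_molpct < 0:
            raise DomainError("noise levels must be non-negative")
        if not 0 < self.p_bite <= 1:
            raise DomainError("p_bite must lie in (0, 1]")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _mixture_density(x_ir: float) -> float:
    """Mass-weighted density of the liquid mixture, g/mL."""
    m_ir = x_ir * MOLAR_MASS_IR3535
    m_acid = (1.0 - x_ir) * MOLAR_MASS_NONANOIC
    v = m_ir / DENSITY_IR3535 + m_acid / DENSITY_NONANOIC
    return (m_ir + m_acid) / v


def _initial_moles(x_ir: float, volume_ml: float) -> float:
    v_ir = MOLAR_MASS_IR3535 / DENSITY_IR3535
    v_acid = MOLAR_MASS_NONANOIC / DENSITY_NONANOIC
    return volume_ml / (x_ir * v_ir + (1.0 - x_ir) * v_acid)


@dataclass(frozen=True)
class OvenExperiment:
    """Everything one oven campaign produces, per mixture."""

    trajectories: tuple[Trajectory, ...]
    drift: DriftDataset
    mass_logs: tuple[MassLog, ...]
    spectra: tuple[tuple[Spectrum, ...], ...]  # per mixture, per sampling time
    sample_times: tuple[np.ndarray, ...]
    initial_molpct: tuple[float, ...]


def gen_oven_experiment(
    config: GeneratorConfig,
    vle: BinaryVLE,
    rng: np.random.Generator | None = None,
    speciation: SpeciationModel | None = None,
) -> OvenExperiment:
    """Simulate the multi-mixture oven campaign.

    Each prepared mixture evaporates openly at the oven temperature; at
    the scheduled sampling times the gross mass is logged, a 10 uL
    aliquot is withdrawn for FTIR (its mass recorded so that sampling
    losses can be corrected) and a synthetic spectrum of the current
    liquid is generated.  Composition observations carry the configured
    Gaussian noise; the prepared composition itself (the first
    observation at zero released mass) is treated as exactly known.
    Aliquot withdrawals (~1% of the charge in total) are bookkept in the
    mass logs but not fed back into the evaporation ODE.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if speciation is None:
        speciation = SpeciationModel()

    trajectories = []
    drift_trajs = []
    mass_logs = []
    spectra_all = []
    sample_times_all = []
    for x0_molpct in config.oven_initial_molpct:
        x0 = x0_molpct / 100.0
        n0 = _initial_moles(x0, config.oven_volume_ml)
        traj = simulate_open_evaporation(
            vle,
            x0=x0,
            n0=n0,
            rate_constant=config.oven_rate_constant,
            t_end=config.oven_t_end_h,
            n_points=800,
        )
        trajectories.append(traj)
        mass0 = traj.mass[0]
        t_last = traj.times[-1]
        times = np.array(
            [t for t in config.oven_sampling_times_h if t <= t_last]
        )
        sim_mass = np.interp(times, traj.times, traj.mass)
        sim_x = np.interp(times, traj.times, traj.x_a)

        # stop sampling a dish once its remaining content cannot support
        # another 10 uL withdrawal (about 10 mg)
        aliquot_list, gross_list, n_keep = [], [], 0
        cum = 0.0
        for mass_i, x_i in zip(sim_mass, sim_x):
            a_i = config.aliquot_volume_ul * 1e-3 * _mixture_density(x_i)
            gross_i = mass_i - cum
            if gross_i < 10.0 * a_i:
                break
            aliquot_list.append(a_i)
            gross_list.append(gross_i)
            cum += a_i
            n_keep += 1
        times, sim_mass, sim_x = times[:n_keep], sim_mass[:n_keep], sim_x[:n_keep]
        released = 1.0 - sim_mass / mass0
        aliquot = np.array(aliquot_list)
        gross = np.array(gross_list)
        log_times = np.concatenate([[0.0], times])
        # no aliquot at preparation time: the starting composition is
        # known from weighing, FTIR sampling begins at the first readout
        mass_logs.append(
            MassLog(
                times=log_times,
                gross_mass=np.concatenate([[mass0], gross]),
                aliquot_mass=np.concatenate([[0.0], aliquot]),
            )
        )

        x_obs = 100.0 * sim_x
        if config.composition_noise_molpct > 0:
            x_obs = x_obs + rng.normal(
                0.0, config.composition_noise_molpct, x_obs.size
            )
        drift_trajs.append(
            DriftTrajectory(
                x0_molpct=x0_molpct,
                released=np.concatenate([[0.0], released]),
                x_molpct=np.concatenate([[x0_molpct], np.clip(x_obs, 0.0, 100.0)]),
            )
        )
        spectra_all.append(
            tuple(
                gen_mixture_spectrum(
                    x_ir=float(x),
                    model=speciation,
                    noise_sigma=config.spectral_noise_sigma,
                    rng=rng,
                )
                for x in sim_x
            )
        )
        sample_times_all.append(times)

    return OvenExperiment(
        trajectories=tuple(trajectories),
        drift=DriftDataset(tuple(drift_trajs)),
        mass_logs=tuple(mass_logs),
        spectra=tuple(spectra_all),
        sample_times=tuple(sample_times_all),
        initial_molpct=tuple(config.oven_initial_molpct),
    )


def gen_calibration_set(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    speciation: SpeciationModel | None = None,
):
    """The known-composition training mixtures and their noisy spectra.

    Compositions span the full range, endpoints included; returns a
    :class:`~azeoblend.calibration.CalibrationSet`.
    """
    from .calibration import CalibrationSet

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if speciation is None:
        speciation = SpeciationModel()
    fractions = np.linspace(0.0, 1.0, config.n_calibration_mixtures)
    grid = default_wavenumber_grid(config.spectral_resolution)
    entries = [
        (
            float(x),
            gen_mixture_spectrum(
                float(x),
                model=speciation,
                noise_sigma=config.spectral_noise_sigma,
                rng=rng,
                wavenumbers=grid,
            ),
        )
        for x in fractions
    ]
    return CalibrationSet.from_entries(entries)


def _beta_binomial(rng, n, p, rho):
    """Beta-binomial draw with mean ``n p`` and overdispersion ``rho``."""
    if rho <= 0:
        return rng.binomial(n, p)
    conc = (1.0 - rho) / rho
    q = rng.beta(p * conc, (1.0 - p) * conc)
    return rng.binomial(n, q)


def gen_assay_counts(
    truth: SigmoidFit,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    treatment: str = "blend",
) -> pd.DataFrame:
    """Probing counts for one treatment under the cup-on-arm protocol.

    Control probes are ``Binomial(n_mosquitoes, p_bite)``; treated probes
    are ``Binomial(n_mosquitoes, p_bite * (1 - P(t)))`` with ``P(t)`` the
    true protection sigmoid.  One row per subject and hourly time point;
    optional beta-binomial overdispersion.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    rho = config.probing_overdispersion or 0.0
    rows = []
    for subject in range(1, config.n_subjects + 1):
        for t in config.assay_times_h:
            p_true = float(truth.predict(t))
            control = _beta_binomial(rng, config.n_mosquitoes, config.p_bite, rho)
            treated = _beta_binomial(
                rng, config.n_mosquitoes, config.p_bite * (1.0 - p_true), rho
            )
            rows.append(
                {
                    "time_h": t,
                    "treated_probes": int(treated),
                    "control_probes": int(control),
                    "subject": f"S{subject}",
                    "treatment": treatment,
                }
            )
    return pd.DataFrame(rows)
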