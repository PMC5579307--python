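"""FTIR spectrum container and the two spectral statistics of the study.

A :class:`Spectrum` is a uniform ascending wavenumber grid (within
600-4000 cm^-1) plus an absorbance vector.  On top of it the module
implements

* the *mixing residual* ``dA_mix = A_mix - [x A_pure_a + (1-x) A_pure_b]``,
  which is identically zero for a non-interacting (Beer-Lambert) mixture
  and flags intermolecular association otherwise, and
* composition-normalised *relative band intensities*: baseline-corrected
  peak height in a window, divided by the mole fraction of the absorbing
  species.

Bands are pseudo-Voigt (linear Gauss/Lorentz mix), the standard line shape
for condensed-phase infrared work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GridMismatchError

__all__ = [
    "Spectrum",
    "Band",
    "pseudo_voigt",
    "mixing_residual",
    "band_intensity",
    "relative_absorbance",
]

WAVENUMBER_MIN = 600.0
WAVENUMBER_MAX = 4000.0


@dataclass(frozen=True)
class Spectrum:
    """Wavenumber grid (cm^-1, uniform, ascending) and absorbance vector."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", nu)
        object.__setattr__(self, "absorbance", ab)
        if nu.ndim != 1 or nu.size < 2:
            raise DomainError("wavenumber grid needs at least two points")
        if ab.shape != nu.shape:
            raise DomainError("absorbance and wavenumber lengths differ")
        steps = np.diff(nu)
        if np.any(steps <= 0):
            raise DomainError("wavenumber grid must be strictly ascending")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise DomainError("wavenumber grid must be uniform")
        if nu[0] < WAVENUMBER_MIN - 1e-9 or nu[-1] > WAVENUMBER_MAX + 1e-9:
            raise DomainError(
                f"grid [{nu[0]}, {nu[-1]}] outside the supported "
                f"{WAVENUMBER_MIN:.0f}-{WAVENUMBER_MAX:.0f} cm^-1 range"
            )

    @property
    def resolution(self) -> float:
        """Grid spacing in cm^-1."""
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavenumbers.shape == other.wavenumbers.shape and np.allclose(
            self.wavenumbers, other.wavenumbers, rtol=0, atol=1e-9
        )

    def with_absorbance(self, absorbance) -> "Spectrum":
        return Spectrum(self.wavenumbers, np.asarray(absorbance, dtype=float))


def pseudo_voigt(nu, center: float, fwhm: float, eta: float):
    """Height-normalised pseudo-Voigt profile.

    ``eta`` is the Lorentzian fraction in [0, 1]; 0 gives a pure Gaussian.
    The profile peaks at 1.0 at ``center`` for both limits.
    """
    if not fwhm > 0:
        raise DomainError(f"fwhm must be positive, got {fwhm}")
    if not 0.0 <= eta <= 1.0:
        raise DomainError(f"Gauss/Lorentz fraction outside [0, 1]: {eta}")
    nu = np.asarray(nu, dtype=float)
    half = fwhm / 2.0
    lorentz = half**2 / ((nu - center) ** 2 + half**2)
    gauss = np.exp(-4.0 * np.log(2.0) * ((nu - center) / fwhm) ** 2)
    return eta * lorentz + (1.0 - eta) * gauss


@dataclass(frozen=True)
class Band:
    """An absorption band: position, width, shape and height."""

    center: float  # cm^-1
    fwhm: float  # cm^-1
    shape: float = 0.5  # Lorentzian fraction
    amplitude: float = 1.0  # peak absorbance
    assignment: str = ""

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise DomainError("band fwhm must be positive")
        if self.amplitude < 0:
            raise DomainError("band amplitude must be non-negative")

    def evaluate(self, nu, amplitude: float | None = None):
        amp = self.amplitude if amplitude is None else amplitude
        return amp * pseudo_voigt(nu, self.center, self.fwhm, self.shape)


def mixing_residual(
    mix: Spectrum, pure_a: Spectrum, pure_b: Spectrum, x_a: float
) -> Spectrum:
    """Spectral residual of a mixture against the additive baseline.

    ``dA_mix(nu) = A_mix(nu) - [x_a A_a(nu) + (1 - x_a) A_b(nu)]``.  The
    three spectra must share one grid exactly; no resampling is attempted.
    """
    if not 0.0 <= x_a <= 1.0:
        raise DomainError(f"x_a outside [0, 1]: {x_a}")
    if not (mix.same_grid(pure_a) and mix.same_grid(pure_b)):
        raise GridMismatchError("mixture and pure spectra are on different grids")
    resid = mix.absorbance - (x_a * pure_a.absorbance + (1.0 - x_a) * pure_b.absorbance)
    return mix.with_absorbance(resid)


def band_intensity(
    spec: Spectrum, window: tuple[float, float], kind: str = "height"
) -> float:
    """Baseline-corrected band intensity within a wavenumber window.

    A straight line anchored at the first and last grid points inside the
    window is subtracted; the default intensity is the maximum of the
    corrected absorbance (peak height), ``kind="area"`` integrates it
    (trapezoid) instead.  The measure is invariant to adding any straight
    line to the spectrum.
    """
    lo, hi = window
    if not lo < hi:
        raise DomainError(f"empty or inverted window {window}")
    mask = (spec.wavenumbers >= lo) & (spec.wavenumbers <= hi)
    if mask.sum() < 3:
        raise DomainError(
            f"window {window} cm^-1 contains fewer than 3 grid points"
        )
    nu = spec.wavenumbers[mask]
    ab = spec.absorbance[mask]
    slope = (ab[-1] - ab[0]) / (nu[-1] - nu[0])
    baseline = ab[0] + slope * (nu - nu[0])
    corrected = ab - baseline
    if kind == "height":
        return float(corrected.max())
    if kind == "area":
        return float(np.trapezoid(corrected, nu))
    raise DomainError(f"unknown intensity kind {kind!r}")


def relative_absorbance(intensity: float, fraction: float) -> float:
    """Band intensity normalised by the mole fraction of its carrier.

    Under Beer-Lambert behaviour (intensity proportional to fraction) the
    result is composition-independent; deviations track speciation.
    """
    if not fraction > 0:
        raise DomainError(f"fraction must be positive, got {fraction}")
    return float(intensity) / float(fraction)
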