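"""Binary vapour-liquid equilibrium with a Redlich-Kister activity model.

The central object is :class:`BinaryVLE`: two pure components (Antoine
vapour pressures), an isothermal Redlich-Kister excess-Gibbs model and a
temperature.  The module computes activity coefficients, the equilibrium
vapour composition ``y(x)`` under modified Raoult's law (ideal gas phase),
and locates and classifies azeotropes -- the interior crossings of the
equilibrium curve with the ``y = x`` diagonal.

Classification follows standard residue-curve (open-evaporation) theory:
under vapour removal the liquid composition obeys ``dx/d ln n = y - x``, so
a crossing with ``dy/dx > 1`` is a stable node (an attractor; the
maximum-boiling, bubble-pressure-minimum, *negative* azeotrope) while a
crossing with ``dy/dx < 1`` is unstable (the *positive* azeotrope, a
bubble-pressure maximum).  Both characterisations are evaluated and must
agree.

Compositions are mole fractions of component A in ``[0, 1]`` throughout;
user-facing reports convert to mol%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.optimize import bisect

from .errors import DomainError

__all__ = [
    "Component",
    "ActivityModel",
    "BinaryVLE",
    "AzeotropePoint",
    "Classification",
    "activity_coefficients",
    "equilibrium_vapor",
    "bubble_pressure",
    "find_azeotropes",
    "classify_azeotrope",
]

#: grid spacing of the sign-change scan used by the azeotrope finder
ROOT_SCAN_POINTS = 1001
#: bisection tolerance on the azeotrope composition
ROOT_XTOL = 1e-10
#: |dy/dx - 1| below this value flags a degenerate (tangential) crossing
DEGENERACY_TOL = 1e-4


@dataclass(frozen=True)
class Component:
    """A pure component with an ln-form Antoine vapour-pressure correlation.

    Parameters
    ----------
    name
        Component label.
    molar_mass
        Molar mass in g/mol; must be positive.
    antoine
        Coefficients ``(A, B, C)`` of ``ln P[Pa] = A - B / (T[K] + C)``.
    t_range
        Temperature validity range of the correlation, in K.
    """

    name: str
    molar_mass: float
    antoine: tuple[float, float, float]
    t_range: tuple[float, float] = (273.15, 423.15)

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise DomainError(f"molar_mass must be positive, got {self.molar_mass}")
        if len(self.antoine) != 3:
            raise DomainError("antoine must supply exactly (A, B, C)")
        lo, hi = self.t_range
        if not lo < hi:
            raise DomainError(f"invalid temperature range {self.t_range}")
        # saturation pressure must stay positive and finite over the range
        for t in (lo, hi):
            p = self._psat_unchecked(t)
            if not (math.isfinite(p) and p > 0):
                raise DomainError(
                    f"{self.name}: saturation pressure not positive at {t} K"
                )

    def _psat_unchecked(self, temperature: float) -> float:
        a, b, c = self.antoine
        return math.exp(a - b / (temperature + c))

    def saturation_pressure(self, temperature: float) -> float:
        """Pure-component vapour pressure in Pa at ``temperature`` (K)."""
        lo, hi = self.t_range
        if not lo <= temperature <= hi:
            raise DomainError(
                f"{self.name}: {temperature} K outside Antoine validity "
                f"range [{lo}, {hi}] K"
            )
        return self._psat_unchecked(temperature)


@dataclass(frozen=True)
class ActivityModel:
    """Isothermal Redlich-Kister expansion of the excess Gibbs energy.

    ``g(x) = G_E / RT = x (1-x) * sum_k  A_k (2x - 1)^k`` with ``x`` the
    mole fraction of component A.  With all coefficients zero the model is
    ideal (both activity coefficients are 1 everywhere), and
    ``ln gamma_i -> 0`` as ``x_i -> 1`` by construction.
    """

    coefficients: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    @property
    def order(self) -> int:
        return len(self.coefficients)

    def excess_gibbs(self, x_a):
        """Dimensionless ``G_E / RT`` at liquid composition ``x_a``."""
        x = np.asarray(x_a, dtype=float)
        z = 2.0 * x - 1.0
        s = np.zeros_like(x)
        for k, a_k in enumerate(self.coefficients):
            s = s + a_k * z**k
        return x * (1.0 - x) * s

    def _g_and_dg(self, x):
        """Return ``g`` and ``dg/dx`` (analytic) at ``x``."""
        x = np.asarray(x, dtype=float)
        z = 2.0 * x - 1.0
        s = np.zeros_like(x)
        ds = np.zeros_like(x)  # d/dx of the RK sum
        for k, a_k in enumerate(self.coefficients):
            s = s + a_k * z**k
            if k >= 1:
                ds = ds + a_k * 2.0 * k * z ** (k - 1)
        g = x * (1.0 - x) * s
        dg = (1.0 - 2.0 * x) * s + x * (1.0 - x) * ds
        return g, dg

    def ln_gammas(self, x_a):
        """``(ln gamma_a, ln gamma_b)`` via the partial-molar relations.

        For a binary, ``ln g_a = g + (1 - x) dg/dx`` and
        ``ln g_b = g - x dg/dx``; Gibbs-Duhem consistency is automatic.
        """
        x = np.asarray(x_a, dtype=float)
        if np.any(x < 0) or np.any(x > 1):
            raise DomainError(f"mole fraction outside [0, 1]: {x_a}")
        g, dg = self._g_and_dg(x)
        return g + (1.0 - x) * dg, g - x * dg

    def curvature(self, x_a):
        """``d^2 g / dx^2``; used for the liquid-stability factor."""
        x = np.asarray(x_a, dtype=float)
        z = 2.0 * x - 1.0
        s = np.zeros_like(x)
        ds = np.zeros_like(x)
        d2s = np.zeros_like(x)
        for k, a_k in enumerate(self.coefficients):
            s = s + a_k * z**k
            if k >= 1:
                ds = ds + a_k * 2.0 * k * z ** (k - 1)
            if k >= 2:
                d2s = d2s + a_k * 4.0 * k * (k - 1) * z ** (k - 2)
        return -2.0 * s + 2.0 * (1.0 - 2.0 * x) * ds + x * (1.0 - x) * d2s

    def is_liquid_stable(self, n_grid: int = 2001) -> bool:
        """True when ``1 + x(1-x) g''(x) > 0`` on a composition grid.

        A violation marks a spinodal region: the single liquid phase the
        VLE model presumes would demix, and bubble-pressure extrema would
        no longer coincide with azeotropes.
        """
        x = np.linspace(1e-6, 1.0 - 1e-6, n_grid)
        return bool(np.all(1.0 + x * (1.0 - x) * self.curvature(x) > 0.0))


def activity_coefficients(model: ActivityModel, x_a):
    """Activity coefficients ``(gamma_a, gamma_b)`` at liquid composition ``x_a``."""
    lga, lgb = model.ln_gammas(x_a)
    return np.exp(lga), np.exp(lgb)


@dataclass(frozen=True)
class BinaryVLE:
    """Two components + activity model + temperature: the full equilibrium."""

    component_a: Component
    component_b: Component
    activity: ActivityModel
    temperature: float

    def __post_init__(self) -> None:
        for comp in (self.component_a, self.component_b):
            lo, hi = comp.t_range
            if not lo <= self.temperature <= hi:
                raise DomainError(
                    f"temperature {self.temperature} K outside Antoine range of "
                    f"{comp.name}"
                )

    @property
    def p_sat_a(self) -> float:
        return self.component_a.saturation_pressure(self.temperature)

    @property
    def p_sat_b(self) -> float:
        return self.component_b.saturation_pressure(self.temperature)

    def partial_pressures(self, x_a):
        """Equilibrium partial pressures ``(p_a, p_b)`` in Pa (modified Raoult)."""
        x = np.asarray(x_a, dtype=float)
        ga, gb = activity_coefficients(self.activity, x)
        return x * ga * self.p_sat_a, (1.0 - x) * gb * self.p_sat_b

    def bubble_pressure(self, x_a):
        """Total equilibrium pressure over liquid of composition ``x_a``."""
        pa, pb = self.partial_pressures(x_a)
        return pa + pb

    def vapor_composition(self, x_a):
        """Mole fraction of A in the equilibrium vapour."""
        pa, pb = self.partial_pressures(x_a)
        return pa / (pa + pb)


def bubble_pressure(vle: BinaryVLE, x_a):
    """Total equilibrium vapour pressure (Pa); module-level convenience."""
    return vle.bubble_pressure(x_a)


def equilibrium_vapor(vle: BinaryVLE, x_a):
    """Equilibrium vapour composition and total pressure at liquid ``x_a``.

    Returns
    -------
    (y_a, pressure)
        ``y_a = x_a gamma_a P_a^sat / P`` with
        ``P = x_a gamma_a P_a^sat + x_b gamma_b P_b^sat``.
    """
    pa, pb = vle.partial_pressures(x_a)
    p = pa + pb
    return pa / p, p


class Classification(NamedTuple):
    """Sign and dynamic stability of an azeotrope root."""

    sign: Literal["negative", "positive"]
    stability: Literal["attractor", "repeller"]
    dy_dx: float
    degenerate: bool


@dataclass(frozen=True)
class AzeotropePoint:
    """An interior crossing of the equilibrium curve with ``y = x``."""

    x_a: float
    pressure: float
    sign: Literal["negative", "positive"]
    stability: Literal["attractor", "repeller"]
    dy_dx: float = field(default=float("nan"))
    degenerate: bool = False

    @property
    def x_a_molpct(self) -> float:
        return 100.0 * self.x_a


def _dydx(vle: BinaryVLE, x: float, h: float = 1e-6) -> float:
    h = min(h, 0.5 * x, 0.5 * (1.0 - x))
    return float(
        (vle.vapor_composition(x + h) - vle.vapor_composition(x - h)) / (2.0 * h)
    )


def classify_azeotrope(vle: BinaryVLE, x_root: float) -> Classification:
    """Classify an azeotrope root by slope and bubble-pressure curvature.

    ``stability = attractor`` iff ``dy/dx > 1`` at the root (stable node of
    the open-evaporation composition dynamics); ``sign = negative`` iff the
    bubble pressure has a local minimum there.  For a Gibbs-stable liquid
    the two criteria coincide; a disagreement raises ``DomainError`` since
    it signals an inconsistent (demixing) activity model.
    """
    if not 0.0 < x_root < 1.0:
        raise DomainError(f"azeotrope root must be interior, got {x_root}")
    slope = _dydx(vle, x_root)
    stability = "attractor" if slope > 1.0 else "repeller"

    delta = min(1e-4, 0.5 * x_root, 0.5 * (1.0 - x_root))
    p_lo = vle.bubble_pressure(x_root - delta)
    p_mid = vle.bubble_pressure(x_root)
    p_hi = vle.bubble_pressure(x_root + delta)
    is_minimum = p_mid < p_lo and p_mid < p_hi
    is_maximum = p_mid > p_lo and p_mid > p_hi
    degenerate = abs(slope - 1.0) < DEGENERACY_TOL or not (is_minimum or is_maximum)
    sign = "negative" if is_minimum else "positive"

    if not degenerate and (sign == "negative") != (stability == "attractor"):
        raise DomainError(
            "inconsistent azeotrope classification: bubble-pressure "
            f"{'minimum' if is_minimum else 'maximum'} but dy/dx = {slope:.6g}; "
            "the activity model is not consistent with a stable single "
            "liquid phase at this composition"
        )
    return Classification(sign, stability, slope, degenerate)


def find_azeotropes(vle: BinaryVLE) -> list[AzeotropePoint]:
    """All interior roots of ``y(x) - x`` on (0, 1), in increasing order.

    A sign-change scan on a uniform grid is followed by bisection; grid
    nodes that hit a root exactly are accepted directly.  Endpoints are
    excluded (they satisfy ``y = x`` trivially).  Returns an empty list
    when the equilibrium curve never crosses the diagonal.
    """
    # endpoints offset so that "round" roots do not sit exactly on a node
    xs = np.linspace(1e-6, 1.0 - 1e-6, ROOT_SCAN_POINTS)
    f = vle.vapor_composition(xs) - xs

    roots: list[float] = []
    exact = np.flatnonzero(np.abs(f) < 1e-15)
    roots.extend(float(xs[i]) for i in exact)
    sign = np.sign(f)
    for i in range(len(xs) - 1):
        if sign[i] == 0 or sign[i + 1] == 0:
            continue  # exact node roots already collected
        if sign[i] * sign[i + 1] < 0:
            func = lambda x: float(vle.vapor_composition(x) - x)
            roots.append(float(bisect(func, xs[i], xs[i + 1], xtol=ROOT_XTOL)))

    roots = sorted(roots)
    # merge near-duplicates from an exact node adjacent to a sign change
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > 10 * ROOT_XTOL:
            merged.append(r)

    points = []
    for r in merged:
        cls = classify_azeotrope(vle, r)
        points.append(
            AzeotropePoint(
                x_a=r,
                pressure=float(vle.bubble_pressure(r)),
                sign=cls.sign,
                stability=cls.stability,
                dy_dx=cls.dy_dx,
                degenerate=cls.degenerate,
            )
        )
    return points
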