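"""Open (convection-swept) evaporation of a binary liquid.

The liquid sits in an open dish; the equilibrium vapour directly above it
is continuously removed by convection, so each component leaves with a
molar flux proportional to its equilibrium partial pressure:

    dn_i/dt = -k * x_i * gamma_i * P_i_sat ,

with a single mass-transfer coefficient ``k`` (mol Pa^-1 h^-1) shared by
both components.  The instantaneous vapour composition therefore equals
the equilibrium ``y_i``, and the liquid composition drifts along the
residue curve ``dx/d ln n = y - x``: negative azeotropes are attractors,
positive ones repellers.

Units: time in hours, mass in grams, amount in moles; these appear in
every CSV header written by this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DataIntegrityError, DomainError, IntegrationError
from .vle import BinaryVLE, activity_coefficients

__all__ = [
    "Trajectory",
    "MassLog",
    "simulate_open_evaporation",
    "composition_vs_released",
    "tga_mass_curve",
    "correct_sampling_losses",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

#: a run terminates when total moles fall below this fraction of n0
MOLE_FLOOR_FRACTION = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """Timed record of a simulated (or measured) open-evaporation run."""

    times: np.ndarray  # h
    moles_a: np.ndarray  # mol
    moles_b: np.ndarray  # mol
    molar_mass_a: float  # g/mol
    molar_mass_b: float  # g/mol

    def __post_init__(self) -> None:
        for name in ("times", "moles_a", "moles_b"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.times) == len(self.moles_a) == len(self.moles_b)):
            raise DomainError("trajectory arrays must have equal length")
        if np.any(self.moles_a < -1e-15) or np.any(self.moles_b < -1e-15):
            raise DataIntegrityError("negative mole amounts in trajectory")

    @property
    def moles_total(self) -> np.ndarray:
        return self.moles_a + self.moles_b

    @property
    def x_a(self) -> np.ndarray:
        """Liquid mole fraction of component A at each time."""
        n = self.moles_total
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(n > 0, self.moles_a / np.where(n > 0, n, 1.0), 0.0)
        return np.clip(x, 0.0, 1.0)

    @property
    def mass(self) -> np.ndarray:
        """Liquid mass in g: ``n_a M_a + n_b M_b``."""
        return self.moles_a * self.molar_mass_a + self.moles_b * self.molar_mass_b

    @property
    def released_fraction(self) -> np.ndarray:
        """``1 - mass / mass(0)``, non-decreasing, in [0, 1)."""
        m = self.mass
        return 1.0 - m / m[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "mass_g": self.mass,
                "x_a": self.x_a,
                "released_fraction": self.released_fraction,
            }
        )


@dataclass(frozen=True)
class MassLog:
    """Gravimetric log of an oven run with aliquot-sampling events.

    ``gross_mass[i]`` is the balance reading at ``times[i]`` *before* the
    aliquot ``aliquot_mass[i]`` (0 when no sample was taken) is removed.
    """

    times: np.ndarray  # h
    gross_mass: np.ndarray  # g
    aliquot_mass: np.ndarray  # g

    def __post_init__(self) -> None:
        for name in ("times", "gross_mass", "aliquot_mass"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.times) == len(self.gross_mass) == len(self.aliquot_mass)):
            raise DomainError("mass-log arrays must have equal length")
        if np.any(self.gross_mass <= 0):
            raise DataIntegrityError("gross mass must be positive")
        if np.any(self.aliquot_mass < 0):
            raise DataIntegrityError("aliquot masses must be non-negative")


def simulate_open_evaporation(
    vle: BinaryVLE,
    x0: float,
    n0: float,
    rate_constant: float,
    t_end: float,
    n_points: int = 400,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the open-evaporation ODE from initial composition ``x0``.

    Parameters
    ----------
    vle
        The binary equilibrium model (fixes temperature and activity).
    x0
        Initial liquid mole fraction of component A, in [0, 1].
    n0
        Initial total moles (> 0).
    rate_constant
        Mass-transfer coefficient ``k`` in mol Pa^-1 h^-1 (> 0).
    t_end
        Simulated duration in hours; the run stops earlier if total moles
        fall below ``MOLE_FLOOR_FRACTION * n0``.
    n_points
        Number of evenly spaced output samples requested on ``[0, t_end]``.
    rtol
        Relative tolerance of the adaptive integrator.  Composition is
        always recomputed from the mole amounts, never integrated.
    """
    if not 0.0 <= x0 <= 1.0:
        raise DomainError(f"x0 outside [0, 1]: {x0}")
    if not n0 > 0:
        raise DomainError(f"n0 must be positive, got {n0}")
    if not rate_constant > 0:
        raise DomainError(f"rate_constant must be positive, got {rate_constant}")

    psat_a = vle.p_sat_a
    psat_b = vle.p_sat_b
    model = vle.activity
    floor = MOLE_FLOOR_FRACTION * n0

    def rhs(t, n):
        na, nb = n
        ntot = na + nb
        if ntot <= 0:
            return [0.0, 0.0]
        x = min(max(na / ntot, 0.0), 1.0)
        ga, gb = activity_coefficients(model, x)
        return [
            -rate_constant * x * float(ga) * psat_a,
            -rate_constant * (1.0 - x) * float(gb) * psat_b,
        ]

    def exhausted(t, n):
        return n[0] + n[1] - floor

    exhausted.terminal = True
    exhausted.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [x0 * n0, (1.0 - x0) * n0],
        method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_points),
        events=exhausted,
        rtol=rtol,
        atol=1e-15 * n0,
    )
    if not sol.success:
        last = (sol.t[-1], sol.y[:, -1]) if sol.t.size else None
        raise IntegrationError(f"evaporation integration failed: {sol.message}", last)

    t = sol.t
    na, nb = sol.y
    if sol.t_events[0].size:  # append the exhaustion point itself
        t = np.append(t, sol.t_events[0][0])
        na = np.append(na, sol.y_events[0][0][0])
        nb = np.append(nb, sol.y_events[0][0][1])
    # guard against tiny negative excursions at the floor
    na = np.clip(na, 0.0, None)
    nb = np.clip(nb, 0.0, None)
    return Trajectory(t, na, nb, vle.component_a.molar_mass, vle.component_b.molar_mass)


def composition_vs_released(traj: Trajectory) -> pd.DataFrame:
    """Two-column table ``(released_fraction, x_a)``.

    The released fraction is made strictly increasing by dropping rows
    that do not advance it (repeated samples at the mole floor).
    """
    m = traj.released_fraction
    x = traj.x_a
    keep = np.ones(len(m), dtype=bool)
    last = -np.inf
    for i, v in enumerate(m):
        if v > last:
            last = v
        else:
            keep[i] = False
    keep[0] = True
    return pd.DataFrame({"released_fraction": m[keep], "x_a": x[keep]})


def tga_mass_curve(traj: Trajectory) -> pd.DataFrame:
    """Isothermal mass-loss table ``(time_h, mass_g)``."""
    return pd.DataFrame({"time_h": traj.times, "mass_g": traj.mass})


def correct_sampling_losses(log: MassLog) -> pd.DataFrame:
    """Evaporative mass loss corrected for aliquot sampling.

    ``evaporative_loss(t_i) = mass(0) - gross_mass(t_i) - sum(aliquots
    removed before t_i)``; the aliquot recorded at ``t_i`` is taken *after*
    the reading, so it only affects later rows.  The result must be
    non-negative and non-decreasing, otherwise the log is inconsistent.
    """
    mass0 = log.gross_mass[0]
    aliquots_before = np.concatenate([[0.0], np.cumsum(log.aliquot_mass)[:-1]])
    loss = mass0 - log.gross_mass - aliquots_before
    if np.any(loss < -1e-12):
        raise DataIntegrityError(
            f"negative evaporative loss (min {loss.min():.6g} g): gross mass "
            "and aliquot records are inconsistent"
        )
    if np.any(np.diff(loss) < -1e-12):
        raise DataIntegrityError("evaporative loss decreases between readings")
    return pd.DataFrame({"time_h": log.times, "evaporative_loss_g": loss})


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write ``time_h, mass_g, x_a, released_fraction`` columns."""
    traj.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    """Read a trajectory table written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path)
    required = {"time_h", "mass_g", "x_a", "released_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise DataIntegrityError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df
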