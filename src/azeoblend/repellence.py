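"""Protection-efficacy statistics for the cup-on-arm mosquito assay.

A cup of 20 host-seeking female mosquitoes is held against a treated and
an untreated (control) forearm for 3 minutes; the probing counts T and C
give the protection value

    P = 1 - T / C ,

clipped to 0 (with a flag) when T exceeds C.  Protection versus time
after application is summarised by a decreasing three-parameter logistic

    P(t) = P_max / (1 + exp((t - t50) / s)) ,

whose closed-form threshold crossing yields the protection duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import spearmanr

from .errors import DataIntegrityError, DomainError, FitError

__all__ = [
    "AssayRecord",
    "ProtectionCurve",
    "SigmoidFit",
    "protection",
    "fit_protection_curve",
    "protection_duration",
]


@dataclass(frozen=True)
class AssayRecord:
    """One exposure: probing counts on treated and control arms."""

    time: float  # h post-application
    treated_probes: int
    control_probes: int
    subject: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.treated_probes < 0 or self.control_probes < 0:
            raise DomainError("probing counts must be non-negative")


def protection(treated: int, control: int) -> float:
    """WHO protection value ``P = 1 - T/C``, clipped to [0, 1].

    ``control`` must be positive for the ratio to be defined.  When more
    mosquitoes probe the treated arm than the control arm the value is
    clipped to 0; detect that case by ``treated > control``.
    """
    if treated < 0 or control < 0:
        raise DomainError("probing counts must be non-negative")
    if control == 0:
        raise DomainError("protection undefined when the control count is zero")
    return max(0.0, 1.0 - treated / control)


@dataclass(frozen=True)
class ProtectionCurve:
    """Protection values over time, with clipping bookkeeping."""

    times: np.ndarray  # h
    protection: np.ndarray  # [0, 1]
    clipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.protection, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "protection", p)
        if t.shape != p.shape or t.ndim != 1:
            raise DomainError("times and protection arrays must match")
        if np.any(p < 0) or np.any(p > 1):
            raise DomainError("protection values must lie in [0, 1]")
        if self.clipped is None:
            object.__setattr__(self, "clipped", np.zeros(t.shape, dtype=bool))

    @classmethod
    def from_counts(cls, times, treated, control) -> "ProtectionCurve":
        times = np.asarray(times, dtype=float)
        treated = np.asarray(treated)
        control = np.asarray(control)
        vals = np.array([protection(int(t), int(c)) for t, c in zip(treated, control)])
        return cls(times, vals, clipped=np.asarray(treated > control))


@dataclass(frozen=True)
class SigmoidFit:
    """Decreasing-logistic fit of protection versus time."""

    p_max: float  # plateau in (0, 1]
    t50: float  # h, midpoint
    s: float  # h, steepness (> 0)
    rmse: float
    flags: frozenset[str]  # subset of {plateau, boundary, increasing, degenerate}

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.p_max / (1.0 + np.exp((t - self.t50) / self.s))


def fit_protection_curve(curve: ProtectionCurve) -> SigmoidFit:
    """Fit ``P(t) = P_max / (1 + exp((t - t50)/s))`` by least squares.

    Deterministic multistart over midpoint/steepness seeds; ``P_max`` is
    bounded to (0, 1] and ``s`` kept positive through a log parameter.
    Pathological inputs are flagged rather than silently fitted:
    ``degenerate`` for all-zero protection, ``plateau`` when the midpoint
    lands beyond the observation window, ``boundary`` when a parameter
    sits on its bound, ``increasing`` when protection trends upward.
    """
    t = curve.times
    p = curve.protection
    if t.size < 4:
        raise DataIntegrityError("need at least 4 time points for the sigmoid fit")
    flags: set[str] = set()
    if np.all(p < 1e-12):
        return SigmoidFit(
            p_max=0.0, t50=float(t.min()), s=1.0, rmse=0.0,
            flags=frozenset({"degenerate"}),
        )
    rho = spearmanr(t, p).statistic if np.ptp(p) > 0 else 0.0
    if rho is not None and not np.isnan(rho) and rho > 0.5:
        flags.add("increasing")

    span = float(t.max() - t.min()) or 1.0
    lo = [1e-6, t.min() - 2.0 * span, np.log(1e-3)]
    hi = [1.0, t.max() + 2.0 * span, np.log(1e3)]

    def residuals(theta):
        p_max, t50, log_s = theta
        return p_max / (1.0 + np.exp((t - t50) / np.exp(log_s))) - p

    best = None
    p_max0 = min(max(float(p.max()), 1e-3), 1.0)
    for t50_0 in (t.min() + 0.25 * span, t.min() + 0.5 * span, t.max(), t.max() + span):
        for s0 in (0.3, 1.0, 3.0):
            theta0 = [p_max0, t50_0, np.log(s0)]
            res = least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, max_nfev=2000,
            )
            if best is None or res.cost < best.cost:
                best = res
    if best is None or best.status <= 0:
        raise FitError("protection sigmoid fit failed to converge")
    p_max, t50, log_s = best.x
    s = float(np.exp(log_s))
    if t50 >= t.max():
        flags.add("plateau")
    for v, l, h in zip(best.x, lo, hi):
        # P_max = 1 is a legitimate value (full protection), not a failure
        if (np.isclose(v, l) or np.isclose(v, h)) and not np.isclose(v, 1.0):
            flags.add("boundary")
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    return SigmoidFit(
        p_max=float(p_max), t50=float(t50), s=s, rmse=rmse, flags=frozenset(flags)
    )


def protection_duration(fit: SigmoidFit, threshold: float) -> float:
    """Time at which the fitted curve falls to ``threshold`` protection.

    Closed form from the logistic:
    ``t = t50 + s * ln(P_max / threshold - 1)``.  Requires
    ``0 < threshold < P_max``; monotone decreasing in the threshold.
    """
    if not 0.0 < threshold:
        raise DomainError("threshold must be positive")
    if threshold >= fit.p_max:
        raise DomainError(
            f"threshold {threshold} never reached: fitted plateau is {fit.p_max}"
        )
    return float(fit.t50 + fit.s * np.log(fit.p_max / threshold - 1.0))
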