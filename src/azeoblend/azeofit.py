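"""Azeotrope-composition estimation from composition-drift data.

During open evaporation the liquid composition drifts from its initial
value toward the attracting (negative) azeotrope.  The drift versus
released mass fraction ``m`` is summarised by a stretched-exponential
(Avrami-type) saturation law

    x(m) = x_az + (x0 - x_az) * exp(-k m^n),

with the asymptote ``x_az`` *shared* across trajectories while each
trajectory keeps its own rate ``k > 0`` and exponent ``n > 0``; ``x0`` is
pinned to the first observation of each trajectory.  The shared asymptote
is the azeotrope-composition estimate; its uncertainty comes from a
residual bootstrap (within-trajectory resampling of leverage-rescaled
residuals) with a percentile confidence interval.

Compositions are in mol% throughout this module, matching how drift data
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DataIntegrityError, DomainError, FitError
from .evaporation import Trajectory

__all__ = [
    "DriftTrajectory",
    "DriftDataset",
    "AvramiFit",
    "BootstrapResult",
    "avrami_drift",
    "fit_avrami",
    "bootstrap_azeotrope",
]

#: default inclusion threshold for the shared fit (mol% of component A)
DEFAULT_MIN_X0 = 40.0
#: spread below which drift data count as constant (degenerate), mol%
DEGENERATE_SPREAD = 1e-6
#: multistart seeds for (k, n)
_KN_STARTS = ((1.0, 1.0), (4.0, 1.0), (10.0, 1.0), (4.0, 2.0), (1.0, 0.7))


def avrami_drift(m, x0: float, x_az: float, k: float, n: float):
    """Stretched-exponential composition drift ``x(m)``, in mol%.

    ``m`` is the released mass fraction in [0, 1); ``k`` and ``n`` must be
    positive.  At ``m = 0`` the value is exactly ``x0``; as ``k m^n``
    grows the value approaches ``x_az`` monotonically.
    """
    if not k > 0:
        raise DomainError(f"rate k must be positive, got {k}")
    if not n > 0:
        raise DomainError(f"exponent n must be positive, got {n}")
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0) or np.any(m_arr >= 1):
        raise DomainError("released fraction must lie in [0, 1)")
    out = x_az + (x0 - x_az) * np.exp(-k * m_arr**n)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class DriftTrajectory:
    """One trajectory: initial composition and (m, x) observations."""

    x0_molpct: float
    released: np.ndarray
    x_molpct: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.released, dtype=float)
        x = np.asarray(self.x_molpct, dtype=float)
        object.__setattr__(self, "released", m)
        object.__setattr__(self, "x_molpct", x)
        if m.shape != x.shape or m.ndim != 1:
            raise DomainError("released and composition arrays must match")
        if np.any(m < 0) or np.any(m >= 1):
            raise DomainError("released fraction must lie in [0, 1)")

    @classmethod
    def from_trajectory(cls, traj: Trajectory, max_released: float = 0.999999):
        """Convert a simulated :class:`~azeoblend.evaporation.Trajectory`."""
        m = traj.released_fraction
        keep = m < max_released
        # enforce strictly increasing m (duplicate floor samples dropped)
        m_kept = m[keep]
        x_kept = 100.0 * traj.x_a[keep]
        inc = np.concatenate([[True], np.diff(m_kept) > 0])
        return cls(
            x0_molpct=float(x_kept[inc][0]),
            released=m_kept[inc],
            x_molpct=x_kept[inc],
        )


@dataclass(frozen=True)
class DriftDataset:
    """A collection of drift trajectories feeding one shared fit."""

    trajectories: tuple[DriftTrajectory, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trajectories", tuple(self.trajectories))

    def __len__(self) -> int:
        return len(self.trajectories)

    def eligible(self, min_x0: float = DEFAULT_MIN_X0) -> "DriftDataset":
        """Trajectories whose initial composition reaches the threshold."""
        return DriftDataset(
            tuple(t for t in self.trajectories if t.x0_molpct >= min_x0)
        )


@dataclass(frozen=True)
class AvramiFit:
    """Shared-asymptote drift fit: ``x_az`` plus per-trajectory (k, n)."""

    x_az: float  # mol%
    k: np.ndarray
    n: np.ndarray
    x0: np.ndarray  # per-trajectory initial compositions (fixed)
    residuals: tuple[np.ndarray, ...]  # per trajectory, model - data
    converged: bool
    degenerate: bool
    cost: float
    data: DriftDataset


def _pack(x_az: float, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    return np.concatenate([[x_az], np.log(k), np.log(n)])


def _unpack(theta: np.ndarray, n_traj: int):
    x_az = theta[0]
    k = np.exp(theta[1 : 1 + n_traj])
    n = np.exp(theta[1 + n_traj :])
    return x_az, k, n


def _residual_system(data: DriftDataset):
    """Build residual and Jacobian callables over concatenated trajectories."""
    ms = [t.released for t in data.trajectories]
    xs = [t.x_molpct for t in data.trajectories]
    x0s = np.array([t.x0_molpct for t in data.trajectories])
    n_traj = len(ms)
    sizes = [m.size for m in ms]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = offsets[-1]

    def residuals(theta):
        x_az, k, n = _unpack(theta, n_traj)
        out = np.empty(total)
        for i in range(n_traj):
            e = np.exp(-k[i] * ms[i] ** n[i])
            out[offsets[i] : offsets[i + 1]] = x_az + (x0s[i] - x_az) * e - xs[i]
        return out

    def jacobian(theta):
        x_az, k, n = _unpack(theta, n_traj)
        jac = np.zeros((total, theta.size))
        for i in range(n_traj):
            m = ms[i]
            mn = m ** n[i]
            e = np.exp(-k[i] * mn)
            sl = slice(offsets[i], offsets[i + 1])
            jac[sl, 0] = 1.0 - e
            amp = (x0s[i] - x_az) * e
            jac[sl, 1 + i] = -amp * k[i] * mn
            with np.errstate(divide="ignore"):
                logm = np.where(m > 0, np.log(np.where(m > 0, m, 1.0)), 0.0)
            jac[sl, 1 + n_traj + i] = -amp * k[i] * mn * n[i] * logm
        return jac

    return residuals, jacobian, x0s


def fit_avrami(
    data: DriftDataset,
    min_x0: float = DEFAULT_MIN_X0,
    x_az_start: float | None = None,
) -> AvramiFit:
    """Least-squares drift fit with a shared asymptote.

    Trajectories with ``x0 < min_x0`` are excluded; at least two eligible
    trajectories with four points each are required, unless the data are
    constant, in which case a degenerate fit pinned at the common value is
    returned.  Deterministic multistart over a fixed (k, n) grid.
    """
    eligible = data.eligible(min_x0)
    all_x = (
        np.concatenate([t.x_molpct for t in eligible.trajectories])
        if len(eligible)
        else np.array([])
    )
    if all_x.size and np.ptp(all_x) < DEGENERATE_SPREAD:
        n_traj = len(eligible)
        return AvramiFit(
            x_az=float(all_x.mean()),
            k=np.full(n_traj, np.nan),
            n=np.full(n_traj, np.nan),
            x0=np.array([t.x0_molpct for t in eligible.trajectories]),
            residuals=tuple(
                t.x_molpct - all_x.mean() for t in eligible.trajectories
            ),
            converged=True,
            degenerate=True,
            cost=0.0,
            data=eligible,
        )
    if len(eligible) < 2:
        raise DataIntegrityError(
            f"need at least two trajectories with x0 >= {min_x0} mol%, "
            f"got {len(eligible)}"
        )
    for t in eligible.trajectories:
        if t.released.size < 4:
            raise DataIntegrityError("each trajectory needs at least 4 points")

    residuals, jacobian, x0s = _residual_system(eligible)
    n_traj = len(eligible)
    if x_az_start is None:
        x_az_start = float(np.mean([t.x_molpct[-1] for t in eligible.trajectories]))

    lo = np.concatenate([[0.0], np.full(n_traj, np.log(1e-3)), np.full(n_traj, np.log(0.05))])
    hi = np.concatenate([[100.0], np.full(n_traj, np.log(1e4)), np.full(n_traj, np.log(50.0))])
    best = None
    for k0, n0 in _KN_STARTS:
        theta0 = _pack(x_az_start, np.full(n_traj, k0), np.full(n_traj, n0))
        res = least_squares(
            residuals,
            theta0,
            jac=jacobian,
            method="trf",
            bounds=(lo, hi),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None or best.status <= 0:
        raise FitError(
            "shared Avrami fit failed to converge",
            {"status": None if best is None else best.status},
        )
    x_az, k, n = _unpack(best.x, n_traj)
    resid = best.fun
    sizes = [t.released.size for t in eligible.trajectories]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    per_traj = tuple(
        resid[offsets[i] : offsets[i + 1]].copy() for i in range(n_traj)
    )
    return AvramiFit(
        x_az=float(x_az),
        k=k,
        n=n,
        x0=x0s,
        residuals=per_traj,
        converged=True,
        degenerate=False,
        cost=float(best.cost),
        data=eligible,
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Azeotrope-composition estimate with a percentile bootstrap CI."""

    estimate: float  # mol%
    ci_low: float
    ci_high: float
    n_replicates: int
    seed: int
    replicates: np.ndarray = field(repr=False)
    ci_contains_estimate: bool = True


def bootstrap_azeotrope(
    fit: AvramiFit,
    n_replicates: int = 1000,
    seed: int = 0,
    max_failure_fraction: float = 0.05,
) -> BootstrapResult:
    """Residual bootstrap of the shared azeotrope-composition estimate.

    Fitted residuals are centred within each trajectory, rescaled by
    ``sqrt(N / (N - p))`` to undo the downward bias of least-squares
    residuals, resampled with replacement *within* trajectory (preserving
    each trajectory's design points), added back to the fitted values and
    refit.  The 95% interval is the 2.5/97.5 percentile of the replicate
    asymptotes.  Fully reproducible for a fixed seed.
    """
    if fit.degenerate:
        return BootstrapResult(
            estimate=fit.x_az,
            ci_low=fit.x_az,
            ci_high=fit.x_az,
            n_replicates=n_replicates,
            seed=seed,
            replicates=np.full(n_replicates, fit.x_az),
        )
    if not fit.converged:
        raise FitError("cannot bootstrap an unconverged fit")
    rng = np.random.default_rng(seed)
    data = fit.data
    n_traj = len(data)
    # points at m = 0 are structurally exact (the model is pinned to the
    # first observation there): they carry no noise and are excluded from
    # the residual pool and from perturbation
    noisy_masks = [t.released > 0 for t in data.trajectories]
    n_free = int(sum(m.sum() for m in noisy_masks))
    n_params = 1 + 2 * n_traj
    if n_free <= n_params:
        raise DataIntegrityError("not enough points to bootstrap the fit")
    fitted = [
        t.x_molpct + r for t, r in zip(data.trajectories, fit.residuals)
    ]
    # undo the downward bias of least-squares residuals with the standard
    # leverage rescaling r_i / sqrt(1 - h_ii), h from the fit Jacobian
    _, jac_full, _ = _residual_system(data)
    theta_hat = _pack(fit.x_az, fit.k, fit.n)
    jac = jac_full(theta_hat)
    gram = jac.T @ jac
    lev = np.einsum(
        "ij,jk,ik->i", jac, np.linalg.pinv(gram), jac
    )
    lev = np.clip(lev, 0.0, 0.95)
    sizes = [t.released.size for t in data.trajectories]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    centred = []
    for i, (r, m) in enumerate(zip(fit.residuals, noisy_masks)):
        h = lev[offsets[i] : offsets[i + 1]][m]
        scaled = r[m] / np.sqrt(1.0 - h)
        centred.append(scaled - scaled.mean())

    estimates = np.empty(n_replicates)
    failures = 0
    for b in range(n_replicates):
        boot_trajs = []
        for t, f, c, mask in zip(data.trajectories, fitted, centred, noisy_masks):
            x_star = t.x_molpct.copy()
            x_star[mask] = f[mask] + rng.choice(c, size=int(mask.sum()), replace=True)
            boot_trajs.append(
                DriftTrajectory(
                    x0_molpct=t.x0_molpct, released=t.released, x_molpct=x_star
                )
            )
        boot = DriftDataset(tuple(boot_trajs))
        res_fn, jac_fn, _ = _residual_system(boot)
        lo = np.concatenate(
            [[0.0], np.full(n_traj, np.log(1e-3)), np.full(n_traj, np.log(0.05))]
        )
        hi = np.concatenate(
            [[100.0], np.full(n_traj, np.log(1e4)), np.full(n_traj, np.log(50.0))]
        )
        start = np.clip(theta_hat, lo, hi)
        try:
            res = least_squares(
                res_fn,
                start,
                jac=jac_fn,
                method="trf",
                bounds=(lo, hi),
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
                max_nfev=400,
            )
            if res.status <= 0:
                raise FitError("replicate refit did not converge")
            estimates[b] = res.x[0]
        except (FitError, np.linalg.LinAlgError):
            estimates[b] = np.nan
            failures += 1

    if failures > max_failure_fraction * n_replicates:
        raise FitError(
            f"{failures}/{n_replicates} bootstrap refits failed "
            f"(> {100 * max_failure_fraction:.0f}%)"
        )
    good = estimates[~np.isnan(estimates)]
    lo, hi = np.percentile(good, [2.5, 97.5])
    return BootstrapResult(
        estimate=fit.x_az,
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=n_replicates,
        seed=seed,
        replicates=good,
        ci_contains_estimate=bool(lo <= fit.x_az <= hi),
    )
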