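"""Sorting kinetics: exponential relaxation fits and lateral diffusion.

The ensemble-mean peptide position relaxing toward its preferred
membrane thickness is fit by

    x(t) = x0 - A * (1 - exp(-t / tau)),

the solution of overdamped motion under a force proportional to the
distance from equilibrium (i.e. proportional to hydrophobic mismatch).
Lateral diffusion coefficients are estimated from mean-squared
displacements with overlapping time origins.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitConvergenceError, FitError, ValidationError

__all__ = [
    "RelaxationFit",
    "DiffusionEstimate",
    "fit_relaxation",
    "estimate_diffusion",
]


@dataclass(frozen=True)
class RelaxationFit:
    """Parameters of x(t) = x0 - A (1 - exp(-t/tau)).

    A > 0 means relaxation toward smaller x; the fitted plateau is
    x(inf) = x0 - A.  ``covariance`` is the 3x3 estimate covariance in
    (x0, A, tau) order.
    """

    x0: float
    A: float
    tau: float
    r_squared: float
    covariance: np.ndarray

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError(f"fitted tau must be > 0, got {self.tau}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError(f"r_squared out of range: {self.r_squared}")

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.x0 - self.A * (1.0 - np.exp(-t / self.tau))

    def to_dict(self) -> dict:
        return {
            "x0": self.x0,
            "A": self.A,
            "tau": self.tau,
            "r_squared": self.r_squared,
            "covariance": np.asarray(self.covariance).tolist(),
        }


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion coefficient from an MSD slope: D = slope / (2 * dimensionality)."""

    D: float  # nm^2/ns
    fit_window: tuple[float, float]  # ns
    dimensionality: int

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValidationError(f"D must be >= 0, got {self.D}")
        if self.dimensionality not in (1, 2):
            raise ValidationError("dimensionality must be 1 or 2")


def _relax_model(t, x0, A, tau):
    return x0 - A * (1.0 - np.exp(-t / tau))


def _relax_jac(t, x0, A, tau):
    e = np.exp(-t / tau)
    return np.stack([np.ones_like(t), -(1.0 - e), A * t * e / tau**2], axis=1)


def fit_relaxation(times, mean_positions) -> RelaxationFit:
    """Nonlinear least squares of the exponential relaxation model.

    Initialisation: x0 = first point, A = first - last, tau = time at
    which half the total displacement is covered (falling back to a
    third of the sampled span when the ensemble has not relaxed that
    far).  Non-convergence raises :class:`FitConvergenceError` with the
    initial guess and optimizer message attached.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(mean_positions, dtype=float)
    if t.size < 4:
        raise FitError(f"need >= 4 points, got {t.size}")
    if t.shape != x.shape:
        raise ValidationError("times and positions must have equal length")
    if not np.all(np.diff(t) > 0):
        raise ValidationError("times must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
        raise ValidationError("inputs must be finite")

    x0_init = x[0]
    a_init = x[0] - x[-1]
    half = x0_init - 0.5 * a_init
    if abs(a_init) > 0:
        crossed = np.nonzero(np.sign(a_init) * (x0_init - x) >= abs(x0_init - half))[0]
        tau_init = t[crossed[0]] if crossed.size and crossed[0] > 0 else (t[-1] - t[0]) / 3.0
    else:
        a_init = 1e-8
        tau_init = (t[-1] - t[0]) / 3.0
    tau_init = max(tau_init, (t[1] - t[0]) / 10.0)

    try:
        popt, pcov = optimize.curve_fit(
            _relax_model,
            t,
            x,
            p0=[x0_init, a_init, tau_init],
            jac=_relax_jac,
            bounds=([-np.inf, -np.inf, np.finfo(float).tiny], [np.inf, np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"relaxation fit did not converge: {exc}",
            diagnostics={"p0": [x0_init, a_init, tau_init], "n": int(t.size)},
        ) from exc

    resid = x - _relax_model(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return RelaxationFit(float(popt[0]), float(popt[1]), float(popt[2]), r2, pcov)


def _msd_curve(pos: np.ndarray, max_lag: int) -> np.ndarray:
    """MSD over lags 1..max_lag with overlapping time origins.

    ``pos`` has shape (n_replicas, n_frames, n_dims).
    """
    msd = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        disp = pos[:, lag:, :] - pos[:, :-lag, :]
        msd[lag - 1] = np.mean(np.sum(disp**2, axis=-1))
    return msd


def estimate_diffusion(
    trajectories: np.ndarray,
    dt: float,
    fit_window: tuple[float, float] | None = None,
    dimensionality: int | None = None,
    max_lag_fraction: float = 0.1,
    box: float | None = None,
) -> DiffusionEstimate:
    """Diffusion coefficient from replica- and origin-averaged MSD.

    Parameters
    ----------
    trajectories
        Unwrapped positions, shape (n_replicas, n_frames) for 1D or
        (n_replicas, n_frames, n_dims).
    dt
        Frame spacing (ns).
    fit_window
        (t_lo, t_hi) in ns for the OLS slope fit; default is the full
        lag range (capped at ``max_lag_fraction`` of the trajectory to
        bound time-origin correlation bias).
    box
        If given, jumps larger than box/2 between consecutive frames
        raise an error advising unwrapping.
    """
    pos = np.asarray(trajectories, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, :, None]
    if pos.ndim != 3 or pos.shape[1] < 3:
        raise ValidationError("trajectories must be (replica, frame[, dim]) with >=3 frames")
    dims = pos.shape[2] if dimensionality is None else dimensionality
    if dims not in (1, 2):
        raise ValidationError("dimensionality must be 1 or 2")
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if box is not None:
        jumps = np.abs(np.diff(pos, axis=1))
        if np.any(jumps > box / 2.0):
            raise ValidationError(
                "detected jumps larger than box/2: coordinates appear wrapped; "
                "unwrap the trajectory before estimating diffusion"
            )

    n_frames = pos.shape[1]
    max_lag = max(2, int(max_lag_fraction * (n_frames - 1)))
    msd = _msd_curve(pos[:, :, :dims], max_lag)
    lag_t = dt * np.arange(1, max_lag + 1)

    if fit_window is None:
        mask = np.ones_like(lag_t, dtype=bool)
    else:
        lo, hi = fit_window
        mask = (lag_t >= lo) & (lag_t <= hi)
        if mask.sum() < 2:
            raise ValidationError(f"fit window {fit_window} covers < 2 MSD points")
    slope = float(np.polyfit(lag_t[mask], msd[mask], 1)[0])
    window = (float(lag_t[mask][0]), float(lag_t[mask][-1]))
    return DiffusionEstimate(max(slope, 0.0) / (2.0 * dims), window, dims)
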