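"""Free-energy machinery for sorting and tilting.

Profiles are reported in units of the thermal energy kBT and referenced
so the minimum (or the modal tilt bin) is exactly zero.  The 1D
potential of mean force over the sorting coordinate is reconstructed
from harmonically biased umbrella windows with the weighted histogram
analysis method (WHAM), mapped to membrane thickness through the linear
thickness-gradient fit, and combined additively with per-window tilt
free-energy profiles into a 2D surface over (thickness, tilt) whose
thermally accessible regions are extracted as sublevel-set components.
The additive composition neglects thickness-tilt correlation within a
window and is an approximation by construction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph

from .errors import AccuracyWarning, FitConvergenceError, ValidationError
from .thickness import LinearRegionFit

__all__ = [
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "FreeEnergySurface",
    "CoordinateMapping",
    "WHAMResult",
    "boltzmann_invert_density",
    "wham_1d",
    "tilt_free_energy",
    "compose_surface_2d",
    "accessible_regions",
]


@dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate under a harmonic bias.

    bias energy: 0.5 * stiffness * (x - center)^2, in kJ/mol when
    ``stiffness`` is in kJ mol^-1 nm^-2.  A stiffness of exactly zero
    marks an unbiased window.  ``theta_samples`` optionally carries the
    paired tilt angles for 2D composition.
    """

    center: float
    stiffness: float
    samples: np.ndarray
    theta_samples: np.ndarray | None = None
    label: str = ""
    min_samples: int = 10

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.stiffness < 0:
            raise ValidationError("stiffness must be >= 0")
        if self.samples.size < self.min_samples:
            raise ValidationError(
                f"window {self.label or self.center}: need >= {self.min_samples} samples"
            )
        if self.theta_samples is not None:
            self.theta_samples = np.asarray(self.theta_samples, dtype=float)

    def bias_energy(self, x) -> np.ndarray:
        return 0.5 * self.stiffness * (np.asarray(x, dtype=float) - self.center) ** 2


@dataclass
class FreeEnergyProfile:
    """1D free-energy profile in kBT units, zero at its reference point."""

    coordinates: np.ndarray
    values: np.ndarray  # kBT; NaN undefined
    reference_index: int

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.coordinates.shape != self.values.shape:
            raise ValidationError("coordinates and values must match")
        finite = self.values[np.isfinite(self.values)]
        if finite.size == 0:
            raise ValidationError("profile has no defined bins")
        if abs(float(np.min(finite))) > 1e-9:
            raise ValidationError("profile must be referenced to a minimum of 0")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class WHAMResult:
    """Outcome of the WHAM self-consistent iteration."""

    profile: FreeEnergyProfile
    window_free_energies: np.ndarray  # kBT, one per window, first fixed to 0
    n_iterations: int
    converged: bool


@dataclass(frozen=True)
class CoordinateMapping:
    """Strictly monotone linear map from position x to thickness d."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("mapping must be strictly monotone (slope != 0)")

    @classmethod
    def from_linear_fit(cls, fit: LinearRegionFit) -> "CoordinateMapping":
        return cls(fit.slope, fit.intercept)

    def __call__(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def inverse(self, d) -> np.ndarray:
        return (np.asarray(d, dtype=float) - self.intercept) / self.slope


@dataclass
class FreeEnergySurface:
    """2D free energy over (thickness d, tilt theta), kBT units, min = 0.

    Values above the mask cutoff are NaN; the cell holding the global
    minimum is never masked.
    """

    d_centers: np.ndarray
    theta_centers: np.ndarray
    values: np.ndarray  # shape (n_d, n_theta)
    minimum: tuple[float, float]  # (d, theta) of the global minimum
    mask_above: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.d_centers), len(self.theta_centers)):
            raise ValidationError("surface shape does not match axes")
        finite = self.values[np.isfinite(self.values)]
        if finite.size == 0 or abs(float(finite.min())) > 1e-9:
            raise ValidationError("surface must have a defined minimum of 0")


def boltzmann_invert_density(
    coordinates,
    density,
    kbt: float = 1.0,
) -> FreeEnergyProfile:
    """Free energy from an observed density: dF = -kBT ln(rho / rho_max).

    The reference (dF = 0) is the density maximum; zero-density bins are
    undefined (NaN).  ``kbt`` rescales the output; the default 1.0
    leaves the profile in kBT units.
    """
    coords = np.asarray(coordinates, dtype=float)
    rho = np.asarray(density, dtype=float)
    if np.any(rho < 0):
        raise ValidationError("density must be >= 0")
    if not np.any(rho > 0):
        raise ValidationError("density is identically zero")
    ref = int(np.nanargmax(rho))
    with np.errstate(divide="ignore"):
        values = np.where(rho > 0, -kbt * np.log(rho / rho[ref]), np.nan)
    return FreeEnergyProfile(coords, values, ref)


def _window_connectivity(counts: np.ndarray) -> None:
    """Error if window histograms form disconnected groups (no overlap)."""
    n_win = counts.shape[0]
    if n_win == 1:
        return
    occupied = counts > 0
    adj = (occupied @ occupied.T) > 0
    n_comp, labels = csgraph.connected_components(sparse.csr_matrix(adj), directed=False)
    if n_comp > 1:
        groups = [list(np.nonzero(labels == c)[0]) for c in range(n_comp)]
        raise ValidationError(
            f"umbrella windows do not overlap; disconnected groups (by index): {groups}"
        )


def wham_1d(
    windows: list[UmbrellaWindow],
    grid,
    kbt: float,
    tol: float = 1e-8,
    max_iterations: int = 100_000,
    min_overlap: float = 0.05,
) -> WHAMResult:
    """Standard binned WHAM over a 1D reaction coordinate.

    Parameters
    ----------
    windows
        Umbrella windows with samples and harmonic bias parameters
        (energies in kJ/mol).
    grid
        Bin edges, or a (lo, hi, n_bins) tuple.
    kbt
        Thermal energy in the same units as the bias (kJ/mol).
    tol
        Convergence tolerance on the per-window free-energy constants
        (kBT units).
    min_overlap
        Warn when adjacent windows share less than this fraction of
        their histogram mass.

    The self-consistent equations

        p_j ∝ sum_i n_ij / sum_i N_i f_i c_ij,   1/f_i = sum_j c_ij p_j

    with c_ij = exp(-w_i(x_j)/kBT) are iterated until the f constants
    are stable.  The returned profile is -ln p referenced to its
    minimum; bins with no samples are undefined.
    """
    if not windows:
        raise ValidationError("need at least one umbrella window")
    if kbt <= 0:
        raise ValidationError("kbt must be > 0")
    if isinstance(grid, tuple) and len(grid) == 3:
        edges = np.linspace(grid[0], grid[1], int(grid[2]) + 1)
    else:
        edges = np.asarray(grid, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_win, n_bins = len(windows), centers.size

    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows]).astype(float)
    _window_connectivity(counts)

    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        na, nb = counts[a].sum(), counts[b].sum()
        both = counts[a] * counts[b] > 0
        overlap = min(counts[a][both].sum() / na, counts[b][both].sum() / nb) if both.any() else 0.0
        if overlap < min_overlap:
            warnings.warn(
                f"adjacent windows at {windows[a].center} and {windows[b].center} "
                f"overlap by only {overlap:.1%}",
                AccuracyWarning,
                stacklevel=2,
            )

    n_i = counts.sum(axis=1)
    m_j = counts.sum(axis=0)
    c_ij = np.exp(-np.stack([w.bias_energy(centers) for w in windows]) / kbt)

    g = np.zeros(n_win)  # window free energies in kBT; f_i = exp(g_i)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        denom = (n_i * np.exp(g)) @ c_ij  # sum_i N_i f_i c_ij, per bin
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, m_j / denom, 0.0)
        norm = p.sum()
        if norm <= 0:
            raise ValidationError("WHAM produced an empty distribution; check samples")
        p /= norm
        with np.errstate(divide="ignore"):
            g_new = -np.log(c_ij @ p)
        g_new -= g_new[0]
        delta = float(np.max(np.abs(g_new - g)))
        g = g_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise FitConvergenceError(
            f"WHAM did not converge in {max_iterations} iterations (last delta {delta:.2e})",
            diagnostics={"delta": delta, "n_windows": n_win, "n_bins": n_bins},
        )

    with np.errstate(divide="ignore"):
        f_vals = np.where(m_j > 0, -np.log(np.where(p > 0, p, 1.0)), np.nan)
    f_vals -= np.nanmin(f_vals)
    ref = int(np.nanargmin(f_vals))
    profile = FreeEnergyProfile(centers, f_vals, ref)
    return WHAMResult(profile, g, n_iter, converged)


def tilt_free_energy(
    theta_samples,
    bins=None,
    theta_range: tuple[float, float] = (0.0, 90.0),
    bin_width: float = 1.0,
    min_samples: int = 10,
) -> FreeEnergyProfile:
    """Tilt free energy dF(theta) = -ln(P(theta)/P(theta0)) in kBT units.

    theta0 is the most likely (modal) tilt bin, where dF = 0 exactly;
    empty bins are undefined.  Default binning: 1 degree over [0, 90].
    """
    theta = np.asarray(theta_samples, dtype=float)
    if theta.size < min_samples:
        raise ValidationError(f"need >= {min_samples} tilt samples, got {theta.size}")
    if bins is None:
        lo, hi = theta_range
        bins = np.arange(lo, hi + bin_width / 2.0, bin_width)
    edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(theta, bins=edges)
    if counts.sum() == 0:
        raise ValidationError("all tilt samples fall outside the histogram range")
    mode = int(np.argmax(counts))
    with np.errstate(divide="ignore"):
        values = np.where(counts > 0, -np.log(counts / counts[mode]), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergyProfile(centers, values, mode)


def compose_surface_2d(
    pmf: FreeEnergyProfile,
    tilt_profiles: list[tuple[float, FreeEnergyProfile]],
    mapping: CoordinateMapping | None = None,
    mask_above: float = 10.0,
) -> FreeEnergySurface:
    """Additive 2D surface dF(d, theta) ≈ dF(d) + dF(theta | window at d).

    ``tilt_profiles`` pairs each window's position with its tilt
    profile; positions and the PMF coordinate are mapped to thickness
    through ``mapping`` when given (for a PMF over x), otherwise taken
    as thickness already.  Each thickness grid point uses the tilt
    profile of the nearest window.  The composed surface is
    re-referenced so its global minimum is exactly 0, and values above
    ``mask_above`` kBT are discarded (NaN); the minimum itself is never
    masked.  The sum neglects d-theta correlation within a window.
    """
    if not tilt_profiles:
        raise ValidationError("need at least one tilt profile")
    d_coords = np.asarray(pmf.coordinates, dtype=float)
    win_pos = np.array([p for p, _ in tilt_profiles], dtype=float)
    if mapping is not None:
        d_coords = mapping(d_coords)
        win_pos = mapping(win_pos)
        if d_coords[0] > d_coords[-1]:  # negative slope: keep grid increasing
            d_coords = d_coords[::-1]
            pmf_vals = pmf.values[::-1]
        else:
            pmf_vals = pmf.values
    else:
        pmf_vals = pmf.values
    if np.any(np.diff(d_coords) <= 0):
        raise ValidationError("thickness coordinate must be strictly monotone")

    theta = tilt_profiles[0][1].coordinates
    for _, prof in tilt_profiles[1:]:
        if prof.coordinates.shape != theta.shape or not np.allclose(prof.coordinates, theta):
            raise ValidationError("all tilt profiles must share one theta grid")

    nearest = np.abs(d_coords[:, None] - win_pos[None, :]).argmin(axis=1)
    surf = pmf_vals[:, None] + np.stack([tilt_profiles[k][1].values for k in nearest])

    finite = np.isfinite(surf)
    if not finite.any():
        raise ValidationError("composed surface has no defined cells")
    surf = surf - np.nanmin(surf[finite])
    i_min, j_min = np.unravel_index(np.nanargmin(np.where(finite, surf, np.inf)), surf.shape)
    masked = np.where(surf > mask_above, np.nan, surf)
    masked[i_min, j_min] = surf[i_min, j_min]  # never mask the minimum
    return FreeEnergySurface(
        d_coords, theta, masked, (float(d_coords[i_min]), float(theta[j_min])), mask_above
    )


def _intervals_from_mask(mask_1d: np.ndarray, centers: np.ndarray, half_width: float):
    """Merge a boolean bin mask into (lo, hi) intervals at bin-edge resolution."""
    intervals = []
    idx = np.nonzero(mask_1d)[0]
    if idx.size == 0:
        return intervals
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        intervals.append((centers[start] - half_width, centers[prev] + half_width))
        start = prev = i
    intervals.append((centers[start] - half_width, centers[prev] + half_width))
    return intervals


def _merge_overlapping(intervals):
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(iv) for iv in merged]


def accessible_regions(
    surface: FreeEnergySurface,
    thresholds=(1.0, 2.0, 5.0, 10.0),
) -> dict[float, dict[str, list[tuple[float, float]]]]:
    """Thermally accessible (d, theta) intervals per kBT threshold.

    For each threshold the sublevel set {dF <= threshold} is split into
    4-connected components; each component is projected onto the
    thickness and tilt axes, and overlapping projections are merged.
    Disjoint minima therefore appear as multiple intervals.  Regions
    are nested across increasing thresholds by construction.
    """
    d_half = 0.5 * float(np.median(np.diff(surface.d_centers))) if len(surface.d_centers) > 1 else 0.0
    t_half = 0.5 * float(np.median(np.diff(surface.theta_centers))) if len(surface.theta_centers) > 1 else 0.0
    out: dict[float, dict[str, list[tuple[float, float]]]] = {}
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    for thr in sorted(thresholds):
        mask = np.isfinite(surface.values) & (surface.values <= thr)
        labels, n_comp = ndimage.label(mask, structure=structure)
        d_ivs, t_ivs = [], []
        for comp in range(1, n_comp + 1):
            comp_mask = labels == comp
            d_ivs.extend(_intervals_from_mask(comp_mask.any(axis=1), surface.d_centers, d_half))
            t_ivs.extend(_intervals_from_mask(comp_mask.any(axis=0), surface.theta_centers, t_half))
        out[float(thr)] = {
            "d": _merge_overlapping(d_ivs),
            "theta": _merge_overlapping(t_ivs),
        }
    return out
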