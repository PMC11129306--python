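"""Peptide geometry and sorting observables.

Tilt theta is the polar angle between the peptide long axis (the
principal axis of its backbone beads) and the membrane normal, folded
to [0, 90] degrees since a rod has no head/tail distinction.  Azimuth
phi is the in-plane direction of the tilted axis relative to the
gradient axis, in [0, 360).  The projected hydrophobic length is
l_proj = l_TM cos(theta) and the realised hydrophobic mismatch is
l_mis = l_proj - d by default (negative when the peptide is shorter
than the local membrane, matching the sign of the mismatch force it
experiences along the gradient); the opposite convention d - l_proj is
selectable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PeptideObservation",
    "SortingStats",
    "UniformityTestResult",
    "TiltAzimuth",
    "hydrophobic_length",
    "tilt_and_azimuth",
    "projected_length_and_mismatch",
    "lateral_density_profile",
    "equilibrium_stats",
    "azimuth_uniformity_test",
    "observations_from_frames",
]

#: Hydrophobic length contributed by one leucine residue (nm).
NM_PER_LEUCINE = 0.15

MismatchConvention = Literal["proj-minus-d", "d-minus-proj"]


class TiltAzimuth(NamedTuple):
    theta_deg: float
    phi_deg: float  # NaN when undefined (theta == 0)
    phi_defined: bool


@dataclass(frozen=True)
class PeptideObservation:
    """Per-frame peptide state."""

    frame: int
    com: tuple[float, float, float]
    tilt_theta: float  # deg, [0, 90]
    azimuth_phi: float  # deg, [0, 360) or NaN
    l_tm: float  # nm
    l_proj: float  # nm
    local_thickness: float  # nm
    l_mis: float  # nm

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt_theta <= 90.0):
            raise ValidationError(f"tilt out of range: {self.tilt_theta}")
        if self.l_proj > self.l_tm + 1e-9:
            raise ValidationError("l_proj cannot exceed l_tm")


@dataclass(frozen=True)
class SortingStats:
    """Equilibrium means and standard deviations over an analysis window."""

    d_eq: tuple[float, float]  # (mean, sd) nm
    theta_eq: tuple[float, float]  # deg
    l_proj: tuple[float, float]  # nm
    l_mis: tuple[float, float]  # nm
    window: tuple[int, int]  # frame range [lo, hi)


@dataclass(frozen=True)
class UniformityTestResult:
    ks_statistic: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ks_statistic <= 1.0 and 0.0 <= self.p_value <= 1.0):
            raise ValidationError("KS statistic and p-value must lie in [0, 1]")


def hydrophobic_length(n_leucines: int) -> float:
    """Hydrophobic length of a polyleucine stretch: 0.15 nm per leucine."""
    if n_leucines <= 0:
        raise ValidationError(f"n_leucines must be >= 1, got {n_leucines}")
    return NM_PER_LEUCINE * n_leucines


def tilt_and_azimuth(
    backbone_positions: np.ndarray,
    gradient_axis: int = 0,
    normal_axis: int = 2,
) -> TiltAzimuth:
    """Tilt and azimuth of a bead rod from its principal axis.

    The axis is the largest-variance direction of the backbone bead
    coordinates (robust for coarse-grained helices), sign-folded so its
    component along the membrane normal is non-negative; theta is then
    automatically in [0, 90].  phi is measured from the gradient axis
    toward the remaining in-plane axis; for an untilted rod it is
    undefined and reported as NaN with ``phi_defined=False``.
    """
    pos = np.asarray(backbone_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] != 3:
        raise ValidationError("need >= 2 backbone beads of shape (n, 3)")
    centered = pos - pos.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValidationError("backbone beads are coincident; axis undefined")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[normal_axis] < 0:
        axis = -axis
    cos_t = np.clip(axis[normal_axis], -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_t)))

    in_plane_axes = [i for i in range(3) if i != normal_axis]
    if gradient_axis not in in_plane_axes:
        raise ValidationError("gradient_axis must differ from normal_axis")
    other_axis = next(i for i in in_plane_axes if i != gradient_axis)
    gx, gy = axis[gradient_axis], axis[other_axis]
    if np.hypot(gx, gy) < 1e-12:
        return TiltAzimuth(theta, float("nan"), False)
    phi = float(np.degrees(np.arctan2(gy, gx)) % 360.0)
    return TiltAzimuth(theta, phi, True)


def projected_length_and_mismatch(
    l_tm: float,
    theta_deg: float,
    local_d: float,
    convention: MismatchConvention = "proj-minus-d",
) -> tuple[float, float]:
    """Projected length l_TM cos(theta) and signed hydrophobic mismatch.

    Default convention ``proj-minus-d`` gives l_mis = l_proj - d
    (negative for a peptide shorter than its local membrane);
    ``d-minus-proj`` flips the sign.
    """
    if not np.isfinite(l_tm) or l_tm <= 0:
        raise ValidationError(f"l_tm must be finite and > 0, got {l_tm}")
    if not (np.isfinite(theta_deg) and np.isfinite(local_d)):
        raise ValidationError("theta and local thickness must be finite")
    l_proj = l_tm * float(np.cos(np.radians(theta_deg)))
    if convention == "proj-minus-d":
        l_mis = l_proj - local_d
    elif convention == "d-minus-proj":
        l_mis = local_d - l_proj
    else:
        raise ValidationError(f"unknown mismatch convention: {convention}")
    return l_proj, l_mis


def lateral_density_profile(
    x: Sequence[float],
    bin_width: float,
    x_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized lateral density of peptide COM positions along x.

    Returns (bin_centers, density); density integrates to 1 (sum of
    density times bin width equals 1).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("no observations in window")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    if x_range is None:
        lo, hi = float(x.min()), float(x.max())
        hi = max(hi, lo + bin_width)
    else:
        lo, hi = x_range
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def _resolve_window(frames: np.ndarray, window) -> np.ndarray:
    """Boolean mask for an analysis window over frame indices."""
    if window is None or window == "last-half":
        cut = frames.min() + (frames.max() + 1 - frames.min()) / 2.0
        return frames >= cut
    lo, hi = window
    return (frames >= lo) & (frames < hi)


def equilibrium_stats(observations: pd.DataFrame, window="last-half") -> SortingStats:
    """Means and standard deviations of d, theta, l_proj, l_mis over a window.

    ``window`` is ``"last-half"`` (default, the analysis window used for
    equilibrium values) or an explicit (lo, hi) frame range.
    """
    frames = observations["frame"].to_numpy()
    mask = _resolve_window(frames, window)
    if not mask.any():
        raise ValidationError(f"window {window} selects no observations")
    sub = observations[mask]

    def ms(col: str) -> tuple[float, float]:
        # frames with an undefined local thickness are excluded, not imputed
        v = sub[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            return float("nan"), float("nan")
        return float(np.mean(v)), float(np.std(v))

    win = (int(frames[mask].min()), int(frames[mask].max()) + 1)
    return SortingStats(ms("d_nm"), ms("theta_deg"), ms("lproj_nm"), ms("lmis_nm"), win)


def azimuth_uniformity_test(phi_samples: Sequence[float]) -> UniformityTestResult:
    """One-sample Kolmogorov-Smirnov test of azimuth uniformity.

    phi/360 is tested against the uniform distribution on [0, 1); a
    small p-value indicates directional tilt.
    """
    phi = np.asarray(phi_samples, dtype=float)
    if phi.size < 5:
        raise ValidationError(f"need >= 5 azimuth samples, got {phi.size}")
    if np.any(phi < 0.0) or np.any(phi >= 360.0):
        raise ValidationError("azimuth samples must lie in [0, 360)")
    res = stats.kstest(phi / 360.0, "uniform")
    return UniformityTestResult(float(res.statistic), float(res.pvalue), int(phi.size))


def observations_from_frames(
    frames,
    l_tm: float | None = None,
    local_half_extent: float = 0.75,
    min_local_beads: int = 3,
    convention: MismatchConvention = "proj-minus-d",
    gradient_axis: int = 0,
    normal_axis: int = 2,
) -> pd.DataFrame:
    """Build the per-frame observation table from a bead trajectory.

    Local thickness at the peptide uses the central-neighbourhood
    estimate: the leaflet-mean z difference over phosphate beads within
    ``local_half_extent`` (default 0.75 nm, i.e. a 3x3 block of 0.5 nm
    cells) of the peptide COM in x and y.  Columns: frame, x, y, z,
    theta_deg, phi_deg, d_nm, lproj_nm, lmis_nm.
    """
    if l_tm is None:
        l_tm = frames.l_tm
    if l_tm is None:
        raise ValidationError("l_tm must be given or recorded in the frame set")
    beads = frames.beads
    box_y = frames.box[1]
    rows = []
    for f, grp in beads.groupby("frame"):
        bb = grp[(grp["leaflet"] == "peptide") & (grp["role"] == "backbone")]
        if bb.empty:
            continue
        ta = tilt_and_azimuth(bb[["x", "y", "z"]].to_numpy(), gradient_axis, normal_axis)
        com = grp[grp["leaflet"] == "peptide"][["x", "y", "z"]].mean()
        phos = grp[grp["role"] == "phosphate"]
        dx = np.abs(phos["x"].to_numpy() - com["x"])
        dy = phos["y"].to_numpy() - com["y"]
        dy = np.abs(dy - box_y * np.round(dy / box_y))
        near = phos[(dx <= local_half_extent) & (dy <= local_half_extent)]
        zu = near[near["leaflet"] == "upper"]["z"]
        zl = near[near["leaflet"] == "lower"]["z"]
        if len(zu) < min_local_beads or len(zl) < min_local_beads:
            d_local = np.nan
        else:
            d_local = float(zu.mean() - zl.mean())
        if np.isfinite(d_local):
            l_proj, l_mis = projected_length_and_mismatch(
                l_tm, ta.theta_deg, d_local, convention
            )
        else:
            l_proj = l_tm * float(np.cos(np.radians(ta.theta_deg)))
            l_mis = np.nan
        rows.append(
            {
                "frame": int(f),
                "x": float(com["x"]),
                "y": float(com["y"]),
                "z": float(com["z"]),
                "theta_deg": ta.theta_deg,
                "phi_deg": ta.phi_deg,
                "d_nm": d_local,
                "lproj_nm": l_proj,
                "lmis_nm": l_mis,
            }
        )
    if not rows:
        raise ValidationError("no peptide backbone beads found in frames")
    return pd.DataFrame(rows)
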