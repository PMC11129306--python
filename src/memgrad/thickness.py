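"""Local membrane thickness from phosphate-marker beads.

Membrane thickness is measured as the interleaflet phosphate distance:
within a spatial bin, the difference between the mean z of upper-leaflet
phosphate beads and the mean z of lower-leaflet phosphate beads, pooled
over frames.  The module provides 1D profiles along the gradient axis
(x), ordinary-least-squares fits over the linear gradient region, 2D
peptide-centered maps, and thickness-perturbation extraction at the
peptide position.

Bins that do not reach ``min_count`` samples in *both* leaflets are
reported as NaN, never imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ValidationError

__all__ = [
    "ThicknessProfile",
    "LinearRegionFit",
    "ThicknessMap",
    "thickness_profile_1d",
    "fit_linear_region",
    "thickness_map_2d",
    "perturbation_at_peptide",
]


@dataclass
class ThicknessProfile:
    """Binned membrane thickness d(x) along the gradient axis.

    Parameters
    ----------
    bin_centers
        Strictly increasing bin centres (nm).
    thickness
        Thickness per bin (nm); NaN marks undefined bins.
    sample_counts
        Per-bin sample count (the smaller of the two leaflet counts);
        zero for model-predicted profiles.
    bin_width
        Width of each bin (nm).
    """

    bin_centers: np.ndarray
    thickness: np.ndarray
    sample_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    bin_width: float = 0.5

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.sample_counts is None:
            self.sample_counts = np.zeros_like(self.bin_centers, dtype=int)
        self.sample_counts = np.asarray(self.sample_counts)
        if self.bin_centers.ndim != 1 or self.bin_centers.shape != self.thickness.shape:
            raise ValidationError("bin_centers and thickness must be matching 1D arrays")
        if self.bin_centers.size > 1 and not np.all(np.diff(self.bin_centers) > 0):
            raise ValidationError("bin_centers must be strictly increasing")
        if self.bin_width <= 0:
            raise ValidationError(f"bin_width must be positive, got {self.bin_width}")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of bins where thickness is defined."""
        return np.isfinite(self.thickness)

    def interp(self, x) -> np.ndarray:
        """Linearly interpolate d(x) over the defined bins."""
        m = self.defined
        if not m.any():
            raise ValidationError("profile has no defined bins")
        return np.interp(np.asarray(x, dtype=float), self.bin_centers[m], self.thickness[m])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x_nm": self.bin_centers,
                "thickness_nm": self.thickness,
                "count": self.sample_counts,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ThicknessProfile":
        df = pd.read_csv(path)
        centers = df["x_nm"].to_numpy()
        width = float(np.median(np.diff(centers))) if len(centers) > 1 else 0.5
        counts = df["count"].to_numpy() if "count" in df else None
        return cls(centers, df["thickness_nm"].to_numpy(), counts, width)


@dataclass(frozen=True)
class LinearRegionFit:
    """OLS fit d(x) = intercept + slope * x over a stated x region."""

    slope: float  # nm/nm
    intercept: float  # nm
    r_squared: float
    region: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError(f"r_squared out of range: {self.r_squared}")

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class ThicknessMap:
    """2D thickness map in peptide-centered (x, y) coordinates.

    ``perturbation`` is map thickness minus the reference profile
    evaluated at the absolute x of each cell (averaged over frames with
    the same weights as the thickness estimate itself).
    """

    x_centers: np.ndarray  # relative to peptide COM, nm
    y_centers: np.ndarray
    thickness: np.ndarray  # shape (nx, ny), NaN undefined
    counts: np.ndarray
    cell: float
    perturbation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.thickness.shape != (len(self.x_centers), len(self.y_centers)):
            raise ValidationError("thickness grid shape does not match axes")


def _phosphates(frames) -> pd.DataFrame:
    beads = frames.beads if hasattr(frames, "beads") else frames
    phos = beads[beads["role"] == "phosphate"]
    if (phos["leaflet"] == "upper").sum() == 0 or (phos["leaflet"] == "lower").sum() == 0:
        raise ValidationError("frames must contain phosphate beads in both leaflets")
    return phos


def _binned_leaflet_means(x, z, edges, min_count):
    counts, _ = np.histogram(x, bins=edges)
    sums, _ = np.histogram(x, bins=edges, weights=z)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def thickness_profile_1d(
    frames,
    bin_width: float = 0.5,
    min_count: int = 10,
    x_range: tuple[float, float] | None = None,
) -> ThicknessProfile:
    """Estimate d(x) = mean(z_upper) - mean(z_lower) per x-bin, pooled over frames.

    Parameters
    ----------
    frames
        A :class:`~memgrad.surrogate.SyntheticFrameSet` or a bead table
        with columns ``role, leaflet, x, z``.
    bin_width
        Bin width along x (nm).
    min_count
        Minimum samples required in each leaflet for a bin to be defined.
    x_range
        Optional (lo, hi) extent; defaults to the frame-set box.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    phos = _phosphates(frames)
    if x_range is None:
        if hasattr(frames, "box"):
            x_range = (0.0, float(frames.box[0]))
        else:
            x_range = (float(phos["x"].min()), float(phos["x"].max()) + 1e-9)
    lo, hi = x_range
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)

    up = phos[phos["leaflet"] == "upper"]
    lowr = phos[phos["leaflet"] == "lower"]
    mu, cu = _binned_leaflet_means(up["x"].to_numpy(), up["z"].to_numpy(), edges, min_count)
    ml, cl = _binned_leaflet_means(lowr["x"].to_numpy(), lowr["z"].to_numpy(), edges, min_count)

    counts = np.minimum(cu, cl)
    ok = (cu >= min_count) & (cl >= min_count)
    d = np.where(ok, mu - ml, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ThicknessProfile(centers, d, counts, bin_width)


def fit_linear_region(profile: ThicknessProfile, region: tuple[float, float]) -> LinearRegionFit:
    """OLS line fit of the thickness profile restricted to ``region``.

    Requires at least 3 defined bins inside the region.
    """
    lo, hi = region
    if lo >= hi:
        raise ValidationError(f"region must satisfy lo < hi, got {region}")
    m = profile.defined & (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    if m.sum() < 3:
        raise FitError(f"need >=3 defined bins in region {region}, found {int(m.sum())}")
    res = stats.linregress(profile.bin_centers[m], profile.thickness[m])
    # linregress R^2 is rvalue**2; degenerate zero-variance y gives nan rvalue
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return LinearRegionFit(float(res.slope), float(res.intercept), r2, (float(lo), float(hi)))


def thickness_map_2d(
    frames,
    peptide_com_per_frame: pd.DataFrame | None = None,
    half_extent: float = 3.0,
    cell: float = 0.5,
    reference: ThicknessProfile | None = None,
    min_count: int = 10,
) -> ThicknessMap:
    """2D thickness map in coordinates relative to the peptide COM.

    Phosphate beads are re-binned per frame into a regular grid centred
    on the peptide, wrapping y to the minimum image; the per-cell
    estimator is the same leaflet-mean difference as the 1D profile.
    When a ``reference`` profile is supplied, the perturbation field
    (map minus reference at absolute x) is computed with frame weights
    matching the thickness estimate.
    """
    if cell <= 0 or half_extent <= 0:
        raise ValidationError("cell and half_extent must be positive")
    phos = _phosphates(frames)
    if peptide_com_per_frame is None:
        peptide_com_per_frame = getattr(frames, "peptide_com", None)
    if peptide_com_per_frame is None:
        raise ValidationError("peptide COM per frame is required")
    box_y = float(frames.box[1]) if hasattr(frames, "box") else None

    n_cells = max(1, int(round(2 * half_extent / cell)))
    edges = -half_extent + cell * np.arange(n_cells + 1)
    shape = (n_cells, n_cells)
    sums = {"upper": np.zeros(shape), "lower": np.zeros(shape)}
    cnts = {"upper": np.zeros(shape, dtype=int), "lower": np.zeros(shape, dtype=int)}
    ref_sum = np.zeros(shape)
    ref_wt = np.zeros(shape)

    com = peptide_com_per_frame.set_index("frame")
    for frame_idx, grp in phos.groupby("frame"):
        if frame_idx not in com.index:
            continue
        xc, yc = float(com.loc[frame_idx, "x"]), float(com.loc[frame_idx, "y"])
        dx = grp["x"].to_numpy() - xc
        dy = grp["y"].to_numpy() - yc
        if box_y:
            dy -= box_y * np.round(dy / box_y)  # minimum image in y
        for leaf in ("upper", "lower"):
            sel = grp["leaflet"].to_numpy() == leaf
            h_cnt, _, _ = np.histogram2d(dx[sel], dy[sel], bins=(edges, edges))
            h_sum, _, _ = np.histogram2d(
                dx[sel], dy[sel], bins=(edges, edges), weights=grp["z"].to_numpy()[sel]
            )
            cnts[leaf] += h_cnt.astype(int)
            sums[leaf] += h_sum
            if reference is not None and leaf == "upper":
                x_abs = xc + 0.5 * (edges[:-1] + edges[1:])
                ref_sum += h_cnt * reference.interp(x_abs)[:, None]
                ref_wt += h_cnt

    with np.errstate(invalid="ignore"):
        mu = np.where(cnts["upper"] > 0, sums["upper"] / np.maximum(cnts["upper"], 1), np.nan)
        ml = np.where(cnts["lower"] > 0, sums["lower"] / np.maximum(cnts["lower"], 1), np.nan)
    ok = (cnts["upper"] >= min_count) & (cnts["lower"] >= min_count)
    thick = np.where(ok, mu - ml, np.nan)
    counts = np.minimum(cnts["upper"], cnts["lower"])

    perturb = None
    if reference is not None:
        with np.errstate(invalid="ignore"):
            ref_map = np.where(ref_wt > 0, ref_sum / np.maximum(ref_wt, 1), np.nan)
        perturb = thick - ref_map

    centers = 0.5 * (edges[:-1] + edges[1:])
    return ThicknessMap(centers, centers.copy(), thick, counts, cell, perturb)


def perturbation_at_peptide(tmap: ThicknessMap, neighborhood: int = 1) -> float:
    """Thickness perturbation at the peptide position (map centre).

    Averages the perturbation field over the central
    (2*neighborhood+1)^2 cells (default 3x3), ignoring undefined cells.
    """
    if tmap.perturbation is None:
        raise ValidationError("map has no perturbation field; pass a reference profile")
    nx, ny = tmap.perturbation.shape
    ci, cj = nx // 2, ny // 2
    lo_i, hi_i = max(0, ci - neighborhood), min(nx, ci + neighborhood + 1)
    lo_j, hi_j = max(0, cj - neighborhood), min(ny, cj + neighborhood + 1)
    block = tmap.perturbation[lo_i:hi_i, lo_j:hi_j]
    if not np.isfinite(block).any():
        raise ValidationError("central cells of the perturbation map are undefined")
    return float(np.nanmean(block))
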