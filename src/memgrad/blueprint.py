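"""Gradient-membrane blueprints.

A thickness gradient is built by tiling a simulation box along x with
patches of single-lipid membranes of increasing hydrophobic thickness,
held in place by flat-bottom positional restraints, with adjacent
patches allowed to mix over a configurable overlap width.  The expected
thickness profile is the reference thickness of each lipid within its
pure interval and a linear interpolation across each overlap region,
which realises an approximately linear gradient over the central
("linear") region of the box.

Coordinate conventions: x is the gradient axis, z the membrane normal;
intervals are half-open [lo, hi); lengths in nm, energies in kJ/mol.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
import yaml

from .errors import SizingError, ValidationError
from .thickness import ThicknessProfile

__all__ = [
    "LipidSpec",
    "RestraintSpec",
    "PatchLayout",
    "Patch",
    "ThicknessTarget",
    "layout_patches",
    "predict_thickness_profile",
    "evaluate_expected_thickness",
    "optimize_overlap",
    "write_flat_bottom_restraints",
    "read_flat_bottom_restraints",
    "flat_bottom_energy",
    "load_blueprint_config",
]

RESTRAINT_DIALECT = "memgrad-flat-bottom-x/1"


@dataclass(frozen=True)
class LipidSpec:
    """A single lipid type and the thickness of its pure membrane."""

    name: str
    reference_thickness: float  # nm, single-component membrane
    count_per_leaflet: int = 0

    def __post_init__(self) -> None:
        if self.reference_thickness <= 0:
            raise ValidationError(f"reference_thickness must be > 0 for {self.name}")
        if self.count_per_leaflet < 0:
            raise ValidationError(f"count_per_leaflet must be >= 0 for {self.name}")


@dataclass(frozen=True)
class RestraintSpec:
    """Flat-bottom positional restraint along one axis.

    Zero potential for |x - center| <= half_width, harmonic wall
    0.5 * k * (|x - center| - half_width)^2 outside.  ``half_width``
    None means "derive per patch from its pure interval plus overlaps".
    """

    force_constant: float = 1000.0  # kJ mol^-1 nm^-2
    half_width: float | None = None  # nm
    axis: str = "x"

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValidationError("force_constant must be >= 0")
        if self.half_width is not None and self.half_width <= 0:
            raise ValidationError("half_width must be > 0 when given")


@dataclass(frozen=True)
class Patch:
    """One lipid patch: its pure x-interval and shared overlap widths."""

    lipid: LipidSpec
    pure_interval: tuple[float, float]  # [lo, hi)
    overlap_left: float = 0.0
    overlap_right: float = 0.0

    @property
    def coverage(self) -> tuple[float, float]:
        """Interval the lipid may occupy: pure interval plus overlaps."""
        lo, hi = self.pure_interval
        return (lo - self.overlap_left, hi + self.overlap_right)


@dataclass(frozen=True)
class ThicknessTarget:
    """Target gradient: slope (nm/nm) over a linear x-region."""

    slope: float
    linear_region: tuple[float, float]

    def __post_init__(self) -> None:
        if self.linear_region[0] >= self.linear_region[1]:
            raise ValidationError("linear_region must satisfy x_lo < x_hi")


@dataclass(frozen=True)
class PatchLayout:
    """Ordered lipid patches tiling [0, box_length_x) along the gradient axis."""

    box_length_x: float
    patches: tuple[Patch, ...]
    restraint: RestraintSpec = field(default_factory=RestraintSpec)

    def __post_init__(self) -> None:
        if self.box_length_x <= 0:
            raise ValidationError("box_length_x must be > 0")
        if not self.patches:
            raise ValidationError("layout needs at least one patch")
        names = [p.lipid.name for p in self.patches]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate lipid names in layout: {names}")
        prev_hi = None
        for p in self.patches:
            lo, hi = p.pure_interval
            if not (0.0 <= lo < hi <= self.box_length_x + 1e-9):
                raise ValidationError(f"pure interval {p.pure_interval} outside box")
            if prev_hi is not None and lo < prev_hi - 1e-9:
                raise ValidationError("pure intervals must be ordered and non-overlapping")
            prev_hi = hi

    @property
    def lipids(self) -> tuple[LipidSpec, ...]:
        return tuple(p.lipid for p in self.patches)


def layout_patches(
    lipids: Sequence[LipidSpec],
    box_length_x: float,
    overlap_widths: Sequence[float] = (),
    restraint: RestraintSpec | None = None,
) -> PatchLayout:
    """Tile the box with equal-width pure patches separated by overlap regions.

    Lipids are ordered by increasing reference thickness along +x.  The
    pure width of every patch is (box - sum(overlaps)) / n_lipids.
    """
    if len(lipids) < 1:
        raise ValidationError("need at least one lipid")
    names = [lipid.name for lipid in lipids]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate lipid names: {names}")
    overlap_widths = list(overlap_widths)
    if len(overlap_widths) != len(lipids) - 1:
        raise ValidationError(
            f"need {len(lipids) - 1} overlap widths for {len(lipids)} lipids, "
            f"got {len(overlap_widths)}"
        )
    if any(w < 0 for w in overlap_widths):
        raise ValidationError("overlap widths must be >= 0")

    ordered = sorted(lipids, key=lambda lipid: lipid.reference_thickness)
    pure_total = box_length_x - sum(overlap_widths)
    pure_width = pure_total / len(ordered)
    if pure_width <= 0:
        raise SizingError(
            f"box of {box_length_x} nm too short for overlaps summing to "
            f"{sum(overlap_widths)} nm"
        )

    patches = []
    cursor = 0.0
    for i, lipid in enumerate(ordered):
        left = overlap_widths[i - 1] if i > 0 else 0.0
        right = overlap_widths[i] if i < len(ordered) - 1 else 0.0
        patches.append(Patch(lipid, (cursor, cursor + pure_width), left, right))
        cursor += pure_width + right
    return PatchLayout(box_length_x, tuple(patches), restraint or RestraintSpec())


def evaluate_expected_thickness(layout: PatchLayout, x) -> np.ndarray:
    """Expected d(x): reference thickness in pure intervals, linear across overlaps."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    # Piecewise-linear node list: (x, d) at the ends of every pure interval.
    xs, ds = [], []
    for p in layout.patches:
        lo, hi = p.pure_interval
        xs.extend([lo, hi])
        ds.extend([p.lipid.reference_thickness] * 2)
    return np.interp(x, xs, ds)


def predict_thickness_profile(layout: PatchLayout, bin_width: float = 0.5) -> ThicknessProfile:
    """Expected thickness profile binned at ``bin_width`` over the box."""
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    n_bins = max(1, int(np.ceil(layout.box_length_x / bin_width - 1e-9)))
    centers = bin_width * (np.arange(n_bins) + 0.5)
    return ThicknessProfile(centers, evaluate_expected_thickness(layout, centers), None, bin_width)


def _max_deviation_from_line(layout: PatchLayout, region: tuple[float, float]) -> float:
    """Max |d(x) - best-fit line| over the region, on a fine grid."""
    lo, hi = region
    x = np.linspace(lo, hi, 1001)
    d = evaluate_expected_thickness(layout, x)
    coeffs = np.polyfit(x, d, 1)
    return float(np.max(np.abs(d - np.polyval(coeffs, x))))


def optimize_overlap(
    lipids: Sequence[LipidSpec],
    box_length_x: float,
    target: ThicknessTarget,
    candidate_overlaps: Sequence[float],
    restraint: RestraintSpec | None = None,
) -> PatchLayout:
    """Pick the uniform overlap width whose expected profile is most linear.

    Each candidate is a single overlap width applied between every pair
    of adjacent patches; the objective is the maximum absolute deviation
    of the expected profile from its own best-fit line over the target's
    linear region.  Ties break toward the smaller overlap.
    """
    candidates = list(candidate_overlaps)
    if not candidates:
        raise ValidationError("candidate_overlaps must not be empty")
    best = None
    for w in sorted(candidates):
        layout = layout_patches(lipids, box_length_x, [w] * (len(lipids) - 1), restraint)
        obj = _max_deviation_from_line(layout, target.linear_region)
        if best is None or obj < best[0] - 1e-12:
            best = (obj, layout)
    return best[1]


def flat_bottom_energy(x, center: float, half_width: float, force_constant: float):
    """Flat-bottom wall energy: 0 inside |x-center|<=half_width, harmonic outside."""
    excess = np.maximum(np.abs(np.asarray(x, dtype=float) - center) - half_width, 0.0)
    return 0.5 * force_constant * excess**2


def write_flat_bottom_restraints(layout: PatchLayout, sink: TextIO) -> None:
    """Serialize per-lipid flat-bottom x-restraints.

    The dialect is a GROMACS-style include-topology text block: one
    record per lipid type with the centre and half-width of the
    zero-force interval (the pure interval plus its overlaps) and the
    wall force constant.  Output is bit-stable across runs.
    """
    k = layout.restraint.force_constant
    sink.write(f"; {RESTRAINT_DIALECT} — flat-bottom positional restraints along "
               f"{layout.restraint.axis}\n")
    sink.write(f"; box_length_x_nm= {layout.box_length_x:.6f}\n")
    sink.write("[ flat_bottom_posres ]\n")
    sink.write("; lipid  center_nm  half_width_nm  force_constant_kJ_mol_nm2\n")
    for p in layout.patches:
        lo, hi = p.coverage
        center = 0.5 * (lo + hi)
        half = layout.restraint.half_width
        if half is None:
            half = 0.5 * (hi - lo)
        sink.write(f"{p.lipid.name}  {center:.6f}  {half:.6f}  {k:.6f}\n")


def read_flat_bottom_restraints(source: TextIO | str) -> list[dict]:
    """Parse the dialect written by :func:`write_flat_bottom_restraints`."""
    if isinstance(source, str):
        source = io.StringIO(source)
    records = []
    for line in source:
        line = line.strip()
        if not line or line.startswith((";", "[")):
            continue
        name, center, half, k = line.split()
        records.append(
            {
                "lipid": name,
                "center": float(center),
                "half_width": float(half),
                "force_constant": float(k),
            }
        )
    return records


def load_blueprint_config(path) -> dict:
    """Load a blueprint config (YAML key/value plus a per-lipid table).

    Recognised keys: ``box_length_x``, ``overlaps`` (list) or
    ``candidate_overlaps`` + ``target`` (slope, linear_region),
    ``bin_width``, ``restraint`` (force_constant, half_width, axis),
    ``lipids`` (list of name/reference_thickness/count_per_leaflet).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "lipids" not in cfg or "box_length_x" not in cfg:
        raise ValidationError("config must define box_length_x and lipids")
    cfg["lipids"] = [
        LipidSpec(
            str(entry["name"]),
            float(entry["reference_thickness"]),
            int(entry.get("count_per_leaflet", 0)),
        )
        for entry in cfg["lipids"]
    ]
    if "restraint" in cfg:
        r = cfg["restraint"]
        cfg["restraint"] = RestraintSpec(
            float(r.get("force_constant", 1000.0)),
            r.get("half_width"),
            str(r.get("axis", "x")),
        )
    return cfg
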