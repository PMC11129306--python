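"""Desk-scale surrogate of mismatch-driven peptide sorting.

Two generators live here:

1. :func:`simulate_sorting_ensemble` — replica ensembles of the peptide
   centre of mass x(t) under overdamped mean-reverting (Ornstein-
   Uhlenbeck) dynamics,

       dx = -(x - x_eq)/tau dt + sqrt(2 D) dW,

   the stochastic idealisation of a lateral force proportional to
   hydrophobic mismatch in a viscous medium.  An optional harmonic
   umbrella bias adds the drift -(k_b/gamma_eff)(x - x_c) with the
   mobility 1/gamma_eff = D/kBT fixed by fluctuation-dissipation, so
   biased runs have a well-defined temperature.

2. :func:`synthesize_membrane_trajectory` — bead-level frames of a
   bilayer realising a prescribed thickness profile (phosphate markers
   at z = +/- d/2 plus positional noise) with an embedded rigid helical
   rod whose tilt/azimuth are drawn per frame from user samplers.
   Every analysis module is testable against this ground truth without
   an MD engine.

All generators are deterministic given their seed.  Time unit: ns.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import AccuracyWarning, ValidationError
from .thickness import ThicknessProfile
from .units import KBT_300K

__all__ = [
    "UmbrellaBias",
    "SortingModelParams",
    "EnsembleTrajectory",
    "PeptideTemplate",
    "SyntheticFrameSet",
    "simulate_sorting_ensemble",
    "synthesize_membrane_trajectory",
    "constant_sampler",
    "uniform_azimuth_sampler",
    "boltzmann_tilt_sampler",
]

Sampler = Callable[[np.random.Generator, int], np.ndarray]


@dataclass(frozen=True)
class UmbrellaBias:
    """Harmonic umbrella bias 0.5 * stiffness * (x - center)^2 (kJ/mol)."""

    center: float  # nm
    stiffness: float  # kJ mol^-1 nm^-2

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValidationError("bias stiffness must be > 0")


@dataclass(frozen=True)
class SortingModelParams:
    """Parameters of the mean-reverting sorting model (lengths nm, times ns)."""

    x_eq: float
    tau: float
    diffusion: float
    x0: float
    n_steps: int
    dt: float | None = None  # default tau/100
    n_replicas: int = 1
    seed: int | None = None
    bias: UmbrellaBias | None = None
    kbt: float = KBT_300K  # kJ/mol; sets the mobility of biased runs

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError(f"tau must be > 0, got {self.tau}")
        if self.diffusion < 0:
            raise ValidationError("diffusion must be >= 0")
        if self.n_replicas < 1 or self.n_steps < 1:
            raise ValidationError("n_replicas and n_steps must be >= 1")
        if self.dt is not None and self.dt <= 0:
            raise ValidationError("dt must be > 0")

    @property
    def effective_dt(self) -> float:
        return self.tau / 100.0 if self.dt is None else self.dt


@dataclass
class EnsembleTrajectory:
    """Replica ensemble of x(t): positions has shape (n_replicas, n_steps + 1)."""

    times: np.ndarray  # ns
    positions: np.ndarray  # nm, unwrapped
    params: SortingModelParams
    seed: int | None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.params.n_replicas, self.times.size):
            raise ValidationError("positions shape inconsistent with params")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions contain non-finite values")

    def mean_path(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def save_npz(self, path) -> None:
        meta = {
            "x_eq": self.params.x_eq,
            "tau": self.params.tau,
            "diffusion": self.params.diffusion,
            "x0": self.params.x0,
            "n_steps": self.params.n_steps,
            "dt": self.params.effective_dt,
            "n_replicas": self.params.n_replicas,
            "seed": self.seed,
            "bias": None if self.params.bias is None else
                    [self.params.bias.center, self.params.bias.stiffness],
            "kbt": self.params.kbt,
        }
        np.savez(path, times=self.times, positions=self.positions,
                 meta=json.dumps(meta))

    @classmethod
    def load_npz(cls, path) -> "EnsembleTrajectory":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        bias = None if meta["bias"] is None else UmbrellaBias(*meta["bias"])
        params = SortingModelParams(
            x_eq=meta["x_eq"], tau=meta["tau"], diffusion=meta["diffusion"],
            x0=meta["x0"], n_steps=meta["n_steps"], dt=meta["dt"],
            n_replicas=meta["n_replicas"], seed=meta["seed"], bias=bias,
            kbt=meta["kbt"],
        )
        return cls(data["times"], data["positions"], params, meta["seed"])


def simulate_sorting_ensemble(params: SortingModelParams) -> EnsembleTrajectory:
    """Euler-Maruyama integration of the (optionally biased) OU sorting model.

    Accuracy contract: dt >= tau is an error; dt >= tau/10 warns, since
    the explicit integrator then resolves the relaxation poorly.
    """
    dt = params.effective_dt
    if dt >= params.tau:
        raise ValidationError(f"dt={dt} must be smaller than tau={params.tau}")
    if dt >= params.tau / 10.0:
        warnings.warn(
            f"dt={dt} is >= tau/10; integration error grows as O(dt)",
            AccuracyWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    n_rep, n_steps = params.n_replicas, params.n_steps
    x = np.full(n_rep, float(params.x0))
    out = np.empty((n_rep, n_steps + 1))
    out[:, 0] = x
    noise_amp = np.sqrt(2.0 * params.diffusion * dt)
    bias_rate = 0.0
    if params.bias is not None:
        # mobility 1/gamma_eff = D/kBT (fluctuation-dissipation)
        bias_rate = params.bias.stiffness * params.diffusion / params.kbt
    for step in range(1, n_steps + 1):
        drift = -(x - params.x_eq) / params.tau
        if params.bias is not None:
            drift = drift - bias_rate * (x - params.bias.center)
        x = x + drift * dt
        if noise_amp > 0:
            x = x + noise_amp * rng.standard_normal(n_rep)
        out[:, step] = x
    times = dt * np.arange(n_steps + 1)
    return EnsembleTrajectory(times, out, params, params.seed)


# ---------------------------------------------------------------------------
# orientation samplers


def constant_sampler(value_deg: float) -> Sampler:
    """Sampler returning a fixed angle (degrees) every frame."""
    return lambda rng, size: np.full(size, float(value_deg))


def uniform_azimuth_sampler() -> Sampler:
    """Uniform azimuth on [0, 360) degrees."""
    return lambda rng, size: rng.uniform(0.0, 360.0, size)


def boltzmann_tilt_sampler(
    free_energy_deg: Callable[[np.ndarray], np.ndarray],
    kbt: float = 1.0,
    theta_max: float = 90.0,
    grid_points: int = 2001,
) -> Sampler:
    """Tilt sampler with density p(theta) ∝ sin(theta) exp(-F(theta)/kBT).

    ``free_energy_deg`` maps tilt in degrees to an energy in the units
    of ``kbt``.  Sampling uses inverse-CDF interpolation on a fine grid.
    """
    theta = np.linspace(0.0, theta_max, grid_points)
    dens = np.sin(np.radians(theta)) * np.exp(-np.asarray(free_energy_deg(theta)) / kbt)
    if not np.all(np.isfinite(dens)) or dens.sum() <= 0:
        raise ValidationError("free energy produced an unnormalisable tilt density")
    cdf = np.cumsum(dens)
    cdf = cdf / cdf[-1]

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.interp(rng.uniform(0, 1, size), cdf, theta)

    return sample


# ---------------------------------------------------------------------------
# bead-level fixture generator


@dataclass(frozen=True)
class PeptideTemplate:
    """Rigid helical rod embedded at the bilayer midplane.

    ``x_com`` may be a scalar or a per-frame sequence; the hydrophobic
    stretch of length l_TM is rendered as backbone beads at
    ``bead_spacing``, flanked by one terminal anchor bead at each end.
    """

    l_tm: float  # nm
    x_com: float | np.ndarray
    tilt_sampler: Sampler
    azimuth_sampler: Sampler
    y_com: float | None = None  # default: box centre
    bead_spacing: float = 0.3  # nm
    anchor_length: float = 0.3  # nm beyond each hydrophobic terminus

    def __post_init__(self) -> None:
        if self.l_tm <= 0:
            raise ValidationError("l_tm must be > 0")


@dataclass
class SyntheticFrameSet:
    """Bead records of a synthetic membrane/peptide trajectory.

    ``beads`` columns: frame, bead_id, role (phosphate|backbone|anchor),
    leaflet (upper|lower|peptide), x, y, z.  ``peptide_com`` has one row
    per frame (frame, x, y, z); ``tilt_deg``/``azimuth_deg`` record the
    angles actually drawn per frame (generator ground truth).
    """

    beads: pd.DataFrame
    box: tuple[float, float, float]
    profile: ThicknessProfile | None = None
    l_tm: float | None = None
    peptide_com: pd.DataFrame | None = None
    tilt_deg: np.ndarray | None = None
    azimuth_deg: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"frame", "bead_id", "role", "leaflet", "x", "y", "z"}
        if not required.issubset(self.beads.columns):
            raise ValidationError(f"beads table must have columns {sorted(required)}")

    @property
    def n_frames(self) -> int:
        return int(self.beads["frame"].max()) + 1

    def write_columnar(self, path) -> None:
        """Plain-text fallback format: JSON metadata line + CSV bead table."""
        meta = {
            "box": list(self.box),
            "l_tm": self.l_tm,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            fh.write("# memgrad-columnar/1 " + json.dumps(meta) + "\n")
            self.beads.to_csv(fh, index=False)

    @classmethod
    def read_columnar(cls, path) -> "SyntheticFrameSet":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# memgrad-columnar/1 "):
                raise ValidationError(f"{path} is not a memgrad columnar file")
            meta = json.loads(header.split(" ", 2)[2])
            beads = pd.read_csv(fh)
        fs = cls(beads, tuple(meta["box"]), l_tm=meta["l_tm"], seed=meta["seed"])
        fs.peptide_com = _peptide_com_table(beads)
        return fs

    def write_gro(self, path, frame: int = 0) -> None:
        """Write one frame as a GRO coordinate file via MDAnalysis."""
        import MDAnalysis as mda

        grp = self.beads[self.beads["frame"] == frame]
        n = len(grp)
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("names", [_bead_name(r) for r in grp["role"]])
        u.add_TopologyAttr("resids", [1])
        u.add_TopologyAttr("resnames", ["MEM"])
        u.atoms.positions = grp[["x", "y", "z"]].to_numpy() * 10.0  # nm -> Angstrom
        u.dimensions = [self.box[0] * 10, self.box[1] * 10, self.box[2] * 10, 90, 90, 90]
        u.atoms.write(str(path))


def _bead_name(role: str) -> str:
    return {"phosphate": "PO4", "backbone": "BB", "anchor": "ANC"}.get(role, "X")


def _peptide_com_table(beads: pd.DataFrame) -> pd.DataFrame | None:
    pep = beads[beads["leaflet"] == "peptide"]
    if pep.empty:
        return None
    com = pep.groupby("frame")[["x", "y", "z"]].mean().reset_index()
    return com


def _rod_axis(tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    t, p = np.radians(tilt_deg), np.radians(azimuth_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def synthesize_membrane_trajectory(
    profile: ThicknessProfile,
    n_lipids_per_leaflet: int,
    n_frames: int,
    positional_noise_sd: float = 0.0,
    peptide: PeptideTemplate | None = None,
    box_y: float = 10.0,
    box_z: float | None = None,
    perturbation: tuple[float, float] | None = None,
    seed: int | None = None,
) -> SyntheticFrameSet:
    """Generate phosphate-marker frames realising ``profile`` plus a rod peptide.

    Upper/lower leaflet beads sit at z = +/- d(x)/2 with isotropic
    Gaussian positional noise of ``positional_noise_sd`` added to z;
    lateral (x, y) positions are redrawn uniformly each frame, which
    emulates fast lateral lipid mixing and gives homogeneous bin
    coverage.  ``perturbation`` = (depth, sigma) encodes a Gaussian
    thickness dimple (depth < 0) or bulge (depth > 0) centred on the
    peptide, for validating perturbation-map analyses.
    """
    if positional_noise_sd < 0:
        raise ValidationError("positional_noise_sd must be >= 0")
    if n_lipids_per_leaflet < 1 or n_frames < 1:
        raise ValidationError("need >= 1 lipid per leaflet and >= 1 frame")
    rng = np.random.default_rng(seed)
    box_x = float(profile.bin_centers[-1] + profile.bin_width / 2.0)
    if box_z is None:
        box_z = float(np.nanmax(profile.thickness)) + 4.0
    box = (box_x, float(box_y), float(box_z))

    pep_x = None
    tilt = azim = None
    if peptide is not None:
        full_len = peptide.l_tm + 2 * peptide.anchor_length
        if full_len > box[2]:
            raise ValidationError(
                f"peptide span {full_len} nm exceeds box z-dimension {box[2]} nm"
            )
        pep_x = np.broadcast_to(np.asarray(peptide.x_com, dtype=float), (n_frames,))
        pep_y = peptide.y_com if peptide.y_com is not None else box_y / 2.0
        tilt = np.asarray(peptide.tilt_sampler(rng, n_frames), dtype=float)
        azim = np.asarray(peptide.azimuth_sampler(rng, n_frames), dtype=float)

    records = []
    for f in range(n_frames):
        for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
            x = rng.uniform(0.0, box_x, n_lipids_per_leaflet)
            y = rng.uniform(0.0, box_y, n_lipids_per_leaflet)
            d = profile.interp(x)
            if perturbation is not None and peptide is not None:
                depth, sigma = perturbation
                dy = y - pep_y
                dy -= box_y * np.round(dy / box_y)
                r2 = (x - pep_x[f]) ** 2 + dy**2
                d = d + depth * np.exp(-r2 / (2.0 * sigma**2))
            z = sign * d / 2.0
            if positional_noise_sd > 0:
                z = z + positional_noise_sd * rng.standard_normal(n_lipids_per_leaflet)
            records.append(
                pd.DataFrame(
                    {
                        "frame": f,
                        "bead_id": np.arange(n_lipids_per_leaflet)
                        + (0 if leaflet == "upper" else n_lipids_per_leaflet),
                        "role": "phosphate",
                        "leaflet": leaflet,
                        "x": x,
                        "y": y,
                        "z": z,
                    }
                )
            )
        if peptide is not None:
            axis = _rod_axis(tilt[f], azim[f])
            half = peptide.l_tm / 2.0
            n_bb = int(round(peptide.l_tm / peptide.bead_spacing)) + 1
            offsets = np.linspace(-half, half, n_bb)
            offsets = np.concatenate(
                [[-half - peptide.anchor_length], offsets, [half + peptide.anchor_length]]
            )
            roles = ["anchor"] + ["backbone"] * n_bb + ["anchor"]
            center = np.array([pep_x[f], pep_y, 0.0])
            pos = center[None, :] + offsets[:, None] * axis[None, :]
            records.append(
                pd.DataFrame(
                    {
                        "frame": f,
                        "bead_id": 2 * n_lipids_per_leaflet + np.arange(len(offsets)),
                        "role": roles,
                        "leaflet": "peptide",
                        "x": pos[:, 0],
                        "y": pos[:, 1],
                        "z": pos[:, 2],
                    }
                )
            )

    beads = pd.concat(records, ignore_index=True)
    com = _peptide_com_table(beads)
    return SyntheticFrameSet(
        beads, box, profile=profile, l_tm=None if peptide is None else peptide.l_tm,
        peptide_com=com, tilt_deg=tilt, azimuth_deg=azim, seed=seed,
    )
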