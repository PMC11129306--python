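"""Reference equilibrium observables for the K2(L)nK2 polyleucine series.

Published coarse-grained equilibrium values for seven lysine-anchored
polyleucine peptides (17-29 leucines) sorting freely in a four-lipid
membrane thickness gradient: preferred local thickness d_eq, tilt angle
theta_eq, projected hydrophobic length l_proj and realised mismatch
l_mis (all mean +/- sd over the equilibrated window).  These printed
values serve as inputs to the package's worked examples and
consistency checks; they are not recomputed here.
"""
from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "PeptideRecord",
    "POLYLEUCINE_SERIES",
    "GRADIENT_SLOPE_NM_PER_NM",
    "LINEAR_REGION_NM",
    "SORTING_TIME_CONSTANT_NS",
    "LATERAL_DIFFUSION_RANGE_NM2_PER_NS",
    "SINGLE_LIPID_THICKNESS_RANGE_NM",
]


class PeptideRecord(NamedTuple):
    """One polyleucine peptide and its equilibrium sorting observables."""

    name: str
    n_leucines: int
    l_tm: float  # nm, hydrophobic length (0.15 nm per leucine)
    d_eq: float  # nm, preferred local thickness (mean)
    d_eq_sd: float
    theta_eq: float  # deg, equilibrium tilt (mean)
    theta_eq_sd: float
    l_proj: float  # nm, projected hydrophobic length (mean)
    l_proj_sd: float
    l_mis: float  # nm, realised mismatch l_proj - d_eq (mean)
    l_mis_sd: float


POLYLEUCINE_SERIES: tuple[PeptideRecord, ...] = (
    PeptideRecord("Leu17", 17, 2.55, 3.3, 0.5, 23, 10, 2.3, 0.4, -1.0, 0.9),
    PeptideRecord("Leu19", 19, 2.85, 3.5, 0.6, 25, 11, 2.6, 0.5, -0.9, 1.1),
    PeptideRecord("Leu21", 21, 3.15, 3.8, 0.6, 26, 12, 2.8, 0.6, -1.0, 1.2),
    PeptideRecord("Leu23", 23, 3.45, 4.3, 0.4, 17, 8, 3.3, 0.3, -1.0, 0.7),
    PeptideRecord("Leu25", 25, 3.75, 4.5, 0.4, 23, 9, 3.4, 0.5, -1.1, 0.9),
    PeptideRecord("Leu27", 27, 4.05, 4.8, 0.6, 16, 8, 3.9, 0.3, -0.9, 0.9),
    PeptideRecord("Leu29", 29, 4.35, 5.1, 0.2, 23, 8, 4.0, 0.5, -1.1, 0.7),
)

#: Thickness-gradient slope realised by the four-lipid blueprint (nm/nm).
GRADIENT_SLOPE_NM_PER_NM = 0.077

#: Linear gradient region along x (nm).
LINEAR_REGION_NM = (8.0, 32.0)

#: Fitted exponential sorting time constant (ns) of the 100-replica
#: relaxation experiment; ground truth for the surrogate.
SORTING_TIME_CONSTANT_NS = 2800.0

#: Lateral peptide diffusion range in the gradient membrane (nm^2/ns).
LATERAL_DIFFUSION_RANGE_NM2_PER_NS = (0.015, 0.027)

#: Thickness range spanned by the four pure single-lipid membranes (nm).
SINGLE_LIPID_THICKNESS_RANGE_NM = (3.34, 4.95)
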