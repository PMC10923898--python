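"""Solvent accessibility and the structured superficial region (SSUP).

SASA is computed with an internal Shrake–Rupley implementation (probe
1.4 Å, 960 sphere points per atom by default, heavy atoms only — AlphaFold
models carry no hydrogens).  RSA divides each residue's SASA by a
published maximum-ASA value; residues with RSA strictly above 0.25 are
exposed.  SSUP is the set of exposed residues outside every IDR.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .disorder import SegmentSet
from .structure_io import ProteinModel, StructureError

RSA_CUTOFF = 0.25
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960

#: Element-based van der Waals radii, Å.
VDW_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70

#: Maximum ASA normalisation tables (Å² per residue type).
MAX_ASA_TABLES: Dict[str, Dict[str, float]] = {
    # Tien et al. 2013, theoretical
    "tien-theoretical": {
        "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
        "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
        "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
        "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    },
    # Tien et al. 2013, empirical
    "tien-empirical": {
        "A": 121.0, "R": 265.0, "N": 187.0, "D": 187.0, "C": 148.0,
        "E": 214.0, "Q": 214.0, "G": 97.0, "H": 216.0, "I": 195.0,
        "L": 191.0, "K": 230.0, "M": 203.0, "F": 228.0, "P": 154.0,
        "S": 143.0, "T": 163.0, "W": 264.0, "Y": 255.0, "V": 165.0,
    },
    # Rost & Sander 1994
    "sander": {
        "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
        "E": 194.0, "Q": 198.0, "G": 84.0, "H": 184.0, "I": 169.0,
        "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
        "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
    },
}


@dataclasses.dataclass
class SurfaceProfile:
    sasa: np.ndarray  # per-residue, Å²
    rsa: np.ndarray
    exposed: np.ndarray  # boolean

    def __post_init__(self) -> None:
        if not (len(self.sasa) == len(self.rsa) == len(self.exposed)):
            raise ValueError("surface arrays of unequal length")


def sphere_points(n: int) -> np.ndarray:
    """n approximately uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_sasa(
    model: ProteinModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    radii: Dict[str, float] | None = None,
) -> np.ndarray:
    """Shrake–Rupley per-residue SASA (Å²), heavy atoms summed per residue."""
    radii = radii or VDW_RADII
    positions: List[np.ndarray] = []
    atom_radius: List[float] = []
    residue_of: List[int] = []
    for ri, res in enumerate(model.residues):
        if not res.atoms:
            raise StructureError(f"residue {res.index} ({res.aa}) has no atoms")
        for atom in res.atoms:
            if atom.element.upper() == "H":
                continue
            positions.append(atom.position)
            atom_radius.append(radii.get(atom.element.upper(), _DEFAULT_RADIUS))
            residue_of.append(ri)
    pos = np.asarray(positions)
    rad = np.asarray(atom_radius) + probe_radius
    res_idx = np.asarray(residue_of)

    unit = sphere_points(n_points)
    tree = cKDTree(pos)
    sasa = np.zeros(len(model))
    for k in range(len(pos)):
        neighbours = tree.query_ball_point(pos[k], rad[k] + rad.max())
        neighbours = [j for j in neighbours if j != k]
        pts = pos[k] + rad[k] * unit
        if neighbours:
            npos = pos[neighbours]
            nrad = rad[neighbours]
            d2 = ((pts[:, None, :] - npos[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < nrad[None, :] ** 2).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_points
        sasa[res_idx[k]] += 4.0 * np.pi * rad[k] ** 2 * accessible / n_points
    return sasa


def compute_rsa(
    sasa: Sequence[float],
    sequence: str,
    table: str | Dict[str, float] = "tien-theoretical",
) -> np.ndarray:
    """Per-residue RSA = SASA / max-ASA(residue type)."""
    if isinstance(table, str):
        table = MAX_ASA_TABLES[table]
    sasa = np.asarray(sasa, dtype=float)
    if len(sasa) != len(sequence):
        raise ValueError("sasa/sequence length mismatch")
    try:
        max_asa = np.array([table[aa] for aa in sequence])
    except KeyError as exc:
        raise ValueError(f"unknown amino acid {exc.args[0]!r}") from None
    return sasa / max_asa


def exposed_mask(rsa: Sequence[float], cutoff: float = RSA_CUTOFF) -> np.ndarray:
    """True where RSA > cutoff (strict)."""
    return np.asarray(rsa, dtype=float) > cutoff


def surface_profile(
    model: ProteinModel,
    table: str | Dict[str, float] = "tien-theoretical",
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    rsa_cutoff: float = RSA_CUTOFF,
) -> SurfaceProfile:
    sasa = compute_sasa(model, probe_radius=probe_radius, n_points=n_points)
    rsa = compute_rsa(sasa, model.sequence, table=table)
    return SurfaceProfile(sasa=sasa, rsa=rsa, exposed=exposed_mask(rsa, rsa_cutoff))


def derive_ssup(
    exposed: Sequence[bool], idrs: SegmentSet, n: int
) -> Tuple[int, ...]:
    """SSUP residue indices (1-based): exposed and outside every IDR."""
    exposed = np.asarray(exposed, dtype=bool)
    if len(exposed) != n:
        raise ValueError("exposed mask length mismatch")
    idr_mask = idrs.to_mask(n)
    return tuple(int(i) + 1 for i in np.nonzero(exposed & ~idr_mask)[0])
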