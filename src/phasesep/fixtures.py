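"""Synthetic structures and datasets with analytically known ground truth.

Three generators back the test suite and the CLI ``fixtures`` subcommand:

* :func:`make_structure` — backbone-only models built from ideal
  phi/psi geometry (helix, extended) or a clash-avoiding random coil,
  with per-segment pLDDT written into the B-factor column;
* :func:`make_sticker_toy` — spatially separated clusters of charged
  residues whose expected sticker counts follow from the construction;
* :func:`make_labeled_features` — feature tables matching the real
  schema with a plantable class signal on SSUP features.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import feature_names
from .structure_io import Atom, ProteinModel, Residue

# Ideal backbone geometry (lengths Å, angles degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "extended": (-135.0, 135.0),
}

_MIN_CA_SEPARATION = 3.2  # Å, non-adjacent residues


@dataclasses.dataclass
class FixtureSegment:
    length: int
    geometry: str  # helix | extended | coil
    plddt: float
    pattern: str = "GASLKE"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if not 0 <= self.plddt <= 100:
            raise ValueError("pLDDT outside [0, 100]")
        if self.geometry not in ("helix", "extended", "coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclasses.dataclass
class FixtureSpec:
    segments: List[FixtureSegment]
    seed: int = 0
    name: str = "fixture"


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position a fourth atom from three predecessors."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -length * math.cos(ang),
        length * math.sin(ang) * math.cos(tor),
        length * math.sin(ang) * math.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(phis: Sequence[float], psis: Sequence[float]) -> List[Dict[str, np.ndarray]]:
    n = len(phis)
    atoms: List[Dict[str, np.ndarray]] = []
    N0 = np.zeros(3)
    CA0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C0 = CA0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    atoms.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = atoms[i - 1]
        Ni = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psis[i - 1])
        CAi = _place(prev["CA"], prev["C"], Ni, _B_N_CA, _A_C_N_CA, _OMEGA)
        Ci = _place(prev["C"], Ni, CAi, _B_CA_C, _A_N_CA_C, phis[i])
        atoms.append({"N": Ni, "CA": CAi, "C": Ci})
    for i in range(n):
        atoms[i]["O"] = _place(
            atoms[i]["N"], atoms[i]["CA"], atoms[i]["C"],
            _B_C_O, _A_CA_C_O, psis[i] + 180.0,
        )
    return atoms


def make_structure(spec: FixtureSpec, max_attempts: int = 50) -> ProteinModel:
    """Build a backbone-only model from the segment plan.

    Coil segments draw a smooth phi/psi random walk; the whole chain is
    rejected and resampled when non-adjacent Cα atoms come closer than
    3.2 Å, and an error is raised when no clash-free chain is found.
    """
    rng = np.random.default_rng(spec.seed)
    total = sum(s.length for s in spec.segments)
    for _ in range(max_attempts):
        phis: List[float] = []
        psis: List[float] = []
        aas: List[str] = []
        plddts: List[float] = []
        for seg in spec.segments:
            if seg.geometry in PHI_PSI:
                phi, psi = PHI_PSI[seg.geometry]
                phis += [phi] * seg.length
                psis += [psi] * seg.length
            else:
                phi = rng.uniform(-150, -60)
                psi = rng.uniform(60, 150)
                for _i in range(seg.length):
                    phi = float(np.clip(phi + rng.normal(0, 20), -170, -50))
                    psi = float(np.clip(psi + rng.normal(0, 20), 40, 170))
                    phis.append(phi)
                    psis.append(psi)
            for k in range(seg.length):
                aas.append(seg.pattern[k % len(seg.pattern)])
                plddts.append(seg.plddt)
        backbone = _build_backbone(phis, psis)
        ca = np.array([b["CA"] for b in backbone])
        diff = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        iu = np.triu_indices(total, k=2)
        if total > 2 and (diff[iu] < _MIN_CA_SEPARATION).any():
            continue
        residues = [
            Residue(
                index=i + 1,
                aa=aas[i],
                atoms=[
                    Atom("N", "N", backbone[i]["N"]),
                    Atom("CA", "C", backbone[i]["CA"]),
                    Atom("C", "C", backbone[i]["C"]),
                    Atom("O", "O", backbone[i]["O"]),
                ],
                plddt=plddts[i],
            )
            for i in range(total)
        ]
        return ProteinModel(id=spec.name, sequence="".join(aas), residues=residues)
    raise RuntimeError("could not build a clash-free fixture chain")


# Local atom template around each toy Cα (keeps SASA well-defined).
_TOY_TEMPLATE = {
    "N": np.array([-1.2, 0.6, 0.0]),
    "CA": np.zeros(3),
    "C": np.array([1.2, 0.6, 0.0]),
    "O": np.array([1.8, 1.6, 0.3]),
}
# In-cluster Cα offsets: pairwise 3.8–9 Å, comfortably under the 14 Å cut.
_CLUSTER_OFFSETS = np.array([
    [0.0, 0.0, 0.0],
    [4.5, 0.0, 0.0],
    [0.0, 4.5, 0.0],
    [4.5, 4.5, 0.0],
    [2.25, 2.25, 4.0],
    [0.0, 0.0, 6.0],
    [4.5, 0.0, 6.0],
    [0.0, 4.5, 6.0],
])


def make_sticker_toy(
    n_pos_clusters: int,
    n_neg_clusters: int,
    residues_per_cluster: int = 4,
    cluster_spacing: float = 50.0,
    name: str = "sticker_toy",
) -> ProteinModel:
    """Charged clusters on a line, far enough apart to never interact.

    Every residue is fully exposed (sparse geometry) and confidently
    ordered (pLDDT 90), so the whole chain is SSUP; each cluster of ≥4
    equal charges reaches |NCI| > 3 through self-inclusion and becomes
    exactly one sticker.
    """
    if residues_per_cluster < 4:
        raise ValueError("residues_per_cluster must be >= 4 to reach |NCI| > 3")
    if residues_per_cluster > len(_CLUSTER_OFFSETS):
        raise ValueError(f"at most {len(_CLUSTER_OFFSETS)} residues per cluster")
    if cluster_spacing < 40.0:
        raise ValueError("cluster_spacing must be >= 40 Å")
    aas: List[str] = []
    centers: List[np.ndarray] = []
    for c in range(n_pos_clusters + n_neg_clusters):
        aa = "K" if c < n_pos_clusters else "D"
        base = np.array([c * cluster_spacing, 0.0, 0.0])
        for k in range(residues_per_cluster):
            aas.append(aa)
            centers.append(base + _CLUSTER_OFFSETS[k])
    if not aas:  # degenerate request: neutral scaffold only
        for k in range(4):
            aas.append("G")
            centers.append(_CLUSTER_OFFSETS[k] * 3.0)
    residues = [
        Residue(
            index=i + 1,
            aa=aas[i],
            atoms=[
                Atom(nm, nm[0], centers[i] + off) for nm, off in _TOY_TEMPLATE.items()
            ],
            plddt=90.0,
        )
        for i in range(len(aas))
    ]
    return ProteinModel(id=name, sequence="".join(aas), residues=residues)


def make_labeled_features(
    n_pos: int,
    n_neg: int,
    effect_size: float,
    missing_idr_fraction: float = 0.3,
    seed: int = 0,
    use_phos: bool = False,
    n_signal_features: int = 8,
) -> pd.DataFrame:
    """Labeled feature table with the production schema.

    Positives get a mean shift of ``effect_size`` standard deviations on
    the first ``n_signal_features`` SSUP composition features.  A fraction
    of rows in both classes lose all IDR features (NaN) to emulate noID
    proteins; positives with missing IDR features are labeled noID-PSP.
    """
    if n_pos < 10 or n_neg < 10:
        raise ValueError("need at least 10 rows per class")
    rng = np.random.default_rng(seed)
    names = feature_names(use_phos=use_phos)
    n = n_pos + n_neg
    sd = 0.15
    data = rng.normal(0.5, sd, size=(n, len(names)))
    signal_cols = [i for i, nm in enumerate(names) if nm.endswith("_ssup")][
        :n_signal_features
    ]
    data[:n_pos, signal_cols] += effect_size * sd

    idr_cols = [
        i for i, nm in enumerate(names)
        if nm.endswith("_idr") or nm in ("idr_length", "idr_percent")
    ]
    missing = rng.random(n) < missing_idr_fraction
    data[np.ix_(missing, idr_cols)] = np.nan

    labels = np.array(
        ["noID-PSP" if missing[i] else "ID-PSP" for i in range(n_pos)]
        + ["non-PSP"] * n_neg
    )
    df = pd.DataFrame(data, columns=names)
    df.insert(0, "protein_id", [f"SYN{i:05d}" for i in range(n)])
    df.insert(1, "label", labels)
    return df
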