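"""Charged sticker detection on the structured superficial region.

For every SSUP residue a net charge index (NCI) is computed: the number of
positively charged SSUP residues minus the number of negatively charged
SSUP residues within a distance cutoff (default 14 Å, self included).
Residues with |NCI| > 3 are candidates; agglomerative clustering with
centroid linkage on their Cα coordinates, cut at the same distance,
yields the sticker clusters.  A cluster's sign is the sign held by the
majority of its members' NCI values.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure_io import ProteinModel

logger = logging.getLogger(__name__)

DISTANCE_THRESHOLD = 14.0
NCI_CUTOFF = 3

POSITIVE_RESIDUES = ("K", "R")
NEGATIVE_RESIDUES = ("D", "E")


@dataclasses.dataclass(frozen=True)
class ChargeAssignment:
    positive: Tuple[str, ...] = POSITIVE_RESIDUES
    negative: Tuple[str, ...] = NEGATIVE_RESIDUES

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative residue sets overlap")

    def swapped(self) -> "ChargeAssignment":
        return ChargeAssignment(positive=self.negative, negative=self.positive)


@dataclasses.dataclass
class StickerCluster:
    sign: str  # '+' or '-'
    members: Tuple[int, ...]  # 1-based residue indices, all in SSUP
    centroid: np.ndarray

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty sticker cluster")
        if self.sign not in ("+", "-"):
            raise ValueError(f"bad cluster sign {self.sign!r}")


@dataclasses.dataclass
class StickerSummary:
    n_pos: int
    n_neg: int
    n_total: int
    n_pairs: int
    freq_sticker: float
    freq_pair: float


def _residue_distances(
    model: ProteinModel, indices: Sequence[int], metric: str, cap: float = np.inf
) -> np.ndarray:
    """Pairwise residue distance matrix for the given 1-based indices.

    With ``metric='heavy'`` only distances up to ``cap`` are resolved;
    larger entries are reported as inf (sufficient for thresholding).
    """
    if metric == "ca":
        coords = np.array([model.residues[i - 1].ca for i in indices])
        return cdist(coords, coords)
    if metric == "heavy":
        atom_pos: List[np.ndarray] = []
        owner: List[int] = []
        for slot, i in enumerate(indices):
            for atom in model.residues[i - 1].atoms:
                if atom.element.upper() == "H":
                    continue
                atom_pos.append(atom.position)
                owner.append(slot)
        pos = np.asarray(atom_pos)
        owner_arr = np.asarray(owner)
        n = len(indices)
        out = np.full((n, n), np.inf)
        np.fill_diagonal(out, 0.0)
        tree = cKDTree(pos)
        radius = cap if np.isfinite(cap) else float(
            np.linalg.norm(pos.max(axis=0) - pos.min(axis=0))
        )
        pairs = tree.query_pairs(r=radius, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
            for (a, b), dist in zip(pairs, d):
                ra, rb = owner_arr[a], owner_arr[b]
                if ra != rb and dist < out[ra, rb]:
                    out[ra, rb] = out[rb, ra] = dist
        return out
    raise ValueError(f"unknown distance metric {metric!r}")


def net_charge_index(
    model: ProteinModel,
    ssup: Sequence[int],
    distance: float = DISTANCE_THRESHOLD,
    charges: ChargeAssignment | None = None,
    metric: str = "ca",
) -> Dict[int, int]:
    """NCI per SSUP residue: (#positive − #negative) SSUP residues within
    ``distance`` of it, self included when charged."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    charges = charges or ChargeAssignment()
    ssup = list(ssup)
    if not ssup:
        return {}
    dmat = _residue_distances(model, ssup, metric, cap=distance)
    seq = model.sequence
    pos_flags = np.array([seq[i - 1] in charges.positive for i in ssup])
    neg_flags = np.array([seq[i - 1] in charges.negative for i in ssup])
    within = dmat <= distance
    nci = within @ pos_flags.astype(int) - within @ neg_flags.astype(int)
    return {i: int(v) for i, v in zip(ssup, nci)}


def candidate_residues(nci: Dict[int, int], cutoff: int = NCI_CUTOFF) -> Tuple[int, ...]:
    """Residues with |NCI| strictly greater than ``cutoff``."""
    return tuple(sorted(i for i, v in nci.items() if abs(v) > cutoff))


def cluster_stickers(
    candidates: Sequence[int],
    model: ProteinModel,
    nci: Dict[int, int],
    distance: float = DISTANCE_THRESHOLD,
) -> List[StickerCluster]:
    """Centroid-linkage agglomerative clustering of candidate residues,
    flat-cut at ``distance`` on Cα Euclidean coordinates."""
    candidates = list(candidates)
    if not candidates:
        return []
    coords = np.array([model.residues[i - 1].ca for i in candidates])
    if len(candidates) == 1:
        labels = np.array([1])
    else:
        Z = linkage(coords, method="centroid", metric="euclidean")
        labels = fcluster(Z, t=distance, criterion="distance")

    clusters: List[StickerCluster] = []
    for label in sorted(set(labels)):
        member_idx = [candidates[k] for k in range(len(candidates)) if labels[k] == label]
        member_coords = coords[labels == label]
        signs = [np.sign(nci[i]) for i in member_idx]
        n_plus = sum(1 for s in signs if s > 0)
        n_minus = sum(1 for s in signs if s < 0)
        if n_plus > n_minus:
            sign = "+"
        elif n_minus > n_plus:
            sign = "-"
        else:
            total = sum(nci[i] for i in member_idx)
            if total == 0:
                logger.warning(
                    "discarding zero-sum sticker cluster with members %s", member_idx
                )
                continue
            sign = "+" if total > 0 else "-"
        clusters.append(
            StickerCluster(
                sign=sign,
                members=tuple(member_idx),
                centroid=member_coords.mean(axis=0),
            )
        )
    return clusters


def summarize_stickers(
    clusters: Iterable[StickerCluster], ssup_size: int
) -> StickerSummary:
    """Counts and SSUP-normalised frequencies; zeros when SSUP is empty."""
    if ssup_size < 0:
        raise ValueError("ssup_size must be non-negative")
    n_pos = sum(1 for c in clusters if c.sign == "+")
    n_neg = sum(1 for c in clusters if c.sign == "-")
    n_total = n_pos + n_neg
    n_pairs = min(n_pos, n_neg)
    if ssup_size == 0:
        freq_sticker = freq_pair = 0.0
    else:
        freq_sticker = n_total / ssup_size
        freq_pair = n_pairs / ssup_size
    return StickerSummary(
        n_pos=n_pos,
        n_neg=n_neg,
        n_total=n_total,
        n_pairs=n_pairs,
        freq_sticker=freq_sticker,
        freq_pair=freq_pair,
    )


def sticker_pipeline(
    model: ProteinModel,
    ssup: Sequence[int],
    distance: float = DISTANCE_THRESHOLD,
    charges: ChargeAssignment | None = None,
    nci_cutoff: int = NCI_CUTOFF,
    metric: str = "ca",
) -> Tuple[List[StickerCluster], StickerSummary]:
    """NCI → candidates → clustering → summary for one protein."""
    nci = net_charge_index(model, ssup, distance=distance, charges=charges, metric=metric)
    cands = candidate_residues(nci, cutoff=nci_cutoff)
    clusters = cluster_stickers(cands, model, nci, distance=distance)
    return clusters, summarize_stickers(clusters, len(list(ssup)))


def threshold_scan(
    models_with_ssup: Sequence[Tuple[ProteinModel, Sequence[int]]],
    distances: Sequence[float] = tuple(range(10, 21)),
    charges: ChargeAssignment | None = None,
    nci_cutoff: int = NCI_CUTOFF,
    metric: str = "ca",
    min_stickers: int = 3,
) -> Tuple[float, Dict[float, float]]:
    """Pick the distance maximising the fraction of proteins with
    ≥ ``min_stickers`` stickers; ties go to the smaller distance."""
    if not models_with_ssup:
        raise ValueError("need at least one protein")
    fractions: Dict[float, float] = {}
    for dist in distances:
        hits = 0
        for model, ssup in models_with_ssup:
            _, summary = sticker_pipeline(
                model, ssup, distance=dist, charges=charges,
                nci_cutoff=nci_cutoff, metric=metric,
            )
            if summary.n_total >= min_stickers:
                hits += 1
        fractions[dist] = hits / len(models_with_ssup)
    best = max(sorted(fractions), key=lambda d: fractions[d])
    return best, fractions
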