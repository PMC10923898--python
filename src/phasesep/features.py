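"""Residue- and region-level feature computation.

For each of the two regions of interest — the concatenated IDR sequence
and the SSUP residue set — the same 39 descriptors are computed: the 20
amino-acid fractions, 15 physicochemical group proportions, mean
normalised Kyte–Doolittle hydropathy, mean Zimmerman polarity, the
isoelectric point, and the molecular weight (both via Biopython's
ProteinAnalysis).  Whole-protein descriptors (IDR extent, sticker
frequencies, phosphosite frequency) complete the vector.

Missing-value semantics: IDR features of proteins without IDRs are NaN
("null"), never zero — zero is a meaningful fraction.  The tree learner
downstream routes missing values natively.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .disorder import SegmentSet
from .stickers import StickerSummary
from .structure_io import ProteinModel

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The fifteen physicochemical residue groups.
GROUPS: Dict[str, str] = {
    "Asx": "DN",
    "Glx": "EQ",
    "Xle": "IL",
    "Pos_charged": "KRH",
    "Neg_charged": "DE",
    "Aromatic": "FWYH",
    "Aliphatic": "VILM",
    "Small": "PGAS",
    "Hydrophilic": "STHNQEDKR",
    "Hydrophobic": "VILFWYM",
    "Alpha_helix": "VIYFWL",
    "Beta_turn": "NPGS",
    "Beta_sheet": "EMAL",
    "Aromaticity": "FWY",
    "Charged": "KRDE",
}

#: Kyte–Doolittle hydropathy.
KYTE_DOOLITTLE: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Zimmerman (1968) polarity.
ZIMMERMAN_POLARITY: Dict[str, float] = {
    "A": 0.00, "G": 0.00, "I": 0.13, "L": 0.13, "V": 0.13,
    "F": 0.35, "M": 1.43, "C": 1.48, "P": 1.58, "Y": 1.61,
    "T": 1.66, "S": 1.67, "W": 2.10, "N": 3.38, "Q": 3.53,
    "K": 49.50, "D": 49.70, "E": 49.90, "H": 51.60, "R": 52.00,
}

REGIONS = ("idr", "ssup")


def feature_names(use_phos: bool = True) -> List[str]:
    """Stable, ordered feature schema shared by every protein in a run."""
    names: List[str] = []
    for region in REGIONS:
        names += [f"fraction_{aa}_{region}" for aa in AMINO_ACIDS]
        names += [f"group_{g}_{region}" for g in GROUPS]
        names += [
            f"hydropathy_{region}",
            f"polarity_{region}",
            f"isoelectric_point_{region}",
            f"molecular_weight_{region}",
        ]
    names += ["idr_length", "idr_percent", "sticker_ssup", "sticker_pair_ssup"]
    if use_phos:
        names.append("phos_frequency")
    return names


def region_sequence(model: ProteinModel, region: SegmentSet | Iterable[int]) -> str:
    """Concatenated residues of a region in index order."""
    if isinstance(region, SegmentSet):
        indices: List[int] = []
        for start, end in region:
            indices.extend(range(start, end + 1))
    else:
        indices = sorted(region)
    n = len(model)
    for i in indices:
        if not 1 <= i <= n:
            raise ValueError(f"residue index {i} outside 1..{n}")
    return "".join(model.sequence[i - 1] for i in indices)


def aa_fractions(seq: str) -> Dict[str, float]:
    """Fraction of each standard amino acid; NaN map for the empty sequence."""
    if not seq:
        return {aa: math.nan for aa in AMINO_ACIDS}
    counts = Counter(seq)
    bad = set(counts) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}")
    return {aa: counts.get(aa, 0) / len(seq) for aa in AMINO_ACIDS}


def group_fractions(seq: str, groups: Mapping[str, str] = GROUPS) -> Dict[str, float]:
    if not seq:
        return {g: math.nan for g in groups}
    n = len(seq)
    return {
        g: sum(1 for c in seq if c in members) / n for g, members in groups.items()
    }


def mean_hydropathy(seq: str) -> float:
    """Mean of the [0, 1]-normalised Kyte–Doolittle scale: (KD + 4.5) / 9."""
    if not seq:
        return math.nan
    return float(np.mean([(KYTE_DOOLITTLE[c] + 4.5) / 9.0 for c in seq]))


def mean_polarity(seq: str, scale: Mapping[str, float] = ZIMMERMAN_POLARITY) -> float:
    if not seq:
        return math.nan
    return float(np.mean([scale[c] for c in seq]))


def isoelectric_point(seq: str) -> float:
    """Isoelectric point of the region treated as a free peptide."""
    if not seq:
        return math.nan
    return float(ProteinAnalysis(seq).isoelectric_point())


def molecular_weight(seq: str) -> float:
    """Average-mass molecular weight (Da), one water per peptide."""
    if not seq:
        return math.nan
    return float(ProteinAnalysis(seq).molecular_weight())


def idr_extent(idrs: SegmentSet, n: int) -> tuple[float, float]:
    """(total IDR residues, fraction of protein length); NaN pair when no IDR."""
    if len(idrs) == 0:
        return (math.nan, math.nan)
    total = idrs.total_length()
    return (float(total), total / n)


def phos_frequency(
    protein_id: str,
    length: int,
    phos_table: Optional[Mapping[str, Sequence[int]]],
) -> float:
    """Unique phosphosite count / protein length; 0 when the id is absent."""
    if phos_table is None or protein_id not in phos_table:
        return 0.0
    sites = set(int(s) for s in phos_table[protein_id])
    outside = [s for s in sites if s > length or s < 1]
    if outside:
        logger.warning(
            "%s: %d phosphosites outside 1..%d (isoform mismatch?); still counted",
            protein_id, len(outside), length,
        )
    return len(sites) / length


def _region_features(seq: str) -> Dict[str, float]:
    feats: Dict[str, float] = {}
    feats.update({f"fraction_{aa}": v for aa, v in aa_fractions(seq).items()})
    feats.update({f"group_{g}": v for g, v in group_fractions(seq).items()})
    feats["hydropathy"] = mean_hydropathy(seq)
    feats["polarity"] = mean_polarity(seq)
    feats["isoelectric_point"] = isoelectric_point(seq)
    feats["molecular_weight"] = molecular_weight(seq)
    return feats


def build_feature_vector(
    model: ProteinModel,
    idrs: SegmentSet,
    ssup: Sequence[int],
    sticker_summary: StickerSummary,
    phos_table: Optional[Mapping[str, Sequence[int]]] = None,
    use_phos: bool = False,
    ignore_idr: bool = False,
) -> Dict[str, float]:
    """Assemble the full named feature map for one protein.

    ``ignore_idr=True`` nullifies every IDR-derived feature regardless of
    IDR presence; an ID protein is then featurised like a noID protein.
    """
    idr_seq = "" if (ignore_idr or len(idrs) == 0) else region_sequence(model, idrs)
    ssup_seq = region_sequence(model, ssup)
    if not ssup_seq:
        logger.warning("%s: empty SSUP; composition features null, stickers zero",
                       model.id)

    feats: Dict[str, float] = {}
    for region, seq in (("idr", idr_seq), ("ssup", ssup_seq)):
        feats.update({f"{k}_{region}": v for k, v in _region_features(seq).items()})

    if ignore_idr:
        feats["idr_length"] = math.nan
        feats["idr_percent"] = math.nan
    else:
        feats["idr_length"], feats["idr_percent"] = idr_extent(idrs, len(model))
    feats["sticker_ssup"] = sticker_summary.freq_sticker
    feats["sticker_pair_ssup"] = sticker_summary.freq_pair
    if use_phos:
        feats["phos_frequency"] = phos_frequency(model.id, len(model), phos_table)

    expected = feature_names(use_phos=use_phos)
    assert list(feats) == expected, "feature schema drift"
    return feats


def read_phos_table(path) -> Dict[str, List[int]]:
    """Read a two-column (id, position) TSV into a phosphosite table."""
    table: Dict[str, List[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed phosphosite line: {line!r}")
            table.setdefault(parts[0], []).append(int(parts[1]))
    return table
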