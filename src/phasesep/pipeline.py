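"""End-to-end per-protein analysis: structure → IDRs → SSUP → stickers → features."""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .config import RunConfig
from .disorder import (
    SegmentSet,
    classify_protein,
    filter_secondary_structure,
    raw_disorder_mask,
    refine_mask,
)
from .features import build_feature_vector
from .secondary_structure import assign_ss
from .stickers import ChargeAssignment, StickerCluster, StickerSummary, sticker_pipeline
from .structure_io import ProteinModel
from .surface import SurfaceProfile, derive_ssup, surface_profile


@dataclasses.dataclass
class ProteinAnalysis:
    model: ProteinModel
    states3: List[str]
    idrs: SegmentSet
    protein_type: str  # 'ID' | 'noID'
    surface: SurfaceProfile
    ssup: Tuple[int, ...]
    clusters: List[StickerCluster]
    sticker_summary: StickerSummary
    features: Dict[str, float]


def analyze_model(
    model: ProteinModel,
    config: Optional[RunConfig] = None,
    phos_table: Optional[Mapping[str, Sequence[int]]] = None,
) -> ProteinAnalysis:
    """Run the full structural pipeline on one parsed model."""
    cfg = config or RunConfig()
    ss = assign_ss(model, backend=cfg.ss_backend)
    mask = raw_disorder_mask(model.plddt, cutoff=cfg.plddt_cutoff)
    mask = filter_secondary_structure(mask, ss.states3)
    idrs = refine_mask(mask, disorder_first=cfg.smooth_disorder_first)
    surf = surface_profile(
        model,
        table=cfg.max_asa_table,
        probe_radius=cfg.sasa_probe_radius,
        n_points=cfg.sasa_points,
        rsa_cutoff=cfg.rsa_cutoff,
    )
    ssup = derive_ssup(surf.exposed, idrs, len(model))
    charges = ChargeAssignment(
        positive=tuple(cfg.positive_residues), negative=tuple(cfg.negative_residues)
    )
    clusters, summary = sticker_pipeline(
        model,
        ssup,
        distance=cfg.distance_threshold,
        charges=charges,
        nci_cutoff=cfg.nci_cutoff,
        metric=cfg.nci_metric,
    )
    feats = build_feature_vector(
        model,
        idrs,
        ssup,
        summary,
        phos_table=phos_table,
        use_phos=cfg.use_phos,
        ignore_idr=cfg.ignore_idr,
    )
    return ProteinAnalysis(
        model=model,
        states3=ss.states3,
        idrs=idrs,
        protein_type=classify_protein(idrs),
        surface=surf,
        ssup=ssup,
        clusters=clusters,
        sticker_summary=summary,
        features=feats,
    )
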