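"""Run configuration with the pipeline's default thresholds.

All defaults are the values the pipeline was designed around; any override
is recorded when a config snapshot is written next to run outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Tuple


@dataclasses.dataclass
class RunConfig:
    """Bundle of every tunable threshold used across the pipeline."""

    #: Cα–Cα (or any-heavy-atom) neighbourhood radius for charge counting and
    #: the flat-cut height of the sticker clustering, in Å.
    distance_threshold: float = 14.0
    #: Residues with relative solvent accessibility above this are "exposed".
    rsa_cutoff: float = 0.25
    #: Residues with pLDDT strictly below this are raw-disordered.
    plddt_cutoff: float = 50.0
    #: Sticker candidates require |net charge index| strictly above this.
    nci_cutoff: int = 3
    positive_residues: Tuple[str, ...] = ("K", "R")
    negative_residues: Tuple[str, ...] = ("D", "E")
    #: "ca" = Cα–Cα Euclidean distance, "heavy" = minimal heavy-atom distance.
    nci_metric: str = "ca"
    #: "external" shells out to a DSSP binary, "internal" uses the built-in
    #: Kabsch–Sander assigner, "auto" prefers external when on PATH.
    ss_backend: str = "auto"
    #: Max-ASA normalisation table: "tien-theoretical", "tien-empirical",
    #: or "sander".
    max_asa_table: str = "tien-theoretical"
    #: Shrake–Rupley sphere points per atom.
    sasa_points: int = 960
    sasa_probe_radius: float = 1.4
    #: Smoothing order inside one refinement pass (see disorder module).
    smooth_disorder_first: bool = True
    use_phos: bool = False
    ignore_idr: bool = False
    seed: int = 42

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for seq_field in ("positive_residues", "negative_residues"):
            setattr(cfg, seq_field, tuple(getattr(cfg, seq_field)))
        return cfg


DEFAULT_CONFIG = RunConfig()
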