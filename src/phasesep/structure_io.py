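"""Reading and writing single-chain AlphaFold-dialect PDB models.

AlphaFold deposition files store the per-residue pLDDT confidence in the
B-factor column, identically for every atom of a residue.  The parser
re-derives a contiguous 1-based residue numbering, extracts the sequence
via the standard 3-to-1 letter mapping, and validates the model.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

#: Lower bound (exclusive) and upper bound (exclusive) on eligible length.
MIN_LENGTH = 100
MAX_LENGTH = 2700

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class StructureError(ValueError):
    """Malformed or unsupported structural input."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) float64, Å

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name!r}: non-finite or malformed position")
        if not self.name:
            raise StructureError("atom with empty name")


@dataclasses.dataclass
class Residue:
    index: int  # 1-based sequential
    aa: str  # one-letter code
    atoms: List[Atom]
    plddt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.plddt <= 100.0:
            raise StructureError(
                f"residue {self.index} ({self.aa}): pLDDT {self.plddt} outside [0, 100]"
            )

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> np.ndarray:
        atom = self.atom("CA")
        if atom is None:
            raise StructureError(f"residue {self.index} ({self.aa}): no CA atom")
        return atom.position


@dataclasses.dataclass
class ProteinModel:
    id: str
    sequence: str
    residues: List[Residue]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.residues):
            raise StructureError("sequence/residue length mismatch")
        for i, res in enumerate(self.residues, start=1):
            if res.index != i:
                raise StructureError(f"residue indices not contiguous at {res.index}")
            res.ca  # raises if absent

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates."""
        return np.array([r.ca for r in self.residues])

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues])


def parse_pdb(
    path: str | Path,
    model_id: Optional[str] = None,
    aa_overrides: Optional[Dict[str, str]] = None,
) -> ProteinModel:
    """Parse a single-chain AlphaFold-dialect PDB file.

    Parameters
    ----------
    path
        PDB file with ATOM records; HETATM records and altlocs other than
        blank/'A' are ignored.
    model_id
        Identifier for the model; defaults to the file stem.
    aa_overrides
        Extra 3-letter → 1-letter mappings for non-standard residues.

    Raises
    ------
    StructureError
        On multiple chains, missing CA atoms, or unmapped residue names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(model_id or path.stem, str(path))
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no ATOM records")
    chains = [c for c in models[0]]
    chains = [c for c in chains if any(r.id[0] == " " for r in c)]
    if len(chains) != 1:
        raise StructureError(f"{path}: expected exactly one chain, found {len(chains)}")

    mapping = dict(protein_letters_3to1)
    if aa_overrides:
        mapping.update({k.upper(): v for k, v in aa_overrides.items()})

    residues: List[Residue] = []
    for res in chains[0]:
        if res.id[0] != " ":  # HETATM / water
            continue
        resname = res.get_resname().upper()
        aa = mapping.get(resname)
        if aa is None or aa not in _STANDARD_AA:
            raise StructureError(
                f"{path}: non-standard residue {resname} at author position {res.id[1]}"
            )
        atoms = []
        bfactors = {}
        for atom in res:
            if atom.get_altloc() not in (" ", "A"):
                continue
            atoms.append(
                Atom(
                    name=atom.get_name(),
                    element=(atom.element or "").strip() or atom.get_name()[0],
                    position=np.asarray(atom.get_coord(), dtype=float),
                )
            )
            bfactors[atom.get_name()] = float(atom.get_bfactor())
        idx = len(residues) + 1
        if "CA" not in bfactors:
            raise StructureError(
                f"{path}: residue {resname} (sequential index {idx}) has no CA atom"
            )
        values = np.array(list(bfactors.values()))
        if np.ptp(values) > 1e-6:
            # AlphaFold files carry one pLDDT per residue; fall back to CA's.
            logger.warning(
                "%s: residue %d has non-uniform B-factors (spread %.3g); using CA value",
                path.name,
                idx,
                float(np.ptp(values)),
            )
        residues.append(Residue(index=idx, aa=aa, atoms=atoms, plddt=bfactors["CA"]))

    if not residues:
        raise StructureError(f"{path}: chain contains no standard residues")
    sequence = "".join(r.aa for r in residues)
    return ProteinModel(id=model_id or path.stem, sequence=sequence, residues=residues)


_AA_1TO3 = {v: k for k, v in protein_letters_3to1.items() if v in _STANDARD_AA}


def write_pdb(model: ProteinModel, path: str | Path) -> None:
    """Write a normalized single-chain PDB file (chain A, sequential numbering)."""
    lines = []
    serial = 1
    for res in model.residues:
        res3 = _AA_1TO3[res.aa]
        for atom in res.atoms:
            name = atom.name
            # PDB column convention: 1-3 char names start in column 14.
            padded = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = atom.position
            lines.append(
                f"ATOM  {serial:5d} {padded}{'':1s}{res3:>3s} A{res.index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{res.plddt:6.2f}          "
                f"{atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def length_eligible(model: ProteinModel | int) -> bool:
    """Dataset length filter: keep proteins with 100 < N < 2700 residues."""
    n = model if isinstance(model, int) else len(model)
    return MIN_LENGTH < n < MAX_LENGTH
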