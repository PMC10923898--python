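"""Per-residue secondary-structure assignment and 3-class collapse.

Two backends produce the classic 8-state alphabet {H, G, I, B, E, S, T, -}:

* ``external`` — shells out to a DSSP executable (``mkdssp`` or ``dssp``)
  when one is on PATH.
* ``internal`` — a built-in Kabsch–Sander assigner: backbone amide
  hydrogens are reconstructed, hydrogen-bond energies are computed with
  the electrostatic model E = 0.084 · 332 · (1/rON + 1/rCH − 1/rOH − 1/rCN)
  kcal/mol, and a bond is called below −0.5 kcal/mol.  Helices follow from
  consecutive n-turns, sheets from parallel/antiparallel bridge patterns,
  bends from the Cα virtual-bond kappa angle.

Downstream consumers only use the 3-class collapse (helix/sheet/loop), so
fine-grained 8-state edge cases (β-bulge stitching, exact tie-breaks
between overlapping patterns) are intentionally not reproduced.
"""

from __future__ import annotations

import dataclasses
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import List, Sequence

import numpy as np

from .structure_io import ProteinModel, StructureError, write_pdb

#: Loop/irregular symbol in the 8-state alphabet.
IRREGULAR = "-"

_COLLAPSE = {
    "H": "helix",
    "G": "helix",
    "I": "helix",
    "B": "sheet",
    "E": "sheet",
    "S": "loop",
    "T": "loop",
    IRREGULAR: "loop",
    "P": "loop",  # polyproline-II from modern DSSP builds
}

# Kabsch–Sander constants
_COUPLING = 0.084 * 332.0  # kcal/mol·Å
_HBOND_CUTOFF = -0.5  # kcal/mol
_CA_SEARCH = 9.0  # Å; pairs beyond this cannot hydrogen-bond
_MIN_DIST = 0.5  # Å; closer contacts are treated as clashes


@dataclasses.dataclass
class SSAssignment:
    states8: str
    states3: List[str]

    def __post_init__(self) -> None:
        if len(self.states8) != len(self.states3):
            raise ValueError("states8/states3 length mismatch")


def collapse_3class(states8: Sequence[str]) -> List[str]:
    """Map 8-state symbols onto {helix, sheet, loop}."""
    out = []
    for s in states8:
        try:
            out.append(_COLLAPSE[s])
        except KeyError:
            raise ValueError(f"unknown secondary-structure symbol {s!r}") from None
    return out


def assign_ss(model: ProteinModel, backend: str = "auto") -> SSAssignment:
    """Assign one 8-state symbol per residue and its 3-class collapse."""
    if backend not in ("auto", "external", "internal"):
        raise ValueError(f"unknown ss backend {backend!r}")
    if backend == "auto":
        backend = "external" if _find_dssp() else "internal"
    if backend == "external":
        exe = _find_dssp()
        if exe is None:
            raise EnvironmentError("no DSSP executable (mkdssp/dssp) found on PATH")
        states8 = _run_external_dssp(model, exe)
    else:
        states8 = _assign_internal(model)
    states8 = states8.replace("P", IRREGULAR)
    return SSAssignment(states8=states8, states3=collapse_3class(states8))


def _find_dssp() -> str | None:
    for name in ("mkdssp", "dssp"):
        exe = shutil.which(name)
        if exe:
            return exe
    return None


def _run_external_dssp(model: ProteinModel, exe: str) -> str:
    with tempfile.TemporaryDirectory() as tmp:
        pdb = Path(tmp) / f"{model.id}.pdb"
        out = Path(tmp) / f"{model.id}.dssp"
        write_pdb(model, pdb)
        subprocess.run(
            [exe, str(pdb), str(out)],
            check=True,
            capture_output=True,
        )
        return _parse_dssp_output(out.read_text(), len(model))


def _parse_dssp_output(text: str, n_residues: int) -> str:
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("  #  RESIDUE"))
    except StopIteration:
        raise StructureError("unrecognized DSSP output") from None
    states = [IRREGULAR] * n_residues
    for line in lines[start + 1 :]:
        if len(line) < 17 or line[13] == "!":
            continue
        resnum = int(line[5:10])
        symbol = line[16]
        states[resnum - 1] = symbol if symbol != " " else IRREGULAR
    return "".join(states)


# ---------------------------------------------------------------------------
# internal Kabsch–Sander backend
# ---------------------------------------------------------------------------


def _backbone(model: ProteinModel, name: str) -> np.ndarray:
    coords = np.empty((len(model), 3))
    for i, res in enumerate(model.residues):
        atom = res.atom(name)
        if atom is None:
            raise StructureError(
                f"residue {res.index} ({res.aa}): missing backbone atom {name}"
            )
        coords[i] = atom.position
    return coords


def _hbond_matrix(model: ProteinModel) -> np.ndarray:
    """Boolean matrix: bond[i, j] ⇔ CO of residue i accepts the NH of residue j."""
    n = len(model)
    N = _backbone(model, "N")
    CA = _backbone(model, "CA")
    C = _backbone(model, "C")
    O = _backbone(model, "O")

    # Amide hydrogen reconstruction: 1 Å from N, anti to the preceding C=O.
    H = np.full((n, 3), np.nan)
    has_h = np.zeros(n, dtype=bool)
    for j in range(1, n):
        if model.residues[j].aa == "P":
            continue
        vec = C[j - 1] - O[j - 1]
        H[j] = N[j] + vec / np.linalg.norm(vec)
        has_h[j] = True

    bond = np.zeros((n, n), dtype=bool)
    ca_dist = np.linalg.norm(CA[:, None, :] - CA[None, :, :], axis=-1)
    for i in range(n):
        for j in range(n):
            if i == j or not has_h[j] or ca_dist[i, j] > _CA_SEARCH:
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
                energy = -9.9
            else:
                energy = _COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HBOND_CUTOFF:
                bond[i, j] = True
    return bond


def _assign_internal(model: ProteinModel) -> str:
    n = len(model)
    if n < 3:
        return IRREGULAR * n
    bond = _hbond_matrix(model)

    def turn(step: int) -> np.ndarray:
        t = np.zeros(n, dtype=bool)
        for i in range(n - step):
            if bond[i, i + step]:
                t[i] = True
        return t

    turn3, turn4, turn5 = turn(3), turn(4), turn(5)

    is_h = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            is_h[i : i + 4] = True

    # Bridges: parallel / antiparallel Kabsch–Sander patterns, |i−j| ≥ 3.
    bridges: list[tuple[int, int, str]] = []
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (bond[i - 1, j] and bond[j, i + 1]) or (
                bond[j - 1, i] and bond[i, j + 1]
            )
            anti = (bond[i, j] and bond[j, i]) or (
                bond[i - 1, j + 1] and bond[j - 1, i + 1]
            )
            if para:
                bridges.append((i, j, "P"))
            elif anti:
                bridges.append((i, j, "A"))

    # Ladders: consecutive bridges of one type; ≥2 rungs → E, isolated → B.
    in_ladder = set()
    bridge_set = set((i, j, t) for i, j, t in bridges)
    for i, j, t in bridges:
        succ = (i + 1, j + 1, "P") if t == "P" else (i + 1, j - 1, "A")
        pred = (i - 1, j - 1, "P") if t == "P" else (i - 1, j + 1, "A")
        if succ in bridge_set or pred in bridge_set:
            in_ladder.add((i, j, t))
    is_e = np.zeros(n, dtype=bool)
    is_b = np.zeros(n, dtype=bool)
    for i, j, t in bridges:
        if (i, j, t) in in_ladder:
            is_e[i] = is_e[j] = True
        else:
            is_b[i] = is_b[j] = True

    is_g = np.zeros(n, dtype=bool)
    for i in range(1, n - 3):
        if turn3[i - 1] and turn3[i]:
            is_g[i : i + 3] = True
    is_i = np.zeros(n, dtype=bool)
    for i in range(1, n - 5):
        if turn5[i - 1] and turn5[i]:
            is_i[i : i + 5] = True

    is_t = np.zeros(n, dtype=bool)
    for step, flags in ((3, turn3), (4, turn4), (5, turn5)):
        for i in range(n - step):
            if flags[i]:
                is_t[i + 1 : i + step] = True

    CA = _backbone(model, "CA")
    is_s = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        u = CA[i] - CA[i - 2]
        v = CA[i + 2] - CA[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        kappa = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if kappa > 70.0:
            is_s[i] = True

    out = []
    for i in range(n):
        if is_h[i]:
            out.append("H")
        elif is_e[i]:
            out.append("E")
        elif is_b[i]:
            out.append("B")
        elif is_g[i]:
            out.append("G")
        elif is_i[i]:
            out.append("I")
        elif is_t[i]:
            out.append("T")
        elif is_s[i]:
            out.append("S")
        else:
            out.append(IRREGULAR)
    return "".join(out)
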