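"""Intrinsically disordered region (IDR) calling from pLDDT.

A residue is raw-disordered when its pLDDT is strictly below 50; residues
assigned helix or sheet secondary structure are forced ordered.  The raw
mask is then refined in three phases:

1. *smoothing* — iterated to a fixpoint: disordered stretches of ≤3
   residues lying between ordered regions become ordered, then ordered
   stretches of ≤3 residues lying between disordered regions become
   disordered (order configurable);
2. *bridging* — a single pass: ordered stretches of ≤10 residues flanked
   on both sides by disordered runs of ≥20 residues become disordered;
3. *pruning* — disordered runs shorter than 20 residues are dropped.

Runs touching a chain terminus have only one flank and are never touched
by the flank-dependent rules (1) and (2).
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np

#: pLDDT strictly below this value marks a residue as raw-disordered.
PLDDT_CUTOFF = 50.0
#: Stretches up to this length are flipped during smoothing.
SMOOTH_MAX = 3
#: Ordered stretches up to this length are bridged when flanked by long IDRs.
BRIDGE_MAX = 10
#: Minimum flank length for bridging and minimum final IDR length.
MIN_IDR = 20


@dataclasses.dataclass(frozen=True)
class SegmentSet:
    """Sorted, non-overlapping 1-based inclusive residue intervals."""

    intervals: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.intervals:
            if not (1 <= start <= end):
                raise ValueError(f"bad interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_length(self) -> int:
        return sum(end - start + 1 for start, end in self.intervals)

    def covers(self, index: int) -> bool:
        return any(start <= index <= end for start, end in self.intervals)

    def to_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for start, end in self.intervals:
            if end > n:
                raise ValueError(f"interval ({start}, {end}) beyond length {n}")
            mask[start - 1 : end] = True
        return mask


def raw_disorder_mask(plddt: Sequence[float], cutoff: float = PLDDT_CUTOFF) -> np.ndarray:
    """True where pLDDT < cutoff (strict)."""
    arr = np.asarray(plddt, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 100):
        raise ValueError("pLDDT scores must lie in [0, 100]")
    return arr < cutoff


def filter_secondary_structure(mask: np.ndarray, states3: Sequence[str]) -> np.ndarray:
    """Force residues assigned helix or sheet to ordered."""
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(states3):
        raise ValueError("mask/states3 length mismatch")
    structured = np.array([s in ("helix", "sheet") for s in states3])
    return mask & ~structured


def _runs(mask: Sequence[bool]) -> List[Tuple[bool, int, int]]:
    """Run-length encode: (value, start, length) with 0-based start."""
    runs = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[start]:
            runs.append((bool(mask[start]), start, i - start))
            start = i
    return runs


def _from_runs(runs: List[Tuple[bool, int, int]], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for value, start, length in runs:
        if value:
            mask[start : start + length] = True
    return mask


def _merge_runs(runs: List[List]) -> List[List]:
    """Coalesce adjacent runs of equal value ([value, length] pairs)."""
    merged: List[List] = []
    for value, length in runs:
        if merged and merged[-1][0] == value:
            merged[-1][1] += length
        else:
            merged.append([value, length])
    return merged


def _smooth_runs(runs: List[List], flip_value: bool, max_len: int) -> List[List]:
    """Flip interior runs of ``flip_value`` with length ≤ max_len."""
    out = [
        [(not value) if (value == flip_value and length <= max_len
                         and 0 < k < len(runs) - 1) else value, length]
        for k, (value, length) in enumerate(runs)
    ]
    return _merge_runs(out)


def refine_mask(
    mask: Sequence[bool],
    disorder_first: bool = True,
) -> SegmentSet:
    """Apply smoothing → bridging → pruning and return the final IDRs.

    Parameters
    ----------
    mask
        Per-residue disorder mask (already secondary-structure filtered).
    disorder_first
        Within one smoothing pass, flip short disordered runs to order
        before flipping short ordered runs to disorder (the default); the
        opposite order is available for sensitivity checks.
    """
    values = [bool(v) for v in mask]
    runs: List[List] = _merge_runs([[v, 1] for v in values])
    first, second = (True, False) if disorder_first else (False, True)

    # Phase 1: smoothing to fixpoint.
    while True:
        before = [tuple(r) for r in runs]
        runs = _smooth_runs(runs, first, SMOOTH_MAX)
        runs = _smooth_runs(runs, second, SMOOTH_MAX)
        if [tuple(r) for r in runs] == before:
            break

    # Phase 2: single bridging pass; qualifying gaps evaluated simultaneously
    # against the smoothed state, then all converted at once.
    bridged = [
        [True, length]
        if (not value and length <= BRIDGE_MAX and 0 < k < len(runs) - 1
            and runs[k - 1][1] >= MIN_IDR and runs[k + 1][1] >= MIN_IDR)
        else [value, length]
        for k, (value, length) in enumerate(runs)
    ]
    bridged = _merge_runs(bridged)

    # Phase 3: prune short IDRs.
    intervals = []
    pos = 1
    for value, length in bridged:
        if value and length >= MIN_IDR:
            intervals.append((pos, pos + length - 1))
        pos += length
    return SegmentSet(intervals=tuple(intervals))


def classify_protein(idrs: SegmentSet) -> str:
    """'ID' when at least one refined IDR exists, else 'noID'."""
    return "ID" if len(idrs) else "noID"


def idrs_to_bed(idrs: SegmentSet, name: str) -> str:
    """BED lines (0-based half-open) for the IDR intervals."""
    return "".join(
        f"{name}\t{start - 1}\t{end}\tIDR\n" for start, end in idrs
    )
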