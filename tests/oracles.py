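"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the production code paths: the disorder oracle
works on D/O strings with regular expressions, the clustering oracle is a
naive O(n^3) agglomerative loop, the SASA oracle is a double loop, and
the AUROC oracle is the Mann-Whitney rank statistic.
"""

from __future__ import annotations

import re
from typing import List, Sequence, Tuple

import numpy as np

SMOOTH_MAX = 3
BRIDGE_MAX = 10
MIN_IDR = 20


def refine_oracle(mask: Sequence[bool]) -> Tuple[Tuple[int, int], ...]:
    """Run-length refinement via string rewriting (smooth → bridge → prune)."""
    s = "".join("D" if v else "O" for v in mask)

    def flip_interior(s: str, char: str, other: str, max_len: int) -> str:
        # interior = flanked on both sides by the opposite character
        pattern = re.compile(
            "(?<=%s)%s{1,%d}(?=%s)" % (other, char, max_len, other)
        )
        return pattern.sub(lambda m: other * len(m.group(0)), s)

    while True:
        before = s
        s = flip_interior(s, "D", "O", SMOOTH_MAX)
        s = flip_interior(s, "O", "D", SMOOTH_MAX)
        if s == before:
            break

    # bridging: O gaps <=10 with >=20 D on each side, evaluated on the
    # smoothed string and converted simultaneously
    to_bridge = []
    for m in re.finditer("O+", s):
        if len(m.group(0)) > BRIDGE_MAX:
            continue
        left = re.search("D+$", s[: m.start()])
        right = re.match("D+", s[m.end() :])
        if left and right and len(left.group(0)) >= MIN_IDR and len(right.group(0)) >= MIN_IDR:
            to_bridge.append((m.start(), m.end()))
    chars = list(s)
    for a, b in to_bridge:
        chars[a:b] = "D" * (b - a)
    s = "".join(chars)

    return tuple(
        (m.start() + 1, m.end())
        for m in re.finditer("D{%d,}" % MIN_IDR, s)
    )


def centroid_linkage_oracle(
    coords: np.ndarray, threshold: float
) -> List[Tuple[int, ...]]:
    """Naive agglomerative clustering with centroid linkage.

    Merges the closest pair of cluster centroids while recording merge
    heights, then cuts into flat clusters where the maximum merge height
    inside a subtree does not exceed the threshold (the same flat-cut
    rule scipy's fcluster applies with criterion='distance').
    """
    n = len(coords)
    clusters = [
        {"members": (i,), "centroid": coords[i].astype(float), "maxh": 0.0}
        for i in range(n)
    ]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(np.linalg.norm(clusters[a]["centroid"] - clusters[b]["centroid"]))
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        ca, cb = clusters[a], clusters[b]
        na, nb = len(ca["members"]), len(cb["members"])
        merged = {
            "members": tuple(sorted(ca["members"] + cb["members"])),
            "centroid": (ca["centroid"] * na + cb["centroid"] * nb) / (na + nb),
            "maxh": max(d, ca["maxh"], cb["maxh"]),
        }
        # only merge everything; the cut is applied afterwards on heights
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        clusters[-1]["height"] = d
        # record the merge tree implicitly via maxh; a subtree is a valid
        # flat cluster iff maxh <= threshold, so we keep a merge history
        merged.setdefault("children", (ca, cb))
    # walk down from the root: split any node whose maxh exceeds threshold
    flat: List[Tuple[int, ...]] = []

    def walk(node):
        if node["maxh"] <= threshold or "children" not in node:
            flat.append(node["members"])
        else:
            for child in node["children"]:
                walk(child)

    walk(clusters[0])
    return sorted(flat)


def sasa_oracle(
    positions: np.ndarray,
    radii: np.ndarray,
    probe: float,
    n_points: int,
) -> np.ndarray:
    """Per-atom Shrake-Rupley, brute-force double loop, Fibonacci sphere."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    unit = np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )
    expanded = radii + probe
    out = np.zeros(len(positions))
    for k in range(len(positions)):
        pts = positions[k] + expanded[k] * unit
        free = np.ones(n_points, dtype=bool)
        for j in range(len(positions)):
            if j == k:
                continue
            free &= np.linalg.norm(pts - positions[j], axis=1) >= expanded[j]
        out[k] = 4.0 * np.pi * expanded[k] ** 2 * free.sum() / n_points
    return out


def auroc_rank_oracle(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUROC as the Mann-Whitney statistic with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
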