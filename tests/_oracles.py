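"""Independent oracles used by the test suite.

These deliberately share no code with the package: the local-alignment
oracle is a direct quadratic Gotoh dynamic program (numba-compiled), and the
scan/pair-counting oracles are brute-force enumerations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def encode(seq: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([table.get(c, 4) for c in seq.upper()], dtype=np.int8)


@njit(cache=True)
def _sw_affine(q, r, match, mismatch, gap_open, gap_extend):
    """Best local alignment score with gap cost gap_open + k * gap_extend
    (penalties negative), one orientation."""
    nq, nr = len(q), len(r)
    H = np.zeros((nq + 1, nr + 1), dtype=np.int64)
    E = np.full((nq + 1, nr + 1), -10**9, dtype=np.int64)
    F = np.full((nq + 1, nr + 1), -10**9, dtype=np.int64)
    best = 0
    for i in range(1, nq + 1):
        for j in range(1, nr + 1):
            s = match if q[i - 1] == r[j - 1] and q[i - 1] < 4 else mismatch
            E[i, j] = max(H[i, j - 1] + gap_open + gap_extend, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open + gap_extend, F[i - 1, j] + gap_extend)
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def sw_score(query: str, reference: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2) -> int:
    """Oracle local-alignment score, one orientation."""
    return int(_sw_affine(encode(query), encode(reference), match, mismatch, gap_open, gap_extend))


def sw_score_both_strands(query: str, reference: str, **kw) -> int:
    return max(sw_score(query, reference, **kw), sw_score(rc(query), reference, **kw))


def brute_force_scan(seq: str, motif: str) -> list[int]:
    """Every offset where the motif occurs exactly (case-insensitive)."""
    seq, motif = seq.upper(), motif.upper()
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


def brute_force_amplicons(positions, motif_len: int, min_len: int, max_len: int) -> int:
    """All ordered site pairs whose start-to-end span is in range."""
    n = 0
    positions = sorted(positions)
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            span = positions[j] + motif_len - positions[i]
            if min_len <= span <= max_len:
                n += 1
    return n


def brute_force_single_linkage(positions: list[int], gap: int) -> list[list[int]]:
    """Clusters of sorted positions where consecutive members differ <= gap."""
    if not positions:
        return []
    positions = sorted(positions)
    clusters = [[positions[0]]]
    for p in positions[1:]:
        if p - clusters[-1][-1] <= gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters
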