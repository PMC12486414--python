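"""Pairwise global alignment with free end gaps (overlap alignment).

This is the identity primitive the whole survey pipeline is built on, so its
conventions are fixed here once:

* scoring: match +1, mismatch -1, gap -2 per gapped position; gaps before the
  first or after the last aligned pair cost nothing, so a PCR fragment aligns
  against a whole gene without penalty for the missing flanks;
* ``N`` and IUPAC ambiguity codes never match anything, including themselves;
* identity = matched positions / length of the shorter sequence, the
  shorter-sequence convention used by greedy incremental clusterers.

Among co-optimal alignments the score alone does not determine the number of
matched positions, which would make "identity" ambiguous.  The dynamic
programme therefore maximises the pair (score, matches) lexicographically by
packing it into a single int64 as ``score * 2**20 + matches``: every edit step
adds a constant increment, and adding a constant preserves the lexicographic
order, so the usual Bellman recursion applies unchanged.

Rows are vectorised with numpy.  The within-row gap dependency
``H[i][j] = max(T[j], H[i][j-1] + gap)`` is a running maximum because the gap
cost is linear: ``H[i][j] = gap*j + cummax(T[j] - gap*j)``.
"""

from __future__ import annotations

import numpy as np

_ENC = 1 << 20  # packs (score, matches); matches < 2**20 always holds here
_GAP = -2 * _ENC  # gap step: score -2, matches +0
_MATCH = _ENC + 1  # score +1, matches +1
_MISMATCH = -_ENC  # score -1, matches +0

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _dp_matrix(a: str, b: str) -> np.ndarray:
    """Full (len(a)+1, len(b)+1) matrix of packed (score, matches) values."""
    la, lb = len(a), len(b)
    a_arr = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    b_unambiguous = np.isin(b_arr, _ACGT)
    h = np.zeros((la + 1, lb + 1), dtype=np.int64)
    idx = np.arange(lb + 1, dtype=np.int64)
    gap_ramp = _GAP * idx
    c = np.empty(lb + 1, dtype=np.int64)
    for i in range(1, la + 1):
        eq = (b_arr == a_arr[i - 1]) & b_unambiguous
        sub = np.where(eq, _MATCH, _MISMATCH)
        t = np.maximum(h[i - 1, :-1] + sub, h[i - 1, 1:] + _GAP)
        c[0] = 0  # free end gap: first column stays at zero
        c[1:] = t
        h[i] = np.maximum.accumulate(c - gap_ramp) + gap_ramp
    return h


def _best_border_cell(h: np.ndarray) -> tuple[int, int]:
    """Arg-max cell over the last row and last column (free trailing gaps).

    Ties prefer the cell closest to the corner (largest i+j, then largest i)
    so the traceback is deterministic.
    """
    la = h.shape[0] - 1
    lb = h.shape[1] - 1
    best = (h[la, lb], la + lb, la)
    cell = (la, lb)
    for j in range(lb + 1):
        key = (h[la, j], la + j, la)
        if key > best:
            best, cell = key, (la, j)
    for i in range(la + 1):
        key = (h[i, lb], i + lb, i)
        if key > best:
            best, cell = key, (i, lb)
    return cell


def align_stats(a: str, b: str) -> tuple[int, int]:
    """Return (score, matches) of the optimal overlap alignment of a and b."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    h = _dp_matrix(a, b)
    best = max(int(h[-1, :].max()), int(h[:, -1].max()))
    matches = best % _ENC
    score = (best - matches) // _ENC
    return score, matches


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions over the shorter sequence.

    Symmetric, 1.0 for identical sequences, 0.0 when nothing matches.
    """
    _, matches = align_stats(a, b)
    return matches / min(len(a), len(b))


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Optimal overlap alignment of two sequences as equal-length gapped strings."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    h = _dp_matrix(a, b)
    i, j = _best_border_cell(h)
    la, lb = len(a), len(b)
    # unaligned suffixes ride along as free end gaps
    ga = [a[i:] + "-" * (lb - j)]
    gb = ["-" * (la - i) + b[j:]]
    while i > 0 and j > 0:
        here = h[i, j]
        pair_ok = a[i - 1] == b[j - 1] and a[i - 1] in "ACGT"
        sub = _MATCH if pair_ok else _MISMATCH
        if here == h[i - 1, j - 1] + sub:
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            i -= 1
            j -= 1
        elif here == h[i - 1, j] + _GAP:
            ga.append(a[i - 1])
            gb.append("-")
            i -= 1
        else:
            ga.append("-")
            gb.append(b[j - 1])
            j -= 1
    ga.append("-" * j + a[:i])
    gb.append(b[:j] + "-" * i)
    ga.reverse()
    gb.reverse()
    return "".join(ga), "".join(gb)
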