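"""Cluster alignment, majority consensus, and maximal-overlap window extraction.

Clusters are aligned with a deterministic center-star aligner (the member
with the greatest summed identity to the rest is the star; everyone else is
pairwise-aligned to it and merged under "once a gap, always a gap").  A
master alignment of cluster consensus sequences plus individual sequences is
then scanned for the longest contiguous column interval covered by enough
rows — the shared gene region that survey fragments of varying length all
overlap — and rows that do not span that window are set aside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._align import align_pair, pairwise_identity

logger = logging.getLogger(__name__)


@dataclass
class Alignment:
    """A multiple alignment: ordered mapping of row id to gapped string."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows have differing lengths: {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degap(self, row_id: str) -> str:
        return self.rows[row_id].replace("-", "")


@dataclass(frozen=True)
class AlignmentWindow:
    """A contiguous column interval [start, end) and the rows covering it."""

    start: int
    end: int
    coverage: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("window must satisfy 0 <= start < end")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


def choose_center(sequences: Mapping[str, str]) -> tuple[str, float]:
    """Pick the center-star sequence: max summed pairwise identity.

    Returns (center id, mean identity of the other sequences to the center).
    Ties prefer the longer sequence, then the lexicographically smaller id.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    ident = {i: 0.0 for i in ids}
    for a_pos, a in enumerate(ids):
        for b in ids[a_pos + 1:]:
            d = pairwise_identity(sequences[a], sequences[b])
            ident[a] += d
            ident[b] += d
    center = min(ids, key=lambda i: (-ident[i], -len(sequences[i]), i))
    mean_ident = ident[center] / (len(ids) - 1)
    return center, mean_ident


def center_star_align(sequences: Mapping[str, str]) -> Alignment:
    """Center-star multiple alignment of >= 2 sequences.

    Every non-center sequence is pairwise-aligned to the center and merged
    into the growing master under the once-a-gap-always-a-gap rule, so
    de-gapping any row reproduces its input sequence exactly.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("center-star alignment needs at least 2 sequences")
    center, _ = choose_center(sequences)
    center_seq = sequences[center]
    rows: dict[str, list[str]] = {center: list(center_seq)}
    for sid in ids:
        if sid == center:
            continue
        ga_center, ga_new = align_pair(center_seq, sequences[sid])
        rows = _merge_into_star(rows, center, ga_center, ga_new, sid)
    ordered = {sid: "".join(rows[sid]) for sid in ids}
    return Alignment(rows=ordered)


def _merge_into_star(
    rows: dict[str, list[str]],
    center: str,
    ga_center: str,
    ga_new: str,
    new_id: str,
) -> dict[str, list[str]]:
    """Merge one pairwise (center, new) alignment into the master alignment."""
    master_center = rows[center]
    ops: list[tuple[str, int, int]] = []  # (kind, master col, pair col)
    i = 0  # master column
    k = 0  # pairwise column
    n_master, n_pair = len(master_center), len(ga_center)
    while i < n_master or k < n_pair:
        if i < n_master and master_center[i] == "-":
            ops.append(("old_ins", i, -1))
            i += 1
        elif k < n_pair and ga_center[k] == "-":
            ops.append(("new_ins", -1, k))
            k += 1
        else:
            # both sides consume the same center residue
            ops.append(("both", i, k))
            i += 1
            k += 1
    merged: dict[str, list[str]] = {}
    for rid, row in rows.items():
        merged[rid] = [row[mi] if kind != "new_ins" else "-" for kind, mi, _ in ops]
    merged[new_id] = [ga_new[pk] if kind != "old_ins" else "-" for kind, _, pk in ops]
    return merged


def majority_consensus(alignment: Alignment) -> str:
    """Per-column plurality consensus.

    Columns that are majority-gap (gap fraction > 0.5) are dropped; otherwise
    the most frequent non-gap base is emitted, ties broken alphabetically.
    """
    mat = np.array([list(s) for s in alignment.rows.values()])
    out = []
    n = alignment.n_rows
    for col in mat.T:
        gaps = int((col == "-").sum())
        if gaps * 2 > n:
            continue
        bases, counts = np.unique(col[col != "-"], return_counts=True)
        out.append(sorted(bases[counts == counts.max()])[0])
    return "".join(out)


def build_master_alignment(
    consensus_seqs: Mapping[str, str], individual_seqs: Mapping[str, str]
) -> Alignment:
    """One alignment holding every cluster consensus and individual sequence."""
    combined = {**consensus_seqs, **individual_seqs}
    if len(combined) != len(consensus_seqs) + len(individual_seqs):
        raise ValueError("consensus and individual ids overlap")
    return center_star_align(combined)


def _row_cover_matrix(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """(non-gap boolean matrix, per-row prefix gap counts)."""
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8)
                    for s in alignment.rows.values()])
    nongap = mat != ord("-")
    prefix_gaps = np.zeros((mat.shape[0], mat.shape[1] + 1), dtype=np.int64)
    np.cumsum(~nongap, axis=1, out=prefix_gaps[:, 1:])
    return nongap, prefix_gaps


def row_covers(
    row: str, start: int, end: int, max_internal_gap_fraction: float = 0.1
) -> bool:
    """A row covers [start, end) if its ends are non-gap and internal gaps are rare."""
    if row[start] == "-" or row[end - 1] == "-":
        return False
    gaps = row.count("-", start, end)
    return gaps <= max_internal_gap_fraction * (end - start)


def extract_window(
    alignment: Alignment,
    min_coverage_fraction: float = 0.5,
    max_internal_gap_fraction: float = 0.1,
) -> AlignmentWindow:
    """Longest contiguous interval covered by enough rows.

    Among all intervals whose coverage reaches ceil(min_coverage_fraction *
    n_rows), the longest wins; ties prefer higher coverage, then the leftmost
    start.  Coverage counts rows with a non-gap character at both interval
    ends and at most ``max_internal_gap_fraction`` gaps inside.
    """
    floor = math.ceil(min_coverage_fraction * alignment.n_rows)
    floor = max(floor, 1)
    nongap, prefix_gaps = _row_cover_matrix(alignment)
    n_rows, n_cols = nongap.shape
    best_key = None
    best: AlignmentWindow | None = None
    ends = np.arange(1, n_cols + 1)
    for start in range(n_cols):
        open_rows = nongap[:, start]
        if not open_rows.any():
            continue
        lengths = ends[start:] - start
        internal_gaps = prefix_gaps[:, start + 1:] - prefix_gaps[:, start, None]
        ok = (
            open_rows[:, None]
            & nongap[:, start:]
            & (internal_gaps <= max_internal_gap_fraction * lengths[None, :])
        )
        coverage = ok.sum(axis=0)
        feasible = coverage >= floor
        if not feasible.any():
            continue
        # lexicographic (length, coverage); n_rows+1 > any coverage value
        key = np.where(feasible, lengths * (n_rows + 1) + coverage, -1)
        j = int(key.argmax())
        if best_key is None or key[j] > best_key:  # strict: leftmost start wins ties
            best_key = int(key[j])
            best = AlignmentWindow(start=start, end=start + int(lengths[j]),
                                   coverage=int(coverage[j]))
    if best is None:
        raise ValueError(
            f"no interval reaches coverage {floor}/{n_rows}; "
            "lower min_coverage_fraction"
        )
    return best


def exclude_divergent(
    alignment: Alignment,
    window: AlignmentWindow,
    max_internal_gap_fraction: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Split row ids into those spanning the window and those that do not."""
    if window.end > alignment.n_cols:
        raise ValueError("window extends past the alignment")
    kept, excluded = [], []
    for rid, row in alignment.rows.items():
        if row_covers(row, window.start, window.end, max_internal_gap_fraction):
            kept.append(rid)
        else:
            excluded.append(rid)
    if excluded:
        logger.info("exclude_divergent: %d of %d rows do not span the window",
                    len(excluded), alignment.n_rows)
    return kept, excluded


def trim_to_window(
    alignment: Alignment, window: AlignmentWindow, row_ids: list[str] | None = None
) -> dict[str, str]:
    """De-gapped window-region substrings for the given rows (default: all)."""
    ids = row_ids if row_ids is not None else list(alignment.rows)
    return {
        rid: alignment.rows[rid][window.start:window.end].replace("-", "")
        for rid in ids
    }
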