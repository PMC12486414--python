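"""Greedy identity-threshold clustering and cluster bookkeeping.

The clusterer mirrors the classic greedy incremental scheme: sequences are
visited in descending length order and each either joins the first existing
cluster whose *representative* it matches at or above the identity threshold,
or founds a new cluster.  Because founders are visited longest-first, every
representative is the longest member of its cluster and representatives of
distinct clusters are pairwise below the threshold.

The survey default threshold is 0.87, an identity level used to delimit
functional-gene groups at roughly species resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._align import pairwise_identity
from .ingest import SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.87


@dataclass
class Cluster:
    """An identity-threshold group of accessions around a representative."""

    cluster_id: str
    representative: str
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class RankAbundance:
    """Cluster sizes against rank, plus the large/unique boundary.

    ``unique_cutoff`` is the first rank (1-based) whose cluster holds two or
    fewer sequences, or None when every cluster is larger.
    """

    ranks: list[tuple[int, int]]
    unique_cutoff: int | None

    @property
    def total_sequences(self) -> int:
        return sum(size for _, size in self.ranks)


def greedy_cluster(
    records: list[SeqRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    id_prefix: str = "C",
) -> list[Cluster]:
    """Cluster records greedily at the given identity threshold.

    Records are processed in descending sequence length, ties broken by
    lexicographic accession, so the result is deterministic.  Each record is
    compared against representatives in cluster-creation order and joins the
    first match at identity >= threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(records, key=lambda r: (-len(r), r.accession))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    for rec in order:
        for cl, rep_seq in zip(clusters, rep_seqs):
            if pairwise_identity(rec.sequence, rep_seq) >= threshold:
                cl.members.append(rec.accession)
                break
        else:
            clusters.append(
                Cluster(
                    cluster_id=f"{id_prefix}{len(clusters):04d}",
                    representative=rec.accession,
                    members=[rec.accession],
                )
            )
            rep_seqs.append(rec.sequence)
    logger.info("greedy_cluster: %d records -> %d clusters at %.2f",
                len(records), len(clusters), threshold)
    return clusters


def filter_aquatic_clusters(
    clusters: list[Cluster], records: list[SeqRecord]
) -> list[Cluster]:
    """Retain clusters containing at least one aquatic-source member."""
    by_acc = {r.accession: r for r in records}
    kept = []
    for cl in clusters:
        try:
            members = [by_acc[m] for m in cl.members]
        except KeyError as exc:
            raise ValueError(f"cluster {cl.cluster_id}: unresolved accession {exc}") from exc
        if any(m.aquatic for m in members):
            kept.append(cl)
    logger.info("filter_aquatic_clusters: kept %d of %d", len(kept), len(clusters))
    return kept


def partition_by_size(
    clusters: list[Cluster], min_large: int = 3
) -> tuple[list[Cluster], list[str]]:
    """Split clusters into large clusters and individual sequences.

    Clusters of size >= min_large are returned intact; members of smaller
    clusters are dissolved into a flat list of accessions to be treated as
    individual sequences downstream.  Total sequence count is conserved.
    """
    large = [cl for cl in clusters if cl.size >= min_large]
    individuals = [m for cl in clusters if cl.size < min_large for m in cl.members]
    return large, individuals


def rank_abundance(clusters: list[Cluster]) -> RankAbundance:
    """Cluster sizes sorted non-increasing, ranked from 1."""
    sizes = sorted((cl.size for cl in clusters), reverse=True)
    cutoff = next((rank for rank, s in enumerate(sizes, start=1) if s <= 2), None)
    return RankAbundance(ranks=list(enumerate(sizes, start=1)), unique_cutoff=cutoff)
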