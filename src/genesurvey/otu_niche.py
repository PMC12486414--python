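"""OTU archetype assignment on the window region and niche statistics.

An archetype is the representative window sequence of an operational
taxonomic unit.  Assignment is greedy maximal coverage: the sequence that
matches the most still-unassigned sequences at or above the identity
threshold becomes the next archetype and claims those sequences, until every
sequence is assigned.  Identities are computed on the de-gapped window
substrings with the same overlap-alignment convention used for clustering.

The niche statistics summarise where OTUs come from: the distinct
environmental sources per OTU, the fraction of single-source OTUs (the
habitat-specificity headline number), per-source percentage tables overall or
per taxon, and the cluster/sequence bookkeeping summary of a survey.
All percentages are rounded to one decimal, half away from zero.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from ._align import pairwise_identity
from .cluster import Cluster
from .ingest import RANKS, SeqRecord

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round to `ndigits` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, one decimal, half away from zero."""
    if denominator == 0:
        raise ValueError("percentage denominator is zero")
    return round_half_away(100.0 * numerator / denominator)


@dataclass
class OTU:
    """An archetype plus the window sequences assigned to it."""

    otu_id: str
    archetype: str
    members: list[str]
    sources: Counter = field(default_factory=Counter)
    taxonomy: str = "unknown"

    @property
    def size(self) -> int:
        return len(self.members)


def assign_archetypes(
    window_seqs: Mapping[str, str],
    threshold: float = 0.87,
    weights: Mapping[str, int] | None = None,
) -> list[OTU]:
    """Group window sequences into OTUs by greedy maximal coverage.

    ``weights`` carries the source-cluster size behind each id (a cluster
    consensus speaks for its whole cluster); it only breaks ties when two
    candidate archetypes would claim equally many sequences.  Remaining ties
    go to the lexicographically smaller id, so the result is deterministic.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ids = list(window_seqs)
    if not ids:
        return []
    weights = weights or {}
    # symmetric identity-threshold match graph
    matches: dict[str, set[str]] = {i: {i} for i in ids}
    for a_pos, a in enumerate(ids):
        for b in ids[a_pos + 1:]:
            if pairwise_identity(window_seqs[a], window_seqs[b]) >= threshold:
                matches[a].add(b)
                matches[b].add(a)
    unassigned = set(ids)
    otus: list[OTU] = []
    while unassigned:
        best = min(
            unassigned,
            key=lambda i: (-len(matches[i] & unassigned), -weights.get(i, 1), i),
        )
        claimed = sorted(matches[best] & unassigned)
        unassigned -= set(claimed)
        otus.append(OTU(otu_id=f"OTU{len(otus):04d}", archetype=best, members=claimed))
    logger.info("assign_archetypes: %d sequences -> %d OTUs at %.2f",
                len(ids), len(otus), threshold)
    return otus


def annotate_otus(
    otus: list[OTU],
    records: Sequence[SeqRecord],
    member_expansion: Mapping[str, list[str]] | None = None,
    hypersaline_accessions: set[str] | None = None,
) -> list[OTU]:
    """Fill each OTU's source multiset and consensus taxonomy in place.

    ``member_expansion`` maps a member id that stands for a whole cluster
    (e.g. a consensus row) to that cluster's accessions; other member ids are
    treated as accessions directly.  ``hypersaline_accessions`` relabels the
    given members' "aquatic_other" source as "hypersaline" post hoc.

    The OTU taxonomy is the most specific rank label shared by at least half
    of the classified member records, else "unknown".
    """
    by_acc = {r.accession: r for r in records}
    expansion = member_expansion or {}
    hyper = hypersaline_accessions or set()
    for otu in otus:
        accs = [a for m in otu.members for a in expansion.get(m, [m])]
        try:
            recs = [by_acc[a] for a in accs]
        except KeyError as exc:
            raise ValueError(f"{otu.otu_id}: unresolved member {exc}") from exc
        otu.sources = Counter(
            "hypersaline" if (r.accession in hyper and r.source == "aquatic_other")
            else r.source
            for r in recs
        )
        otu.taxonomy = _consensus_taxonomy(recs)
    return otus


def _consensus_taxonomy(records: Sequence[SeqRecord]) -> str:
    label = "unknown"
    for depth in range(len(RANKS)):
        classified = [r.taxonomy[depth] for r in records if r.taxonomy[depth] != "NA"]
        if not classified:
            break
        top, n = Counter(classified).most_common(1)[0]
        if 2 * n >= len(classified):
            label = top
        else:
            break
    return label


def otu_source_profile(otus: list[OTU]) -> pd.DataFrame:
    """Table of (otu_id, sources, n_sources); requires annotated OTUs."""
    rows = []
    for otu in otus:
        if not otu.sources:
            raise ValueError(f"{otu.otu_id}: no sources; run annotate_otus first")
        srcs = sorted(otu.sources)
        rows.append({"otu_id": otu.otu_id, "sources": ",".join(srcs),
                     "n_sources": len(srcs)})
    return pd.DataFrame(rows, columns=["otu_id", "sources", "n_sources"])


def single_source_fraction(profiles: pd.DataFrame) -> float:
    """Percent of OTUs whose members all come from one environmental source."""
    n = len(profiles)
    if n == 0:
        raise ValueError("no OTUs")
    return percentage(int((profiles["n_sources"] == 1).sum()), n)


def source_percentages(
    otus: list[OTU],
    group_by_taxon: bool = False,
    counting: str = "all_sources",
) -> pd.DataFrame:
    """Per-source percentage table for annotated OTUs.

    With ``counting="all_sources"`` an OTU contributes one count to every
    distinct source among its members, so multi-source OTUs appear under
    several categories; with ``"majority"`` only its most common source (ties
    alphabetical) counts.  Percentages are taken over the total contributions
    within each group, so each group's column sums to 100 up to rounding.
    """
    if counting not in ("all_sources", "majority"):
        raise ValueError("counting must be 'all_sources' or 'majority'")
    rows = []
    for otu in otus:
        if not otu.sources:
            raise ValueError(f"{otu.otu_id}: no sources; run annotate_otus first")
        group = otu.taxonomy if group_by_taxon else "all"
        if counting == "all_sources":
            for src in sorted(otu.sources):
                rows.append((group, src))
        else:
            top = min(otu.sources.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            rows.append((group, top))
    df = pd.DataFrame(rows, columns=["group", "source"])
    counts = df.groupby(["group", "source"]).size().rename("count").reset_index()
    totals = counts.groupby("group")["count"].transform("sum")
    counts["percent"] = [
        percentage(int(c), int(t)) for c, t in zip(counts["count"], totals)
    ]
    return counts


@dataclass
class DomainSummary:
    """Cluster/sequence bookkeeping for one domain of a survey.

    All derived percentages are re-derivable from the stored integer counts.
    """

    n_sequences: int
    n_clusters: int
    n_large_clusters: int
    n_sequences_in_large: int
    n_individuals: int
    largest_cluster_size: int
    n_otus: int | None = None

    @property
    def pct_large_clusters(self) -> float:
        return percentage(self.n_large_clusters, self.n_clusters)

    @property
    def pct_sequences_in_large(self) -> float:
        return percentage(self.n_sequences_in_large, self.n_sequences)

    @property
    def pct_clusters_individual(self) -> float:
        return percentage(self.n_clusters - self.n_large_clusters, self.n_clusters)

    @property
    def pct_sequences_individual(self) -> float:
        return percentage(self.n_individuals, self.n_sequences)

    @property
    def largest_cluster_share(self) -> float:
        return percentage(self.largest_cluster_size, self.n_sequences)

    def as_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "n_clusters": self.n_clusters,
            "n_large_clusters": self.n_large_clusters,
            "n_sequences_in_large": self.n_sequences_in_large,
            "n_individuals": self.n_individuals,
            "largest_cluster_size": self.largest_cluster_size,
            "n_otus": self.n_otus,
            "pct_large_clusters": self.pct_large_clusters,
            "pct_sequences_in_large": self.pct_sequences_in_large,
            "pct_clusters_individual": self.pct_clusters_individual,
            "pct_sequences_individual": self.pct_sequences_individual,
            "largest_cluster_share": self.largest_cluster_share,
        }


def survey_summary(
    clusters: list[Cluster],
    partition: tuple[list[Cluster], list[str]],
    otus: list[OTU] | None = None,
) -> DomainSummary:
    """Bookkeeping summary from the clustering and size partition of one domain."""
    large, individuals = partition
    n_sequences = sum(cl.size for cl in clusters)
    if not clusters or n_sequences == 0:
        raise ValueError("survey_summary needs at least one non-empty cluster")
    return DomainSummary(
        n_sequences=n_sequences,
        n_clusters=len(clusters),
        n_large_clusters=len(large),
        n_sequences_in_large=sum(cl.size for cl in large),
        n_individuals=len(individuals),
        largest_cluster_size=max(cl.size for cl in clusters),
        n_otus=len(otus) if otus is not None else None,
    )
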