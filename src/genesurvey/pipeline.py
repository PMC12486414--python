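"""End-to-end orchestration: ingest -> cluster -> consensus/window -> OTU -> tree.

Bacteria and Archaea run through the same stages separately (they differ in
length floor and end up with different shared windows), and a JSON manifest
records the per-stage bookkeeping so sequence conservation can be audited at
every boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cluster import (
    filter_aquatic_clusters,
    greedy_cluster,
    partition_by_size,
    rank_abundance,
)
from .consensus_window import (
    Alignment,
    build_master_alignment,
    center_star_align,
    choose_center,
    exclude_divergent,
    extract_window,
    majority_consensus,
    trim_to_window,
)
from .ingest import SeqRecord, deduplicate, filter_by_length, read_survey
from .otu_niche import (
    annotate_otus,
    assign_archetypes,
    otu_source_profile,
    single_source_fraction,
    source_percentages,
    survey_summary,
)
from .phylogeny import jc_distance, neighbor_joining, write_newick

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated settings for a survey run; defaults are the study settings."""

    fasta: str = ""
    metadata: str = ""
    out_dir: str = "survey_out"
    identity_threshold: float = 0.87
    otu_threshold: float = 0.87
    min_len_bacteria: int = 400
    min_len_archaea: int = 300
    min_large: int = 3
    window_min_coverage: float = 0.5
    window_max_internal_gap: float = 0.1
    min_center_identity: float = 0.40
    require_aquatic: bool = True
    domains: tuple[str, ...] = ("Bacteria", "Archaea")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "otu_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("window_min_coverage", "window_max_internal_gap",
                     "min_center_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_large < 1:
            raise ValueError("min_large must be >= 1")
        if min(self.min_len_bacteria, self.min_len_archaea) < 1:
            raise ValueError("length floors must be positive")
        bad = set(self.domains) - {"Bacteria", "Archaea"}
        if bad:
            raise ValueError(f"unknown domains: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "domains" in raw:
            raw["domains"] = tuple(raw["domains"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class DomainResult:
    """Everything one domain track produced."""

    records: list[SeqRecord]
    clusters: list
    aquatic_clusters: list
    large_clusters: list
    individuals: list[str]
    divergent_clusters: list[str]
    window: object | None
    excluded_rows: list[str]
    otus: list
    summary: object | None
    counts: dict = field(default_factory=dict)


def _run_domain(records: list[SeqRecord], config: PipelineConfig, domain: str):
    prefix = "CARC" if domain == "Archaea" else "CBAC"
    clusters = greedy_cluster(records, config.identity_threshold, id_prefix=prefix)
    aquatic = (filter_aquatic_clusters(clusters, records)
               if config.require_aquatic else clusters)
    large, individuals = partition_by_size(aquatic, config.min_large)
    by_acc = {r.accession: r for r in records}

    consensus: dict[str, str] = {}
    cluster_members: dict[str, list[str]] = {}
    divergent_clusters: list[str] = []
    for cl in large:
        seqs = {m: by_acc[m].sequence for m in cl.members}
        _, mean_ident = choose_center(seqs)
        if mean_ident < config.min_center_identity:
            divergent_clusters.append(cl.cluster_id)
            continue
        aln = center_star_align(seqs)
        consensus[cl.cluster_id] = majority_consensus(aln)
        cluster_members[cl.cluster_id] = list(cl.members)
    individual_seqs = {acc: by_acc[acc].sequence for acc in individuals}

    window = None
    excluded: list[str] = []
    master: Alignment | None = None
    if len(consensus) + len(individual_seqs) >= 2:
        master = build_master_alignment(consensus, individual_seqs)
        window = extract_window(master, config.window_min_coverage,
                                config.window_max_internal_gap)
        kept, excluded = exclude_divergent(master, window,
                                           config.window_max_internal_gap)
        window_seqs = trim_to_window(master, window, kept)
    else:
        window_seqs = {**consensus, **individual_seqs}

    weights = {cid: len(mem) for cid, mem in cluster_members.items()}
    otus = assign_archetypes(window_seqs, config.otu_threshold, weights=weights)
    annotate_otus(otus, records, member_expansion=cluster_members)
    analyzed = [cl for cl in large if cl.cluster_id not in divergent_clusters]
    summary = None
    if aquatic:
        summary = survey_summary(aquatic, (large, individuals), otus)

    counts = {
        "n_records": len(records),
        "n_clusters": len(clusters),
        "n_aquatic_clusters": len(aquatic),
        "n_large_clusters": len(large),
        "n_individuals": len(individuals),
        "n_divergent_clusters": len(divergent_clusters),
        "n_consensus": len(consensus),
        "n_window_excluded": len(excluded),
        "n_otus": len(otus),
        "n_sequences_in_aquatic": sum(cl.size for cl in aquatic),
        "n_sequences_in_large": sum(cl.size for cl in large),
        "n_sequences_analyzed": sum(len(m) for m in cluster_members.values())
        + len(individual_seqs),
    }
    assert counts["n_sequences_in_aquatic"] == (
        counts["n_sequences_in_large"] + counts["n_individuals"]
    ), "sequence conservation violated at the size partition"
    result = DomainResult(
        records=records, clusters=clusters, aquatic_clusters=aquatic,
        large_clusters=analyzed, individuals=individuals,
        divergent_clusters=divergent_clusters, window=window,
        excluded_rows=excluded, otus=otus, summary=summary, counts=counts,
    )
    return result, master


def run_pipeline(
    config: PipelineConfig, records: list[SeqRecord] | None = None
) -> dict:
    """Run the whole survey; returns the manifest and writes outputs to out_dir.

    ``records`` may be passed directly (e.g. from the simulator); otherwise
    they are read from the configured FASTA + metadata paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records is None:
        records = read_survey(config.fasta, config.metadata)
    n_input = len(records)
    records = deduplicate(records)
    n_dedup = len(records)
    records = filter_by_length(records, config.min_len_bacteria, config.min_len_archaea)
    n_filtered = len(records)

    manifest: dict = {
        "genesurvey_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "counts": {
            "n_input": n_input,
            "n_after_dedup": n_dedup,
            "n_after_length_filter": n_filtered,
        },
        "domains": {},
    }

    for domain in config.domains:
        recs = [r for r in records if r.domain == domain]
        dom_key = domain.lower()
        if not recs:
            manifest["domains"][dom_key] = {"note": "no records"}
            continue
        result, master = _run_domain(recs, config, domain)
        _write_domain_outputs(out, dom_key, result, master)
        dom_manifest = dict(result.counts)
        if result.window is not None:
            dom_manifest["window"] = {
                "start": result.window.start,
                "end": result.window.end,
                "length": result.window.length,
                "coverage": result.window.coverage,
            }
        if result.summary is not None:
            dom_manifest["summary"] = result.summary.as_dict()
            profiles = otu_source_profile(result.otus)
            dom_manifest["single_source_otu_pct"] = single_source_fraction(profiles)
        if len(result.otus) >= 3 and master is not None and result.window is not None:
            arch_rows = {
                otu.otu_id: master.rows[otu.archetype][
                    result.window.start:result.window.end
                ]
                for otu in result.otus
                if otu.archetype in master.rows
            }
            if len(arch_rows) >= 3:
                tree = neighbor_joining(jc_distance(Alignment(rows=arch_rows)))
                write_newick(tree, out / f"tree_{dom_key}.nwk")
                dom_manifest["tree"] = f"tree_{dom_key}.nwk"
            else:
                dom_manifest["tree"] = None
        else:
            dom_manifest["tree"] = None
        manifest["domains"][dom_key] = dom_manifest

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest


def _write_domain_outputs(out: Path, dom_key: str, result: DomainResult,
                          master: Alignment | None) -> None:
    with open(out / f"clusters_{dom_key}.tsv", "w") as fh:
        fh.write("cluster_id\trepresentative\tsize\tmembers\n")
        for cl in result.aquatic_clusters:
            fh.write(f"{cl.cluster_id}\t{cl.representative}\t{cl.size}\t"
                     f"{','.join(cl.members)}\n")
    ra = rank_abundance(result.aquatic_clusters)
    with open(out / f"rank_abundance_{dom_key}.tsv", "w") as fh:
        fh.write("rank\tsize\n")
        for rank, size in ra.ranks:
            fh.write(f"{rank}\t{size}\n")
    if master is not None:
        with open(out / f"master_{dom_key}.afa", "w") as fh:
            for rid, row in master.rows.items():
                fh.write(f">{rid}\n{row}\n")
    if result.window is not None:
        with open(out / f"window_{dom_key}.tsv", "w") as fh:
            fh.write("start\tend\tlength\tcoverage\n")
            w = result.window
            fh.write(f"{w.start}\t{w.end}\t{w.length}\t{w.coverage}\n")
    with open(out / f"otus_{dom_key}.tsv", "w") as fh:
        fh.write("otu_id\tarchetype\tn_members\tmembers\tsources\ttaxonomy\n")
        for otu in result.otus:
            srcs = ",".join(sorted(otu.sources))
            fh.write(f"{otu.otu_id}\t{otu.archetype}\t{otu.size}\t"
                     f"{','.join(otu.members)}\t{srcs}\t{otu.taxonomy}\n")
    if result.otus and result.otus[0].sources:
        source_percentages(result.otus).to_csv(
            out / f"source_percentages_{dom_key}.tsv", sep="\t", index=False
        )
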