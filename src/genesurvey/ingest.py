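"""Reading, deduplicating and length-filtering survey sequences.

A survey arrives as a multi-record nucleotide FASTA plus a tab-separated
metadata table keyed on accession, carrying the domain (Bacteria/Archaea,
Eukaryota rows are dropped on read), one of nine controlled environmental
source labels, and optional taxonomy ranks ("NA" where unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: the nine controlled environmental source categories
SOURCE_LABELS = (
    "marine_sediment",
    "marine_water_column",
    "marine_omz",
    "freshwater_estuary",
    "hydrothermal_vent",
    "wastewater",
    "aquatic_other",
    "terrestrial",
    "animal",
)

_NON_AQUATIC = frozenset({"terrestrial", "animal"})

#: taxonomy ranks carried in the metadata table, most to least inclusive
RANKS = ("phylum", "class", "order", "family", "genus")

_DOMAINS = frozenset({"Bacteria", "Archaea"})
_IUPAC = frozenset("ACGTNRYSWKMBDHV")


def is_aquatic(source: str) -> bool:
    """True for every source category except terrestrial and animal."""
    if source not in SOURCE_LABELS:
        raise ValueError(f"unknown source label: {source!r}")
    return source not in _NON_AQUATIC


@dataclass(frozen=True)
class SeqRecord:
    """One gene sequence with its survey metadata.

    ``taxonomy`` holds the five ranks of :data:`RANKS` in order, "NA" where
    unclassified.  Sequences are normalised on construction to uppercase DNA
    (U becomes T).
    """

    accession: str
    sequence: str
    domain: str
    source: str
    taxonomy: tuple[str, ...] = field(default=("NA",) * 5)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - _IUPAC
        if not seq or bad:
            raise ValueError(
                f"{self.accession}: invalid sequence characters {sorted(bad)}"
                if bad
                else f"{self.accession}: empty sequence"
            )
        object.__setattr__(self, "sequence", seq)
        if self.domain not in _DOMAINS:
            raise ValueError(f"{self.accession}: domain must be one of {sorted(_DOMAINS)}")
        if self.source not in SOURCE_LABELS:
            raise ValueError(f"{self.accession}: unknown source {self.source!r}")
        if len(self.taxonomy) != len(RANKS):
            raise ValueError(f"{self.accession}: taxonomy must have {len(RANKS)} ranks")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def aquatic(self) -> bool:
        return is_aquatic(self.source)


def _validate_fasta_layout(fasta_path) -> None:
    """Cheap structural check so malformed files fail with a line number."""
    with open(fasta_path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise ValueError(f"{fasta_path}: empty FASTA id at line {lineno}")
                seen_header = True
            elif not seen_header:
                raise ValueError(
                    f"{fasta_path}: sequence data before first '>' header at line {lineno}"
                )


def read_survey(fasta_path, metadata_path) -> list[SeqRecord]:
    """Read a FASTA + metadata TSV pair into records, in FASTA file order.

    Every FASTA id must resolve to a metadata row; a missing row is a hard
    error naming the accession.  Eukaryota rows are dropped with a logged
    count; metadata rows without a FASTA record are reported as warnings.
    """
    _validate_fasta_layout(fasta_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"accession", "domain", "source", *RANKS}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"{metadata_path}: missing columns {sorted(missing_cols)}")
    by_acc = meta.set_index("accession", verify_integrity=True)

    records: list[SeqRecord] = []
    seen: set[str] = set()
    n_eukaryota = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in by_acc.index:
            raise ValueError(f"accession {rec.id!r} has no metadata row")
        row = by_acc.loc[rec.id]
        seen.add(rec.id)
        if row["domain"] == "Eukaryota":
            n_eukaryota += 1
            continue
        records.append(
            SeqRecord(
                accession=rec.id,
                sequence=str(rec.seq),
                domain=row["domain"],
                source=row["source"],
                taxonomy=tuple(row[r] for r in RANKS),
            )
        )
    if n_eukaryota:
        logger.info("dropped %d Eukaryota records", n_eukaryota)
    orphans = set(by_acc.index) - seen
    if orphans:
        logger.warning("%d metadata rows had no FASTA record: %s",
                       len(orphans), sorted(orphans)[:10])
    return records


def write_survey(records: list[SeqRecord], fasta_path, metadata_path) -> None:
    """Write records back out as the FASTA + TSV pair `read_survey` accepts."""
    SeqIO.write(
        (_BioSeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
    pd.DataFrame(
        [
            {"accession": r.accession, "domain": r.domain, "source": r.source,
             **dict(zip(RANKS, r.taxonomy))}
            for r in records
        ],
        columns=["accession", "domain", "source", *RANKS],
    ).to_csv(metadata_path, sep="\t", index=False)


def deduplicate(records: list[SeqRecord]) -> list[SeqRecord]:
    """Drop records whose sequence string was already seen, keeping the first.

    Equality is exact string equality of the normalised (uppercase, U→T)
    sequence; the accession plays no part in the key.  Input order is
    preserved.
    """
    seen: set[str] = set()
    kept: list[SeqRecord] = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            kept.append(rec)
    n_removed = len(records) - len(kept)
    if n_removed:
        logger.info("deduplicate: removed %d of %d records", n_removed, len(records))
    return kept


def filter_by_length(
    records: list[SeqRecord], min_bacteria: int = 400, min_archaea: int = 300
) -> list[SeqRecord]:
    """Keep bacterial records of length >= min_bacteria and archaeal of >= min_archaea.

    Thresholds are inclusive.  The defaults are the survey's gene-length
    floors for the two domains.
    """
    floors = {"Bacteria": min_bacteria, "Archaea": min_archaea}
    for rec in records:
        if rec.domain not in floors:
            raise ValueError(f"{rec.accession}: unexpected domain {rec.domain!r}")
    kept = [r for r in records if len(r) >= floors[r.domain]]
    n_removed = len(records) - len(kept)
    if n_removed:
        logger.info("filter_by_length: removed %d of %d records", n_removed, len(records))
    return kept
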