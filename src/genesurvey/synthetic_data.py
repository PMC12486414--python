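"""Synthetic survey generator with planted, recoverable structure.

Emulates the geometry of a public-database functional-gene compilation
without any download: families of related sequences radiate from per-domain
root genes (bacterial-like ~1,105 bp, archaeal-like ~1,425 bp), members
within a family differ by a small per-site substitution rate while family
ancestors are strongly diverged from each other, a fraction of records is
truncated to PCR-fragment-like pieces, exact duplicates are injected, and
each family is habitat-specific (single environmental source) with a tunable
probability.  Every planted fact is returned as ground truth so downstream
stages can be scored against it.

Randomness derives from one global seed, stream-split per family, so the
same config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus_window import Alignment, AlignmentWindow
from .ingest import SOURCE_LABELS, SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# small taxonomy pools for plausible-looking rank labels
_PHYLA = {
    "Bacteria": ("Pseudomonadota", "Bacteroidota", "Nitrospirota"),
    "Archaea": ("Nitrososphaerota", "Euryarchaeota"),
}
_CLASSES = {
    "Pseudomonadota": ("Alphaproteobacteria", "Betaproteobacteria",
                       "Gammaproteobacteria"),
    "Bacteroidota": ("Flavobacteriia",),
    "Nitrospirota": ("Nitrospiria",),
    "Nitrososphaerota": ("Nitrososphaeria",),
    "Euryarchaeota": ("Halobacteria",),
}


@dataclass
class SyntheticConfig:
    """Study-condition knobs for a simulated survey.

    Defaults are the survey-like regime the test-bed assumes: strongly
    separated families (within-family substitution rate 0.03 per site vs.
    0.45 between family ancestors, i.e. within-family identity far above the
    0.87 clustering threshold and between-family identity far below it),
    mostly PCR-fragment-length records with a minority of whole genes, a few
    percent exact duplicates, and three-quarters of families confined to a
    single environmental source.
    """

    n_families: int = 10
    seqs_per_family: tuple[int, int] = (4, 20)  # inclusive range
    ancestor_length_bacteria: int = 1105
    ancestor_length_archaea: int = 1425
    within_family_sub_rate: float = 0.03
    between_family_divergence: float = 0.30
    conserved_fraction: float = 0.25
    fragment_prob: float = 0.7
    fragment_length: tuple[int, int] = (350, 900)
    fragment_anchor: float | None = 0.6
    duplicate_rate: float = 0.05
    source_specificity: float = 0.75
    archaea_fraction: float = 0.15
    source_pool: tuple[str, ...] = SOURCE_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_family_sub_rate", "between_family_divergence",
                     "conserved_fraction", "fragment_prob", "duplicate_rate",
                     "source_specificity", "archaea_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if isinstance(self.seqs_per_family, int):
            self.seqs_per_family = (self.seqs_per_family, self.seqs_per_family)
        lo, hi = self.seqs_per_family
        if not 1 <= lo <= hi:
            raise ValueError("seqs_per_family range must satisfy 1 <= lo <= hi")
        if min(self.ancestor_length_bacteria, self.ancestor_length_archaea) < 1:
            raise ValueError("ancestor lengths must be positive")
        flo, fhi = self.fragment_length
        min_anc = min(self.ancestor_length_bacteria, self.ancestor_length_archaea)
        if not 1 <= flo <= fhi:
            raise ValueError("fragment_length range must satisfy 1 <= lo <= hi")
        if self.fragment_prob > 0.0 and flo > min_anc:
            raise ValueError("fragment_length minimum exceeds the ancestor length")
        if self.fragment_anchor is not None and not 0.0 <= self.fragment_anchor <= 1.0:
            raise ValueError("fragment_anchor must be in [0, 1] or None")
        unknown = set(self.source_pool) - set(SOURCE_LABELS)
        if unknown or not self.source_pool:
            raise ValueError(f"invalid source pool entries: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted facts behind a simulated survey."""

    family_of: dict[str, str] = field(default_factory=dict)
    family_domain: dict[str, str] = field(default_factory=dict)
    family_sources: dict[str, tuple[str, ...]] = field(default_factory=dict)
    family_single_source: dict[str, bool] = field(default_factory=dict)
    ancestors: dict[str, str] = field(default_factory=dict)
    duplicate_accessions: list[str] = field(default_factory=list)

    @property
    def n_duplicates(self) -> int:
        return len(self.duplicate_accessions)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(
    seq: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    protected: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site substitution to one of the three other bases.

    Sites flagged in ``protected`` are immune — used for the conserved
    functional core shared by all family ancestors.
    """
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    if protected is not None:
        hit &= ~protected
    offsets = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + offsets) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def expected_within_family_identity(rate: float) -> float:
    """Expected per-site identity of two siblings mutated at `rate` from one ancestor.

    Both same as ancestor: (1-r)^2; both mutated and coinciding: r^2/3.
    """
    return (1.0 - rate) ** 2 + rate**2 / 3.0


def simulate_survey(config: SyntheticConfig) -> tuple[list[SeqRecord], GroundTruth]:
    """Generate a survey with planted family, fragment, duplicate and source structure."""
    ss = np.random.SeedSequence(config.seed)
    global_stream, *family_streams = ss.spawn(config.n_families + 1)
    g_rng = np.random.default_rng(global_stream)
    roots = {
        "Bacteria": _random_seq(g_rng, config.ancestor_length_bacteria),
        "Archaea": _random_seq(g_rng, config.ancestor_length_archaea),
    }
    # sites under deep functional constraint: shared verbatim by all ancestors
    conserved = {
        dom: g_rng.random(len(root)) < config.conserved_fraction
        for dom, root in roots.items()
    }
    truth = GroundTruth()
    records: list[SeqRecord] = []
    for fam_idx, stream in enumerate(family_streams):
        rng = np.random.default_rng(stream)
        domain = "Archaea" if rng.random() < config.archaea_fraction else "Bacteria"
        fam_id = f"F{fam_idx:03d}"
        ancestor = _mutate(roots[domain], config.between_family_divergence, rng,
                           protected=conserved[domain])
        single = rng.random() < config.source_specificity
        if single:
            sources = (str(rng.choice(config.source_pool)),)
        else:
            k = min(int(rng.integers(2, 4)), len(config.source_pool))
            sources = tuple(rng.choice(config.source_pool, size=k, replace=False))
        taxonomy = _family_taxonomy(domain, rng)
        truth.family_domain[fam_id] = domain
        truth.family_sources[fam_id] = sources
        truth.family_single_source[fam_id] = single
        truth.ancestors[fam_id] = _to_str(ancestor)
        lo, hi = config.seqs_per_family
        n_members = int(rng.integers(lo, hi + 1))
        for m_idx in range(n_members):
            seq = _mutate(ancestor, config.within_family_sub_rate, rng)
            if rng.random() < config.fragment_prob:
                flo, fhi = config.fragment_length
                frag_len = int(rng.integers(flo, min(fhi, len(seq)) + 1))
                if config.fragment_anchor is not None:
                    # PCR-like fragments: centred on a common locus with a
                    # little end jitter, so family members overlap heavily
                    anchor = int(config.fragment_anchor * len(seq))
                    jitter = int(rng.integers(-frag_len // 50, frag_len // 50 + 1))
                    start = anchor - frag_len // 2 + jitter
                    start = max(0, min(start, len(seq) - frag_len))
                else:
                    start = int(rng.integers(0, len(seq) - frag_len + 1))
                seq = seq[start:start + frag_len]
            acc = f"{'ARC' if domain == 'Archaea' else 'BAC'}{fam_idx:03d}_{m_idx:03d}"
            records.append(
                SeqRecord(
                    accession=acc,
                    sequence=_to_str(seq),
                    domain=domain,
                    source=str(rng.choice(sources)),
                    taxonomy=taxonomy,
                )
            )
            truth.family_of[acc] = fam_id
    # exact duplicates, appended after the originals so keep-first retains the originals
    n_dup = round(config.duplicate_rate * len(records))
    if n_dup:
        targets = g_rng.choice(len(records), size=n_dup, replace=False)
        for k, t in enumerate(sorted(int(t) for t in targets)):
            orig = records[t]
            acc = f"{orig.accession}_dup{k:02d}"
            records.append(
                SeqRecord(
                    accession=acc,
                    sequence=orig.sequence,
                    domain=orig.domain,
                    source=orig.source,
                    taxonomy=orig.taxonomy,
                )
            )
            truth.family_of[acc] = truth.family_of[orig.accession]
            truth.duplicate_accessions.append(acc)
    return records, truth


def _family_taxonomy(domain: str, rng: np.random.Generator) -> tuple[str, ...]:
    """Partially classified ranks: some families stay unknown, as in real surveys."""
    if rng.random() < 0.5:
        return ("NA",) * 5
    phylum = str(rng.choice(_PHYLA[domain]))
    ranks = [phylum, "NA", "NA", "NA", "NA"]
    if rng.random() < 0.8:
        ranks[1] = str(rng.choice(_CLASSES[phylum]))
        if rng.random() < 0.5:
            ranks[4] = f"Genus{int(rng.integers(0, 30)):02d}"
    return tuple(ranks)


def plant_window(
    n_cols: int = 400,
    window: tuple[int, int] = (120, 280),
    n_core: int = 7,
    n_full: int = 2,
    n_ragged: int = 3,
    seed: int = 0,
) -> tuple[Alignment, AlignmentWindow]:
    """Build a staggered alignment whose maximal-coverage window is known.

    ``n_core`` rows span exactly the planted window, ``n_full`` rows span
    every column, and ``n_ragged`` rows are short fragments strictly inside
    the window.  With the default coverage floor of half the rows, extending
    past the window loses the core rows (coverage collapses to ``n_full``),
    so the planted interval is the unique optimum whenever
    ``n_full + n_ragged < ceil(0.5 * n_rows) <= n_core + n_full``.
    With ``n_core = n_ragged = 0`` every row is full length and the planted
    window is the whole alignment.
    """
    rng = np.random.default_rng(seed)
    start, end = window
    if (n_core or n_ragged) and not 0 <= start < end <= n_cols:
        raise ValueError("window must lie inside [0, n_cols)")
    rows: dict[str, str] = {}

    def spanning_row(lo: int, hi: int) -> str:
        body = _to_str(_random_seq(rng, hi - lo))
        return "-" * lo + body + "-" * (n_cols - hi)

    for k in range(n_core):
        rows[f"core{k:02d}"] = spanning_row(start, end)
    for k in range(n_full):
        rows[f"full{k:02d}"] = spanning_row(0, n_cols)
    span = end - start
    for k in range(n_ragged):
        frag_len = int(rng.integers(max(2, span // 8), max(3, span // 2)))
        lo = int(rng.integers(start, end - frag_len + 1))
        rows[f"frag{k:02d}"] = spanning_row(lo, lo + frag_len)
    alignment = Alignment(rows=rows)
    if n_core == 0 and n_ragged == 0:
        truth = AlignmentWindow(start=0, end=n_cols, coverage=n_full)
    else:
        truth = AlignmentWindow(start=start, end=end, coverage=n_core + n_full)
    return alignment, truth
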