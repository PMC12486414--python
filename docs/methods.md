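# Methods

This note records the models, conventions and design choices behind
`genesurvey`, in the order the pipeline applies them.

## Sequence identity

Every threshold in the pipeline is expressed in terms of one identity
primitive (`genesurvey._align`): a global alignment with free end gaps
(match +1, mismatch −1, gap −2), with identity defined as the number of
identical aligned positions divided by the length of the shorter sequence.
Free end gaps are *one-sided*: unaligned leading characters may come from
only one of the two sequences, and likewise trailing ones. The alternative
(both sequences free at both ends) is equivalent to local alignment and
would silently trim mismatching ends of equal-length sequences, inflating
identity; the one-sided convention scores a PCR fragment against a whole
gene without penalty while still forcing equal-length sequences to align
end to end. `N` and IUPAC ambiguity codes never match anything, including
themselves — conservative and deterministic.

Because co-optimal alignments can disagree on the number of matched
positions, the dynamic programme maximises the pair (score, matches)
lexicographically, which makes the identity fraction well defined. The pair
is packed into one int64 (`score * 2^20 + matches`); every edit step adds a
constant, and adding a constant preserves lexicographic order, so the usual
recursion applies and rows can be vectorised with a running-maximum trick
for the linear gap cost.

## Greedy clustering (87%)

Sequences are visited longest-first (ties: lexicographic accession) and
join the first existing cluster whose representative they match at
≥ 0.87 identity, else found a new cluster. Comparing to representatives
only — not all members — mirrors CD-HIT semantics and makes two invariants
checkable: every member reaches the threshold to its representative, and
representatives of distinct clusters are pairwise below it. The default
0.87 is the identity level commonly used to delimit functional-gene groups
at roughly species resolution. Clusters lacking any aquatic-source member
are dropped (the survey's scope is marine/aquatic); clusters of fewer than
`min_large = 3` sequences dissolve into individual sequences. The
literature this pipeline follows states both "more than three" and "one or
two removed" for that boundary; `min_large` is configurable and defaults to
3, consistent with the published counts of clusters "containing more than
2 sequences".

## Consensus and the shared window

Large clusters are center-star aligned: the member with the greatest summed
identity to the rest is the star, every other member is pairwise-aligned to
it, and the pairwise alignments are merged under once-a-gap-always-a-gap.
This is deterministic and adequate at the within-cluster identity scales
the threshold guarantees (≥ 0.87); it does not attempt guide trees or
iterative refinement. A cluster whose members average < 0.40 identity to
the star is set aside whole as unalignable rather than forced through.
The consensus is per-column plurality: majority-gap columns are dropped,
otherwise the most frequent non-gap base wins, ties resolved
alphabetically.

The master alignment (cluster consensus sequences + individual sequences)
is scanned for the *window*: the longest contiguous column interval whose
coverage reaches `ceil(min_coverage_fraction × n_rows)` (default fraction
0.5). A row covers an interval if it has a base at both interval ends and
at most 10% internal gaps. The published procedure is bi-objective
("longest region where the greatest number overlap"); this implementation
resolves it as a coverage floor first, then maximum length, with ties going
to higher coverage and then the leftmost start. The floor and gap tolerance
are configurable. Rows that fail the coverage rule for the chosen window
are excluded and logged, mirroring the survey's exclusion of individual
sequences that did not align in the shared region. Coordinates are 0-based
half-open throughout.

## OTU archetypes

Window sequences (de-gapped window substrings) are grouped at 87% identity
by greedy maximal coverage: the sequence matching the most still-unassigned
sequences becomes the next archetype and claims them, until all are
assigned. Ties prefer the candidate standing for the larger source cluster,
then the lexicographically smaller id. Identity between window sequences is
computed by re-aligning the de-gapped pairs with the same primitive as
clustering, rather than by comparing gapped columns — one identity
convention everywhere. Greedy maximal coverage is this package's concrete
realization of archetype selection; the historical probe-design algorithm
it stands in for is not specified at this level of detail anywhere we could
follow, so the choice is documented here as an interpretation. On
well-separated inputs it provably returns the minimum number of archetypes
(each family's sequences mutually match and no others), which the tests
assert against an exhaustive set-cover oracle.

## Niche statistics

An OTU's source profile is the multiset of environmental source labels over
its member records (cluster consensus members expand to their cluster's
accessions). The nine controlled labels are marine_sediment,
marine_water_column, marine_omz, freshwater_estuary, hydrothermal_vent,
wastewater, aquatic_other, terrestrial, animal; all but the last two count
as aquatic. A post-hoc hypersaline relabeling of flagged `aquatic_other`
members is supported for the archaeal-style breakdown. In per-source
percentage tables an OTU contributes one count to every distinct source
among its members (configurable to majority-source-only); percentages are
taken over total contributions within a group so each group sums to 100 up
to rounding. All percentages are rounded to one decimal, half away from
zero — the convention that reproduces every checkable published value.
OTU taxonomy is the most specific rank shared by at least half of the
classified member records, else "unknown".

## Phylogeny

Jukes–Cantor distances are computed over shared non-gap columns (pairwise
deletion; window rows are near-complete so the impact is minimal), with
saturated pairs (p ≥ 3/4) capped at a configurable maximum with a warning.
Neighbor joining is the standard agglomeration with Q-criterion ties going
to the smallest index pair and negative branch-length estimates clamped to
zero; it is exact on additive matrices, which the tests verify by
regenerating the input matrix from the output tree. NJ over JC distances
replaces likelihood-based inference deliberately: it is deterministic,
desk-scale, and sufficient for the clade-level structure the survey
interprets. Trees are emitted as Newick with OTU ids as leaf labels.

## Synthetic surveys

The generator emulates the geometry of a public-database gene compilation:

| parameter | default | meaning |
|---|---|---|
| `n_families` | 10 | planted species-level groups |
| `seqs_per_family` | (4, 20) | uniform inclusive range |
| `ancestor_length_bacteria/archaea` | 1105 / 1425 | reference gene lengths for the two domains |
| `within_family_sub_rate` | 0.03 | per-site substitution within a family (pairwise identity ≈ (1−r)² + r²/3 ≈ 0.94, far above the 0.87 threshold) |
| `between_family_divergence` | 0.30 | per-site divergence of family ancestors from a root (identity ≈ 0.63 with the conserved core, far below threshold) |
| `conserved_fraction` | 0.25 | sites under deep functional constraint, shared verbatim by all ancestors — the conserved motifs that make cross-family alignment meaningful for a real functional gene |
| `fragment_prob`, `fragment_length` | 0.7, (350, 900) | PCR-fragment truncation |
| `fragment_anchor` | 0.6 | fragments are centred (±2% jitter) on a common locus, as amplicons with fixed primer sites are |
| `duplicate_rate` | 0.05 | exact duplicates appended after their originals |
| `source_specificity` | 0.75 | probability a family is single-source (else 2–3 sources) |
| `archaea_fraction` | 0.15 | domain mix |

One global seed is stream-split per family, so the same config yields
byte-identical FASTA/TSV. Substitutions only, by default: length variation
in real compilations comes chiefly from fragmentation, which the fragment
model covers; there is no indel, codon, GC or horizontal-transfer
modelling. Ground truth records each record's family, each family's
domain and planted sources, the ancestors, and the injected duplicates.
`plant_window` builds staggered alignments whose maximal-coverage window is
known by construction (core rows spanning exactly the planted interval,
a sub-floor number of full-length rows, ragged fragments inside).

What passing tests on these surveys do **not** show: robustness to indels
and chimeras, to misannotated metadata, to identity levels near the 0.87
boundary (the recovery guarantees are proved in the well-separated regime),
or to the taxonomic label noise of real databases.

## Problem sizes

The test suite and the acceptance script run synthetic surveys of 5–40
families (≈ 60–240 sequences, 300–1425 bp); these sizes give exact planted
recovery and tight statistical checks while keeping a full run in the tens
of seconds on one CPU. The clustering stage is quadratic in the number of
cluster representatives and linear in sequence length per comparison, and
scales to thousands of sequences without modification.

## Known limitations

* The center-star aligner degrades below ≈ 40–50% pairwise identity, where
  any alignment is ill-defined; such clusters are set aside, as the
  published procedure also did for its most divergent clusters.
* Published totals that are internally inconsistent in the source tables
  (e.g. alternative counts of individual sequences) are reported as-is
  where touched, never reconciled silently.
* The aquatic-cluster filter biases recovered single-source fractions on
  synthetic data (single-source terrestrial families are removed
  preferentially), so specificity-recovery checks run before that filter.
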