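"""OTU archetype assignment, source profiles and survey bookkeeping."""

import itertools
import math

import numpy as np
import pytest

from genesurvey import (
    Cluster,
    DomainSummary,
    OTU,
    SeqRecord,
    annotate_otus,
    assign_archetypes,
    otu_source_profile,
    pairwise_identity,
    round_half_away,
    single_source_fraction,
    source_percentages,
    survey_summary,
)


def _mutate_str(seq, rate, rng):
    bases = "ACGT"
    return "".join(
        bases[(bases.index(ch) + rng.integers(1, 4)) % 4]
        if rng.random() < rate else ch
        for ch in seq
    )


def _min_cover_oracle(seqs, threshold):
    """Smallest number of archetypes covering all sequences (exhaustive)."""
    ids = list(seqs)
    match = {
        i: frozenset(
            j for j in ids
            if pairwise_identity(seqs[i], seqs[j]) >= threshold
        )
        for i in ids
    }
    universe = frozenset(ids)
    for k in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            if frozenset().union(*(match[c] for c in combo)) == universe:
                return k
    raise AssertionError("unreachable")


class TestAssignArchetypes:
    def test_mutually_similar_sequences_form_one_otu(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), size=100))
        seqs = {f"s{i}": _mutate_str(base, 0.02, rng) for i in range(6)}
        otus = assign_archetypes(seqs, 0.87)
        assert len(otus) == 1
        assert sorted(otus[0].members) == sorted(seqs)

    def test_empty_input_yields_no_otus(self):
        assert assign_archetypes({}, 0.87) == []

    def test_planted_families_match_exhaustive_set_cover(self):
        """Four well-separated families: greedy count equals the exhaustive
        minimum cover, and memberships follow the plants."""
        rng = np.random.default_rng(3)
        ancestors = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(4)]
        seqs = {}
        planted = {}
        for f, anc in enumerate(ancestors):
            for m in range(4):
                sid = f"f{f}m{m}"
                seqs[sid] = _mutate_str(anc, 0.02, rng)
                planted[sid] = f
        otus = assign_archetypes(seqs, 0.87)
        assert len(otus) == 4 == _min_cover_oracle(seqs, 0.87)
        for otu in otus:
            assert len({planted[m] for m in otu.members}) == 1

    def test_members_reach_threshold_to_archetype_and_partition(self):
        rng = np.random.default_rng(12)
        ancestors = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(3)]
        seqs = {
            f"f{f}m{m}": _mutate_str(anc, 0.04, rng)
            for f, anc in enumerate(ancestors) for m in range(6)
        }
        otus = assign_archetypes(seqs, 0.87)
        assigned = [m for otu in otus for m in otu.members]
        assert sorted(assigned) == sorted(seqs)
        for otu in otus:
            for m in otu.members:
                assert pairwise_identity(seqs[m], seqs[otu.archetype]) >= 0.87

    def test_weight_breaks_ties_toward_large_source_clusters(self):
        seqs = {"a": "ACGTACGTAC", "b": "ACGTACGTAC"}
        otus = assign_archetypes(seqs, 0.87, weights={"b": 5})
        assert otus[0].archetype == "b"


def _records_for(sources_by_acc, taxonomy=("NA",) * 5):
    return [
        SeqRecord(accession=acc, sequence="ACGT", domain="Bacteria",
                  source=src, taxonomy=taxonomy)
        for acc, src in sources_by_acc.items()
    ]


class TestSourceProfiles:
    def test_single_source_otu(self):
        otus = [OTU("o0", "a", ["a", "b"])]
        recs = _records_for({"a": "marine_sediment", "b": "marine_sediment"})
        annotate_otus(otus, recs)
        prof = otu_source_profile(otus)
        assert prof.loc[0, "n_sources"] == 1

    def test_five_source_otu(self):
        srcs = ["marine_sediment", "marine_water_column", "marine_omz",
                "wastewater", "terrestrial"]
        otus = [OTU("o0", "m0", [f"m{i}" for i in range(5)])]
        recs = _records_for({f"m{i}": s for i, s in enumerate(srcs)})
        annotate_otus(otus, recs)
        assert otu_source_profile(otus).loc[0, "n_sources"] == 5

    def test_profile_equals_set_union_oracle(self):
        rng = np.random.default_rng(5)
        from genesurvey import SOURCE_LABELS
        accs = {f"m{i}": SOURCE_LABELS[int(rng.integers(9))] for i in range(30)}
        otus = [
            OTU(f"o{k}", f"m{10 * k}", [f"m{i}" for i in range(10 * k, 10 * k + 10)])
            for k in range(3)
        ]
        annotate_otus(otus, _records_for(accs))
        prof = otu_source_profile(otus).set_index("otu_id")
        for otu in otus:
            expected = {accs[m] for m in otu.members}
            assert prof.loc[otu.otu_id, "n_sources"] == len(expected)

    def test_member_expansion_resolves_cluster_ids(self):
        otus = [OTU("o0", "c0", ["c0", "x"])]
        recs = _records_for({"a": "marine_omz", "b": "terrestrial",
                             "x": "wastewater"})
        annotate_otus(otus, recs, member_expansion={"c0": ["a", "b"]})
        assert set(otus[0].sources) == {"marine_omz", "terrestrial", "wastewater"}

    def test_unresolved_member_is_an_error(self):
        otus = [OTU("o0", "ghost", ["ghost"])]
        with pytest.raises(ValueError, match="ghost"):
            annotate_otus(otus, [])


class TestSingleSourceFraction:
    @pytest.mark.parametrize(
        "n_single,n_total,expected",
        [(267, 353, 75.6), (37, 50, 74.0), (10, 10, 100.0)],
    )
    def test_fraction_values(self, n_single, n_total, expected):
        import pandas as pd
        prof = pd.DataFrame({
            "otu_id": [f"o{i}" for i in range(n_total)],
            "n_sources": [1] * n_single + [2] * (n_total - n_single),
        })
        assert single_source_fraction(prof) == expected

    def test_zero_otus_is_an_error(self):
        import pandas as pd
        with pytest.raises(ValueError):
            single_source_fraction(pd.DataFrame({"n_sources": []}))


class TestSourcePercentages:
    def test_single_otu_single_source_is_all_of_it(self):
        from collections import Counter
        otus = [OTU("o0", "a", ["a"], sources=Counter({"marine_omz": 1}))]
        table = source_percentages(otus)
        assert table.loc[0, "percent"] == 100.0

    def test_wastewater_dominated_class_geometry(self):
        """8 single-source OTUs, 5 from wastewater: wastewater reads 62.5%."""
        from collections import Counter
        srcs = ["wastewater"] * 5 + ["marine_sediment", "marine_omz",
                                     "freshwater_estuary"]
        otus = [OTU(f"o{i}", f"m{i}", [f"m{i}"], sources=Counter({s: 1}),
                    taxonomy="Betaproteobacteria") for i, s in enumerate(srcs)]
        table = source_percentages(otus, group_by_taxon=True).set_index("source")
        assert table.loc["wastewater", "percent"] == 62.5

    def test_random_fixture_matches_counting_oracle_and_sums_to_100(self):
        rng = np.random.default_rng(8)
        from collections import Counter
        from genesurvey import SOURCE_LABELS
        otus = []
        for i in range(40):
            k = int(rng.integers(1, 4))
            srcs = rng.choice(SOURCE_LABELS, size=k, replace=False)
            otus.append(OTU(f"o{i}", f"m{i}", [f"m{i}"],
                            sources=Counter({str(s): 1 for s in srcs})))
        table = source_percentages(otus)
        total = sum(len(o.sources) for o in otus)
        for _, row in table.iterrows():
            n = sum(1 for o in otus if row["source"] in o.sources)
            assert row["count"] == n
            assert row["percent"] == round_half_away(100 * n / total)
        assert abs(table["percent"].sum() - 100.0) <= 0.3

    def test_majority_counting_gives_one_vote_per_otu(self):
        from collections import Counter
        otus = [OTU("o0", "a", ["a"],
                    sources=Counter({"marine_omz": 3, "wastewater": 1}))]
        table = source_percentages(otus, counting="majority")
        assert list(table["source"]) == ["marine_omz"]
        assert table.loc[0, "percent"] == 100.0


class TestSurveySummary:
    def test_printed_integer_geometry(self):
        """180 of 729 clusters large, 2314 of 2876 sequences inside them."""
        s = DomainSummary(
            n_sequences=2876, n_clusters=729, n_large_clusters=180,
            n_sequences_in_large=2314, n_individuals=562,
            largest_cluster_size=167,
        )
        assert s.pct_large_clusters == 24.7
        assert s.pct_sequences_in_large == 80.5
        assert s.pct_clusters_individual == 75.3
        assert s.pct_sequences_individual == 19.5
        assert s.largest_cluster_share == 5.8

    def test_single_cluster_holding_everything(self):
        cl = Cluster("c0", "a", ["a", "b", "c"])
        s = survey_summary([cl], ([cl], []))
        assert s.pct_large_clusters == 100.0
        assert s.pct_sequences_in_large == 100.0
        assert s.pct_sequences_individual == 0.0

    def test_percentages_rederivable_from_counts(self):
        clusters = [
            Cluster("c0", "a", [f"a{i}" for i in range(5)]),
            Cluster("c1", "b", [f"b{i}" for i in range(3)]),
            Cluster("c2", "c", ["c0", "c1"]),
        ]
        large = clusters[:2]
        s = survey_summary(clusters, (large, ["c0", "c1"]))
        assert s.n_sequences == 10
        d = s.as_dict()
        assert d["pct_large_clusters"] == round_half_away(100 * 2 / 3)
        assert d["pct_sequences_in_large"] == 80.0

    def test_empty_survey_is_an_error(self):
        with pytest.raises(ValueError):
            survey_summary([], ([], []))


@pytest.mark.parametrize(
    "value,expected",
    [(24.65, 24.7), (24.64999, 24.6), (-1.25, -1.3), (0.05, 0.1), (2.0, 2.0)],
)
def test_rounding_is_half_away_from_zero(value, expected):
    assert round_half_away(value) == expected
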