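import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celluclass.cazy_ingest import (
    FilterThresholds,
    ModuleHit,
    build_genes,
    filter_hits,
    genes_from_frame,
    genes_to_frame,
    module_abundance,
    parse_dbcan_table,
    read_gene_tsv,
    write_gene_tsv,
)
from celluclass.errors import ConfigurationError, ParseError, ValidationError


def hit(family="GH9", protein="g1", genome="G1", start=1, end=100, e=1e-30, cov=0.9):
    return ModuleHit(family, protein, genome, start, end, e, cov)


class TestParseDbcanTable:
    def test_hmmscan_row_maps_fields_directly(self, tmp_path):
        path = tmp_path / "G1.hmmtab"
        path.write_text("GH48.hmm\t600\tg1\t700\t1e-50\t5\t590\t20\t650\t0.97\n")
        (hit,) = parse_dbcan_table(path)
        assert hit.family == "GH48"
        assert hit.protein_id == "g1"
        assert hit.genome_id == "G1"
        assert (hit.aa_start, hit.aa_end) == (20, 650)
        assert hit.e_value == 1e-50
        assert hit.hmm_coverage == 0.97

    def test_empty_file_yields_empty_list(self, tmp_path):
        path = tmp_path / "empty.hmmtab"
        path.write_text("")
        assert parse_dbcan_table(path) == []

    def test_two_families_on_one_protein(self, tmp_path):
        path = tmp_path / "G1.hmmtab"
        path.write_text(
            "GH9.hmm\t400\tg1\t700\t1e-40\t1\t390\t10\t400\t0.95\n"
            "CBM3.hmm\t100\tg1\t700\t1e-30\t1\t95\t450\t550\t0.90\n"
        )
        hits = parse_dbcan_table(path)
        assert [h.family for h in hits] == ["GH9", "CBM3"]
        assert {h.protein_id for h in hits} == {"g1"}

    def test_malformed_row_cites_line_number(self, tmp_path):
        path = tmp_path / "bad.hmmtab"
        path.write_text(
            "GH9.hmm\t400\tg1\t700\t1e-40\t1\t390\t10\t400\t0.95\n"
            "GH9.hmm\t400\tg2\t700\tnot_a_number\t1\t390\t10\t400\t0.95\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            parse_dbcan_table(path)

    def test_unknown_dialect_rejected(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("")
        with pytest.raises(ConfigurationError, match="dialect"):
            parse_dbcan_table(path, dialect="domtblout")

    def test_overview_dialect_splits_plus_joined_families(self, tmp_path):
        path = tmp_path / "G2.overview"
        path.write_text("Gene ID\tHMMER\ng1\tGH9+CBM3\ng2\tGH48\n")
        hits = parse_dbcan_table(path, dialect="overview")
        assert [(h.protein_id, h.family) for h in hits] == [
            ("g1", "GH9"),
            ("g1", "CBM3"),
            ("g2", "GH48"),
        ]
        # scores absent: treated as passing the default thresholds
        assert filter_hits(hits) == hits


class TestFilterHits:
    def test_high_e_value_removed(self):
        assert filter_hits([hit(e=1e-3)]) == []

    def test_low_coverage_removed(self):
        assert filter_hits([hit(cov=0.20)]) == []

    def test_best_per_region_keeps_lowest_e_value(self):
        a = hit(start=10, end=100, e=1e-40)
        b = hit(start=50, end=120, e=1e-20)
        assert filter_hits([a, b]) == [a]
        assert filter_hits([b, a]) == [a]

    def test_non_overlapping_same_family_both_survive(self):
        a = hit(start=10, end=100)
        b = hit(start=200, end=300)
        assert set(filter_hits([a, b])) == {a, b}

    def test_keep_all_policy_retains_overlaps(self):
        a = hit(start=10, end=100, e=1e-40)
        b = hit(start=50, end=120, e=1e-20)
        thresholds = FilterThresholds(same_family_overlap_policy="keep_all")
        assert set(filter_hits([a, b], thresholds)) == {a, b}

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 80),          # start
                st.integers(1, 60),          # span - 1
                st.sampled_from(["GH9", "GH5"]),
                st.floats(1e-60, 1e-16),
            ),
            max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_survivors_never_majority_overlap_and_filter_is_idempotent(self, raw):
        hits = [hit(family=f, start=s, end=s + d, e=e) for s, d, f, e in raw]
        once = filter_hits(hits)
        # no two surviving same-family hits overlap by more than half the
        # shorter interval (exhaustive pairwise check)
        for i, a in enumerate(once):
            for b in once[i + 1 :]:
                if a.family != b.family:
                    continue
                overlap = min(a.aa_end, b.aa_end) - max(a.aa_start, b.aa_start) + 1
                assert overlap <= min(a.span, b.span) / 2
        assert filter_hits(once) == once


class TestBuildGenes:
    def test_hits_grouped_per_protein(self):
        hits = [hit(protein="g1"), hit(protein="g1", family="CBM3", start=200, end=260), hit(protein="g2")]
        genes = build_genes(hits)
        assert sorted(len(g.hits) for g in genes) == [1, 2]

    def test_architecture_sorted_by_start(self):
        hits = [hit(family="CBM3", start=200, end=260), hit(family="GH9", start=1, end=100)]
        (gene,) = build_genes(hits)
        assert gene.families == ["GH9", "CBM3"]

    def test_hit_exceeding_protein_length_rejected(self):
        class P:
            genome_id, protein_id, aa_length = "G1", "g1", 700

        with pytest.raises(ValidationError, match="exceeds length"):
            build_genes([hit(start=700, end=800)], proteins=[P()])

    def test_permutation_invariance(self):
        hits = [hit(start=s, end=s + 40, family=f) for s, f in [(1, "GH9"), (100, "CBM3"), (200, "SLH")]]
        shuffled = list(hits)
        random.Random(0).shuffle(shuffled)
        assert build_genes(hits) == build_genes(shuffled)

    def test_no_empty_genes_emitted(self):
        assert build_genes([]) == []


class TestModuleAbundance:
    def test_occurrence_counting_within_one_gene(self):
        hits = [hit(start=1, end=50), hit(start=100, end=150), hit(family="CBM3", start=200, end=250)]
        genes = build_genes(hits)
        assert module_abundance(genes) == {"G1": {"GH9": 2, "CBM3": 1}}

    def test_empty_corpus(self):
        assert module_abundance([]) == {}

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["G1", "G2"]),
                st.sampled_from(["g1", "g2", "g3"]),
                st.sampled_from(["GH9", "CBM3", "SLH"]),
                st.integers(1, 500),
            ),
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_total_counts_equal_hit_count(self, raw):
        hits = [hit(genome=g, protein=p, family=f, start=s, end=s + 10) for g, p, f, s in raw]
        genes = build_genes(hits)
        total = sum(sum(counts.values()) for counts in module_abundance(genes).values())
        assert total == len(hits)


class TestGeneTableRoundTrip:
    def test_tsv_round_trip_preserves_genes(self, tmp_path):
        hits = [
            hit(protein="g1", family="GH9", start=1, end=100),
            hit(protein="g1", family="CBM3", start=150, end=220),
            hit(protein="g2", genome="G2", family="SLH", start=5, end=60),
        ]

        class P:
            def __init__(self, g, p, n):
                self.genome_id, self.protein_id, self.aa_length = g, p, n

        genes = build_genes(hits, proteins=[P("G1", "g1", 300), P("G2", "g2", 100)])
        path = write_gene_tsv(genes, tmp_path / "genes.tsv")
        assert read_gene_tsv(path) == genes

    def test_frame_round_trip(self):
        genes = build_genes([hit(), hit(family="CBM3", start=200, end=260)])
        assert genes_from_frame(genes_to_frame(genes)) == genes
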