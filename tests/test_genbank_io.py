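import pytest

from celluclass.errors import ParseError, ValidationError
from celluclass.genbank_io import (
    StrainManifest,
    aggregate_strain,
    parse_genbank,
    read_faa,
    read_manifest,
    write_faa,
)
from conftest import make_genbank

# toy CDS nucleotides; the expected protein is translated independently with
# the bacterial codon table and frozen here: ATG=M, AAA=K, CTG=L, TAA=stop
TOY_CDS = "atgaaactgtaa"
TOY_PROTEIN = "MKL"


def write_gbk(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestParseGenbank:
    def test_single_cds_with_translation(self, tmp_path):
        gbk = make_genbank("REP1", 60, [{"start": 1, "end": 12, "protein_id": "p1", "translation": "MKL"}])
        (rec,) = parse_genbank(write_gbk(tmp_path, "a.gbk", gbk))
        assert rec.protein_id == "p1"
        assert rec.aa_sequence == "MKL"
        assert rec.aa_length == 3
        assert (rec.nt_start, rec.nt_end, rec.strand) == (1, 12, "+")
        assert rec.replicon_id == "REP1.1"

    def test_two_cds_opposite_strands_ordered_by_start(self, tmp_path):
        gbk = make_genbank(
            "REP1", 60,
            [
                {"start": 30, "end": 41, "strand": "-", "protein_id": "p2", "translation": "MWV"},
                {"start": 1, "end": 12, "protein_id": "p1", "translation": "MKL"},
            ],
        )
        records = parse_genbank(write_gbk(tmp_path, "a.gbk", gbk))
        assert [r.protein_id for r in records] == ["p1", "p2"]
        assert [r.strand for r in records] == ["+", "-"]

    def test_cds_without_translation_uses_bacterial_codon_table(self, tmp_path):
        gbk = make_genbank("REP1", 12, [{"start": 1, "end": 12, "protein_id": "p1"}], sequence=TOY_CDS)
        (rec,) = parse_genbank(write_gbk(tmp_path, "a.gbk", gbk))
        assert rec.aa_sequence == TOY_PROTEIN  # trailing stop stripped

    def test_pseudo_cds_skipped(self, tmp_path):
        gbk = make_genbank(
            "REP1", 60,
            [
                {"start": 1, "end": 12, "protein_id": "p1", "translation": "MKL"},
                {"start": 20, "end": 31, "protein_id": "p2", "pseudo": True},
            ],
        )
        records = parse_genbank(write_gbk(tmp_path, "a.gbk", gbk))
        assert [r.protein_id for r in records] == ["p1"]

    def test_unreadable_file_names_path(self, tmp_path):
        with pytest.raises(ParseError, match="missing.gbk"):
            parse_genbank(tmp_path / "missing.gbk")


class TestAggregateStrain:
    def make_strain(self, tmp_path, duplicate_ids=False):
        chrom = make_genbank(
            "CHR1", 60,
            [
                {"start": 1, "end": 12, "protein_id": "p1", "translation": "MKL"},
                {"start": 20, "end": 31, "protein_id": "p2", "translation": "MAD"},
            ],
        )
        plasmid_pid = "p1" if duplicate_ids else "p3"
        plasmid = make_genbank("PLS1", 24, [{"start": 1, "end": 12, "protein_id": plasmid_pid, "translation": "MKV"}])
        return StrainManifest(
            genome_id="strainX",
            replicon_files=[write_gbk(tmp_path, "chr.gbk", chrom), write_gbk(tmp_path, "pls.gbk", plasmid)],
        )

    def test_replicons_concatenate_under_one_genome(self, tmp_path):
        records = aggregate_strain(self.make_strain(tmp_path))
        assert len(records) == 3
        assert {r.genome_id for r in records} == {"strainX"}
        assert {r.replicon_id for r in records} == {"CHR1.1", "PLS1.1"}

    def test_single_file_manifest_matches_parse_genbank(self, tmp_path):
        gbk = make_genbank("REP1", 60, [{"start": 1, "end": 12, "protein_id": "p1", "translation": "MKL"}])
        path = write_gbk(tmp_path, "a.gbk", gbk)
        manifest = StrainManifest(genome_id="s1", replicon_files=[path])
        direct = parse_genbank(path, genome_id="s1")
        assert aggregate_strain(manifest) == direct

    def test_duplicate_protein_ids_get_replicon_prefix(self, tmp_path):
        records = aggregate_strain(self.make_strain(tmp_path, duplicate_ids=True))
        ids = sorted(r.protein_id for r in records)
        assert ids == ["CHR1.1:p1", "PLS1.1:p1", "p2"]

    def test_aggregation_order_insensitive(self, tmp_path):
        manifest = self.make_strain(tmp_path)
        reversed_manifest = StrainManifest(
            genome_id="strainX", replicon_files=list(reversed(manifest.replicon_files))
        )
        a = aggregate_strain(manifest)
        b = aggregate_strain(reversed_manifest)
        key = lambda r: (r.replicon_id, r.protein_id)
        assert sorted(a, key=key) == sorted(b, key=key)

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValidationError, match="no replicon files"):
            StrainManifest(genome_id="s", replicon_files=[])

    def test_manifest_tsv_reader(self, tmp_path):
        manifest = self.make_strain(tmp_path)
        tsv = tmp_path / "manifest.tsv"
        tsv.write_text("strainX\tchr.gbk\nstrainX\tpls.gbk\n")
        (loaded,) = read_manifest(tsv)
        assert loaded.genome_id == "strainX"
        assert len(aggregate_strain(loaded)) == 3


class TestFaaRoundTrip:
    def test_single_record_single_header(self, tmp_path):
        gbk = make_genbank("REP1", 60, [{"start": 1, "end": 12, "protein_id": "p1", "translation": "MKL"}])
        records = parse_genbank(write_gbk(tmp_path, "a.gbk", gbk))
        out = write_faa(records, tmp_path / "out.faa")
        lines = out.read_text().splitlines()
        assert sum(1 for ln in lines if ln.startswith(">")) == 1

    def test_sequences_wrap_at_sixty_columns(self, tmp_path):
        gbk = make_genbank("REP1", 300, [{"start": 1, "end": 297, "protein_id": "p1", "translation": "M" * 98}])
        records = parse_genbank(write_gbk(tmp_path, "a.gbk", gbk))
        out = write_faa(records, tmp_path / "out.faa")
        seq_lines = [ln for ln in out.read_text().splitlines() if not ln.startswith(">")]
        assert [len(ln) for ln in seq_lines] == [60, 38]

    def test_empty_record_list_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_faa([], tmp_path / "out.faa")

    def test_round_trip_preserves_identity_triples(self, tmp_path):
        chrom = make_genbank(
            "CHR1", 120,
            [
                {"start": 1, "end": 12, "protein_id": "p1", "translation": "MKL"},
                {"start": 20, "end": 31, "strand": "-", "protein_id": "p2", "translation": "MADKLLVV"},
            ],
        )
        records = parse_genbank(write_gbk(tmp_path, "chr.gbk", chrom), genome_id="strainX")
        out = write_faa(records, tmp_path / "x.faa")
        reread = read_faa(out)
        triples = lambda recs: sorted((r.protein_id, r.genome_id, r.aa_length) for r in recs)
        assert triples(reread) == triples(records)
        assert sorted(r.aa_sequence for r in reread) == sorted(r.aa_sequence for r in records)
        assert {(r.nt_start, r.nt_end, r.strand) for r in reread} == {(1, 12, "+"), (20, 31, "-")}
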