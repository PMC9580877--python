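import textwrap

import pytest

from celluclass.catalog import load_catalog
from celluclass.cazy_ingest import GeneRecord, ModuleHit


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def make_genbank(replicon_id, length_bp, cds_specs, sequence=None):
    """Minimal GenBank flat-file text.

    ``cds_specs``: list of dicts with keys start, end, strand ('+'/'-'),
    and optional protein_id, translation, pseudo.
    """
    if sequence is None:
        sequence = ("atgaaactgtaa" * (length_bp // 12 + 1))[:length_bp]
    lines = [
        f"LOCUS       {replicon_id:<16} {length_bp:>11} bp    DNA     linear   BCT 01-JAN-2020",
        "DEFINITION  synthetic test replicon.",
        f"ACCESSION   {replicon_id}",
        f"VERSION     {replicon_id}.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{length_bp}",
    ]
    for spec in cds_specs:
        loc = f"{spec['start']}..{spec['end']}"
        if spec.get("strand", "+") == "-":
            loc = f"complement({loc})"
        lines.append(f"     CDS             {loc}")
        if "protein_id" in spec:
            lines.append(f"                     /protein_id=\"{spec['protein_id']}\"")
        if spec.get("pseudo"):
            lines.append("                     /pseudo")
        if "translation" in spec:
            lines.append(f"                     /translation=\"{spec['translation']}\"")
    lines.append("ORIGIN")
    for i in range(0, len(sequence), 60):
        chunk = sequence[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def make_gene(families, protein_id="g1", genome_id="G1", aa_length=None, module_len=50, gap=10):
    """GeneRecord with sequential non-overlapping module coordinates."""
    hits = []
    cursor = 1
    for family in families:
        hits.append(
            ModuleHit(
                family=family,
                protein_id=protein_id,
                genome_id=genome_id,
                aa_start=cursor,
                aa_end=cursor + module_len - 1,
                e_value=1e-30,
                hmm_coverage=0.9,
            )
        )
        cursor += module_len + gap
    if aa_length is None:
        aa_length = cursor + 20
    return GeneRecord(protein_id=protein_id, genome_id=genome_id, hits=hits, aa_length=aa_length)
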