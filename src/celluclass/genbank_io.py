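"""Protein extraction from GenBank flat files and per-strain aggregation.

Complete prokaryote genomes typically ship one GenBank file per replicon
(chromosome plus plasmids).  This module extracts the amino-acid sequence of
every CDS feature, aggregates replicons under one strain identifier, and
round-trips the result through amino-acid FASTA whose headers keep the
provenance (genome, replicon, coordinates) in a parseable layout:

    >{genome_id}|{protein_id} replicon={replicon_id} loc={start}..{end}({strand})

CDS features lacking a ``/translation`` qualifier are translated from the
nucleotide span with translation table 11 (bacterial) and a trailing stop
trimmed; features flagged ``/pseudo`` are skipped and logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from celluclass.errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

FASTA_WRAP = 60

_HEADER_RE = re.compile(
    r"^(?P<genome>[^|\s]+)\|(?P<protein>\S+)"
    r"(?:\s+replicon=(?P<replicon>\S+))?"
    r"(?:\s+loc=(?P<start>\d+)\.\.(?P<end>\d+)\((?P<strand>[+-])\))?"
)


@dataclass
class ProteinRecord:
    """One protein-coding gene product with its genomic provenance."""

    protein_id: str
    genome_id: str
    replicon_id: str
    aa_sequence: str
    nt_start: int
    nt_end: int
    strand: str
    multi_segment: bool = False

    def __post_init__(self):
        if not self.aa_sequence:
            raise ValidationError(f"protein {self.protein_id}: empty amino-acid sequence")
        if self.nt_start > self.nt_end:
            raise ValidationError(f"protein {self.protein_id}: nt_start > nt_end")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"protein {self.protein_id}: strand must be + or -")

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)


@dataclass
class StrainManifest:
    """One strain's replicon files plus optional free-form metadata."""

    genome_id: str
    replicon_files: list[Path]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.replicon_files:
            raise ValidationError(f"strain {self.genome_id}: manifest lists no replicon files")
        self.replicon_files = [Path(p) for p in self.replicon_files]


def _feature_protein_id(feature, index: int) -> str:
    for key in ("protein_id", "locus_tag", "gene"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return f"cds_{index}"


def _extract_cds(feature, seqrecord, genome_id: str, index: int) -> ProteinRecord | None:
    if "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers:
        logger.info("skipping pseudo CDS %s in %s", _feature_protein_id(feature, index), seqrecord.id)
        return None
    location = feature.location
    nt_start = int(location.start) + 1  # GenBank 1-based inclusive
    nt_end = int(location.end)
    strand = "-" if location.strand == -1 else "+"
    multi = len(getattr(location, "parts", [location])) > 1

    if "translation" in feature.qualifiers:
        aa = feature.qualifiers["translation"][0]
    else:
        nt = feature.extract(seqrecord.seq)
        aa = str(Seq(nt).translate(table=11))
        if aa.endswith("*"):
            aa = aa[:-1]
        if not aa or "*" in aa:
            logger.info("skipping untranslatable CDS at %s..%s in %s", nt_start, nt_end, seqrecord.id)
            return None
    return ProteinRecord(
        protein_id=_feature_protein_id(feature, index),
        genome_id=genome_id,
        replicon_id=seqrecord.id,
        aa_sequence=aa,
        nt_start=nt_start,
        nt_end=nt_end,
        strand=strand,
        multi_segment=multi,
    )


def parse_genbank(path: str | Path, genome_id: str | None = None) -> list[ProteinRecord]:
    """Extract one :class:`ProteinRecord` per translated CDS feature.

    ``genome_id`` defaults to the file stem.  Records are ordered by
    replicon then nucleotide start.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    try:
        handle = path.open()
    except OSError as exc:
        raise ParseError(f"cannot read GenBank file {path}: {exc}") from exc
    records: list[ProteinRecord] = []
    with handle:
        try:
            for seqrecord in SeqIO.parse(handle, "genbank"):
                index = 0
                replicon_records = []
                for feature in seqrecord.features:
                    if feature.type != "CDS":
                        continue
                    index += 1
                    rec = _extract_cds(feature, seqrecord, genome_id, index)
                    if rec is not None:
                        replicon_records.append(rec)
                replicon_records.sort(key=lambda r: (r.nt_start, r.nt_end, r.protein_id))
                records.extend(replicon_records)
        except ValueError as exc:
            raise ParseError(f"malformed GenBank record in {path}: {exc}") from exc
    return records


def aggregate_strain(manifest: StrainManifest) -> list[ProteinRecord]:
    """Concatenate per-replicon proteins under one genome_id.

    Protein-id collisions across replicons are resolved deterministically by
    prefixing the colliding ids with their replicon id.
    """
    per_replicon: list[list[ProteinRecord]] = []
    for path in sorted(manifest.replicon_files):
        recs = parse_genbank(path, genome_id=manifest.genome_id)
        per_replicon.append(recs)

    seen: dict[str, int] = {}
    for recs in per_replicon:
        for r in recs:
            seen[r.protein_id] = seen.get(r.protein_id, 0) + 1
    colliding = {pid for pid, count in seen.items() if count > 1}

    merged: list[ProteinRecord] = []
    for recs in per_replicon:
        for r in recs:
            if r.protein_id in colliding:
                r.protein_id = f"{r.replicon_id}:{r.protein_id}"
            merged.append(r)
    return merged


def write_faa(records: Iterable[ProteinRecord], path: str | Path) -> Path:
    """Write records as 60-column-wrapped amino-acid FASTA (see module
    docstring for the header layout)."""
    records = list(records)
    if not records:
        raise ValidationError("write_faa requires at least one record")
    path = Path(path)
    seqs = [
        SeqRecord(
            Seq(r.aa_sequence),
            id=f"{r.genome_id}|{r.protein_id}",
            description=f"replicon={r.replicon_id} loc={r.nt_start}..{r.nt_end}({r.strand})",
        )
        for r in records
    ]
    try:
        with path.open("w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_WRAP)
            writer.write_file(seqs)
    except OSError as exc:
        raise ParseError(f"cannot write FASTA to {path}: {exc}") from exc
    return path


def read_faa(path: str | Path) -> list[ProteinRecord]:
    """Re-ingest a FASTA written by :func:`write_faa`."""
    records: list[ProteinRecord] = []
    for seq in SeqIO.parse(str(path), "fasta"):
        header = seq.description
        match = _HEADER_RE.match(header)
        if not match:
            raise ParseError(f"FASTA header {header!r} does not follow the genome|protein layout")
        aa = str(seq.seq)
        records.append(
            ProteinRecord(
                protein_id=match["protein"],
                genome_id=match["genome"],
                replicon_id=match["replicon"] or match["genome"],
                aa_sequence=aa,
                nt_start=int(match["start"]) if match["start"] else 1,
                nt_end=int(match["end"]) if match["end"] else max(3 * len(aa), 1),
                strand=match["strand"] or "+",
            )
        )
    return records


def read_manifest(path: str | Path) -> list[StrainManifest]:
    """Load strain manifests from a 2-column TSV (genome_id, file path) or a
    YAML list of ``{genome_id, replicon_files, metadata?}`` entries."""
    path = Path(path)
    base = path.parent
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        return [
            StrainManifest(
                genome_id=entry["genome_id"],
                replicon_files=[base / p for p in entry["replicon_files"]],
                metadata=entry.get("metadata", {}),
            )
            for entry in data
        ]
    groups: dict[str, list[Path]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"manifest line {lineno}: expected genome_id<TAB>path")
        groups.setdefault(parts[0], []).append(base / parts[1])
    return [StrainManifest(genome_id=g, replicon_files=files) for g, files in groups.items()]
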