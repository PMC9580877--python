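"""Ingest of dbCAN-style HMM search tables into per-gene module architectures.

The pipeline consumes the tabular output of a dbCAN HMM search (it never runs
the search itself).  Rows become :class:`ModuleHit` records; hits are score-
filtered, then grouped per protein into :class:`GeneRecord` architectures
ordered along the protein, which are the unit every downstream rule reads.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from celluclass.catalog import normalize_family
from celluclass.errors import ConfigurationError, ParseError, ValidationError

DIALECTS = ("hmmscan-parser", "overview")

GENE_TSV_COLUMNS = [
    "genome_id",
    "protein_id",
    "aa_length",
    "family",
    "aa_start",
    "aa_end",
    "e_value",
    "hmm_coverage",
]


@dataclass(frozen=True)
class ModuleHit:
    """One CAZy/accessory module occurrence on a protein."""

    family: str
    protein_id: str
    genome_id: str
    aa_start: int
    aa_end: int
    e_value: float
    hmm_coverage: float

    def __post_init__(self):
        if self.aa_start > self.aa_end:
            raise ValidationError(
                f"hit {self.family} on {self.protein_id}: aa_start {self.aa_start} > aa_end {self.aa_end}"
            )
        if self.e_value < 0:
            raise ValidationError(f"hit {self.family} on {self.protein_id}: negative e-value")
        if not 0 <= self.hmm_coverage <= 1:
            raise ValidationError(
                f"hit {self.family} on {self.protein_id}: coverage {self.hmm_coverage} outside [0,1]"
            )
        if not self.family:
            raise ValidationError(f"empty family label on {self.protein_id}")

    @property
    def span(self) -> int:
        return self.aa_end - self.aa_start + 1


@dataclass
class GeneRecord:
    """A protein-coding gene with its ordered module architecture."""

    protein_id: str
    genome_id: str
    hits: list[ModuleHit] = field(default_factory=list)
    aa_length: int | None = None
    replicon_id: str | None = None

    @property
    def families(self) -> list[str]:
        """Module labels in N-to-C order."""
        return [h.family for h in self.hits]


@dataclass(frozen=True)
class FilterThresholds:
    """Score cutoffs applied to raw HMM hits.

    Defaults follow the commonly recommended dbCAN HMM criteria
    (E-value <= 1e-15, HMM coverage >= 0.35) and are fully configurable.
    """

    max_e_value: float = 1e-15
    min_hmm_coverage: float = 0.35
    same_family_overlap_policy: str = "best_per_region"

    def __post_init__(self):
        if self.max_e_value <= 0:
            raise ConfigurationError("max_e_value must be positive")
        if not 0 <= self.min_hmm_coverage <= 1:
            raise ConfigurationError("min_hmm_coverage must lie in [0,1]")
        if self.same_family_overlap_policy not in ("keep_all", "best_per_region"):
            raise ConfigurationError(
                f"unknown overlap policy {self.same_family_overlap_policy!r}"
            )


def _parse_hmmscan_row(fields: list[str], genome_id: str, lineno: int) -> ModuleHit:
    # 10 columns: HMM name, HMM length, query name, query length, E-value,
    # HMM start, HMM end, query start, query end, coverage
    if len(fields) < 10:
        raise ParseError(f"line {lineno}: expected 10 tab-separated columns, got {len(fields)}")
    try:
        return ModuleHit(
            family=normalize_family(fields[0]),
            protein_id=fields[2],
            genome_id=genome_id,
            aa_start=int(fields[7]),
            aa_end=int(fields[8]),
            e_value=float(fields[4]),
            hmm_coverage=float(fields[9]),
        )
    except (ValueError, ValidationError) as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def _parse_overview_rows(lines: list[str], genome_id: str) -> list[ModuleHit]:
    # first column gene id, remaining columns per annotation tool, families
    # joined by "+"; scores and coordinates are absent so hits are treated as
    # passing and given ordinal coordinates that preserve listed order
    hits: list[ModuleHit] = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.rstrip("\n").split("\t")
        if lineno == 1 and fields and fields[0].lower() in {"gene id", "gene_id", "#gene id"}:
            continue
        protein_id = fields[0]
        position = 0
        for cell in fields[1:]:
            cell = cell.strip()
            if not cell or cell in {"-", "N"}:
                continue
            for token in cell.split("+"):
                token = token.split("(")[0].strip()  # strip "(count)" decorations
                if not token:
                    continue
                position += 1
                hits.append(
                    ModuleHit(
                        family=normalize_family(token),
                        protein_id=protein_id,
                        genome_id=genome_id,
                        aa_start=position,
                        aa_end=position,
                        e_value=0.0,
                        hmm_coverage=1.0,
                    )
                )
    return hits


def parse_dbcan_table(
    path: str | Path, dialect: str = "hmmscan-parser", genome_id: str | None = None
) -> list[ModuleHit]:
    """Parse a dbCAN result table into :class:`ModuleHit` records.

    ``genome_id`` defaults to the file stem, matching the one-table-per-genome
    layout dbCAN batch runs produce.  Family labels are normalized (``.hmm``
    suffix stripped, structural-module aliases canonicalized).
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if genome_id is None:
        genome_id = path.stem
    try:
        text = path.read_text()
    except OSError as exc:
        raise ParseError(f"cannot read dbCAN table {path}: {exc}") from exc

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if dialect == "overview":
        return _parse_overview_rows(lines, genome_id)
    return [
        _parse_hmmscan_row(ln.rstrip("\n").split("\t"), genome_id, lineno)
        for lineno, ln in enumerate(lines, start=1)
    ]


def _overlap_majority(a: ModuleHit, b: ModuleHit) -> bool:
    """True when the residue intervals overlap by more than half of the
    shorter interval."""
    overlap = min(a.aa_end, b.aa_end) - max(a.aa_start, b.aa_start) + 1
    return overlap > min(a.span, b.span) / 2


def filter_hits(hits: Iterable[ModuleHit], thresholds: FilterThresholds | None = None) -> list[ModuleHit]:
    """Apply score cutoffs and (optionally) same-family overlap resolution.

    Under ``best_per_region``, among same-protein same-family hits whose
    intervals overlap by more than half of the shorter interval, only the
    lowest-E-value hit survives (ties broken by smaller start).  The
    operation is idempotent.
    """
    thresholds = thresholds or FilterThresholds()
    passing = [
        h
        for h in hits
        if h.e_value <= thresholds.max_e_value and h.hmm_coverage >= thresholds.min_hmm_coverage
    ]
    if thresholds.same_family_overlap_policy == "keep_all":
        return passing

    by_group: dict[tuple[str, str, str], list[ModuleHit]] = defaultdict(list)
    for h in passing:
        by_group[(h.genome_id, h.protein_id, h.family)].append(h)

    kept: list[ModuleHit] = []
    for group in by_group.values():
        group.sort(key=lambda h: (h.e_value, h.aa_start, h.aa_end))
        accepted: list[ModuleHit] = []
        for cand in group:
            if not any(_overlap_majority(cand, acc) for acc in accepted):
                accepted.append(cand)
        kept.extend(accepted)
    # preserve the deterministic overall order of the passing list
    kept_set = {id(h) for h in kept}
    return [h for h in passing if id(h) in kept_set]


def build_genes(
    hits: Iterable[ModuleHit],
    proteins: Sequence | None = None,
) -> list[GeneRecord]:
    """Group filtered hits by (genome, protein) into gene architectures.

    ``proteins`` is an optional sequence of objects with ``genome_id``,
    ``protein_id``, ``aa_length`` (and optionally ``replicon_id``) used to
    attach protein lengths; a hit whose coordinates exceed the supplied
    length is a validation error.  Genes without hits are not emitted.
    """
    lengths: dict[tuple[str, str], int] = {}
    replicons: dict[tuple[str, str], str | None] = {}
    if proteins is not None:
        for p in proteins:
            key = (p.genome_id, p.protein_id)
            lengths[key] = p.aa_length
            replicons[key] = getattr(p, "replicon_id", None)

    grouped: dict[tuple[str, str], list[ModuleHit]] = defaultdict(list)
    for h in hits:
        grouped[(h.genome_id, h.protein_id)].append(h)

    genes: list[GeneRecord] = []
    for (genome_id, protein_id) in sorted(grouped):
        gene_hits = sorted(grouped[(genome_id, protein_id)], key=lambda h: (h.aa_start, h.aa_end, h.family))
        aa_length = lengths.get((genome_id, protein_id))
        if aa_length is not None:
            for h in gene_hits:
                if h.aa_end > aa_length:
                    raise ValidationError(
                        f"hit {h.family} at {h.aa_start}-{h.aa_end} exceeds length "
                        f"{aa_length} of protein {protein_id} ({genome_id})"
                    )
        genes.append(
            GeneRecord(
                protein_id=protein_id,
                genome_id=genome_id,
                hits=gene_hits,
                aa_length=aa_length,
                replicon_id=replicons.get((genome_id, protein_id)),
            )
        )
    return genes


def module_abundance(genes: Iterable[GeneRecord]) -> dict[str, Counter]:
    """Per-genome counts of module occurrences.

    The counting unit is the module occurrence: a family hit twice in one
    gene counts twice.  Genomes with zero hits are absent from the map.
    """
    abundance: dict[str, Counter] = defaultdict(Counter)
    for gene in genes:
        for hit in gene.hits:
            abundance[gene.genome_id][hit.family] += 1
    return dict(abundance)


def genes_to_frame(genes: Iterable[GeneRecord]) -> pd.DataFrame:
    """Flatten gene architectures to a one-row-per-hit table (stable schema,
    re-ingestable via :func:`genes_from_frame`)."""
    rows = []
    for gene in genes:
        for h in gene.hits:
            rows.append(
                {
                    "genome_id": gene.genome_id,
                    "protein_id": gene.protein_id,
                    "aa_length": gene.aa_length if gene.aa_length is not None else -1,
                    "family": h.family,
                    "aa_start": h.aa_start,
                    "aa_end": h.aa_end,
                    "e_value": h.e_value,
                    "hmm_coverage": h.hmm_coverage,
                }
            )
    return pd.DataFrame(rows, columns=GENE_TSV_COLUMNS)


def genes_from_frame(frame: pd.DataFrame) -> list[GeneRecord]:
    """Rebuild :class:`GeneRecord` objects from a :func:`genes_to_frame` table."""
    missing = set(GENE_TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"gene table lacks columns {sorted(missing)}")
    hits = [
        ModuleHit(
            family=str(row.family),
            protein_id=str(row.protein_id),
            genome_id=str(row.genome_id),
            aa_start=int(row.aa_start),
            aa_end=int(row.aa_end),
            e_value=float(row.e_value),
            hmm_coverage=float(row.hmm_coverage),
        )
        for row in frame.itertuples()
    ]

    class _Len:
        __slots__ = ("genome_id", "protein_id", "aa_length")

        def __init__(self, g, p, n):
            self.genome_id, self.protein_id, self.aa_length = g, p, n

    lengths = [
        _Len(str(row.genome_id), str(row.protein_id), int(row.aa_length))
        for row in frame.itertuples()
        if int(row.aa_length) > 0
    ]
    return build_genes(hits, proteins=lengths or None)


def write_gene_tsv(genes: Iterable[GeneRecord], path: str | Path) -> Path:
    path = Path(path)
    genes_to_frame(genes).to_csv(path, sep="\t", index=False)
    return path


def read_gene_tsv(path: str | Path) -> list[GeneRecord]:
    frame = pd.read_csv(
        path, sep="\t",
        dtype={"genome_id": str, "protein_id": str, "family": str},
        float_precision="round_trip",
    )
    return genes_from_frame(frame)
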