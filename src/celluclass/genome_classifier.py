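"""Genome-level genotype classification of putative cellulolytic anaerobes.

A genome's typed genes are summarized to per-type counts and two role flags
(presence of exoglucanase and endoglucanase GH modules anywhere in the
genome), then routed through a sequential decision flow:

1. no CAZy modules annotated at all            -> NO_CAZY
2. not (exoglucanase AND endoglucanase)        -> Group II
3. adhering scaffoldin (A1, or A2-a + A2-b)    -> Group I-a
4. free scaffoldin (A3, or unpaired A2-a):
       SLH-cCBM gene (B) present               -> Group I-b
       otherwise                               -> Group I-c
5. B gene present (no scaffoldin)              -> Group I-d
6. cGH-cCBM gene (C) present                   -> Group I-e
7. otherwise                                   -> Group I-f

Groups I-a..I-c carry cellulosome gene clusters; I-a's complex can anchor to
the cell surface, I-b's cannot but the genome encodes SLH-cCBM adhesion
proteins that may still sandwich cell, enzymes and substrate, and I-c's
cellulosome is likely truly free.  I-d..I-f lack cellulosomes and are ranked
by the remaining synergy machinery (adhesion proteins, then enzyme-borne
cellulose binding, then none).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from celluclass.catalog import ModuleCatalog, roles_of
from celluclass.errors import ValidationError
from celluclass.gene_typing import GeneTypeProfile

GROUP_LABELS = ("I-a", "I-b", "I-c", "I-d", "I-e", "I-f", "II", "NO_CAZY")

TYPE_COUNT_FIELDS = {
    "A1": "n_A1",
    "A2-a": "n_A2a",
    "A2-b": "n_A2b",
    "A3": "n_A3",
    "A-s": "n_As",
    "B": "n_B",
    "C": "n_C",
    "D": "n_D",
}


@dataclass
class GenomeProfile:
    """Per-genome gene-type counts, role flags and module abundances."""

    genome_id: str
    n_A1: int = 0
    n_A2a: int = 0
    n_A2b: int = 0
    n_A3: int = 0
    n_As: int = 0
    n_B: int = 0
    n_C: int = 0
    n_D: int = 0
    has_exo: bool = False
    has_endo: bool = False
    module_abundance: Counter = field(default_factory=Counter)


def summarize_genome(
    profiles: Iterable[GeneTypeProfile],
    abundance: Mapping[str, int] | None,
    catalog: ModuleCatalog,
    genome_id: str | None = None,
) -> GenomeProfile:
    """Aggregate typed genes of one genome into a :class:`GenomeProfile`.

    Type counts are tallied by each gene's ``primary_type``, so a gene whose
    primary label is cellulosomal (A1/A2-a/A2-b/A-s) never inflates the
    non-cellulosome B/C/D tallies even when it satisfies their predicates.
    ``has_exo``/``has_endo`` are computed from the genome-wide module
    abundance, not only from typed genes.
    """
    profiles = list(profiles)
    genome_ids = {p.genome_id for p in profiles}
    if len(genome_ids) > 1:
        raise ValidationError(f"summarize_genome received mixed genome ids: {sorted(genome_ids)}")
    if genome_id is None:
        if not genome_ids:
            raise ValidationError("genome_id required when the profile list is empty")
        genome_id = genome_ids.pop()
    elif genome_ids and genome_ids != {genome_id}:
        raise ValidationError(f"profiles belong to {genome_ids.pop()}, not {genome_id}")

    genome = GenomeProfile(genome_id=genome_id, module_abundance=Counter(abundance or {}))
    for p in profiles:
        if p.primary_type is not None:
            attr = TYPE_COUNT_FIELDS[p.primary_type]
            setattr(genome, attr, getattr(genome, attr) + 1)
    for family, count in genome.module_abundance.items():
        if count <= 0:
            continue
        roles = roles_of(family, catalog)
        if "exo" in roles:
            genome.has_exo = True
        if "endo" in roles:
            genome.has_endo = True
    return genome


def has_adhering_scaffold(profile: GenomeProfile, a2_requires_pair: bool = True) -> bool:
    """True when the genome can build a cell-surface-anchored scaffoldin.

    A1 scaffoldins carry SLH directly; the A2 route requires both the
    dockerin-tailed backbone (A2-a) and the SLH carrier (A2-b) whose
    cohesin-dockerin pairing assembles SLH onto the backbone.  With
    ``a2_requires_pair=False`` an A2-a backbone alone counts as adhering.
    """
    if profile.n_A1 >= 1:
        return True
    if a2_requires_pair:
        return profile.n_A2a >= 1 and profile.n_A2b >= 1
    return profile.n_A2a >= 1


def _has_free_scaffold(profile: GenomeProfile, a2_requires_pair: bool) -> bool:
    if profile.n_A3 >= 1:
        return True
    # an A2-a backbone with no A2-b partner cannot acquire SLH: free scaffold
    return a2_requires_pair and profile.n_A2a >= 1 and profile.n_A2b == 0


def classify_genome(
    profile: GenomeProfile, a2_requires_pair: bool = True
) -> tuple[str, list[str]]:
    """Assign the genotype group label; returns ``(label, decision_path)``.

    The decision path lists the predicates evaluated in order with their
    outcomes, for traceable reports.
    """
    path: list[str] = []
    if sum(profile.module_abundance.values()) == 0:
        path.append("no CAZy modules annotated")
        return "NO_CAZY", path

    both = profile.has_exo and profile.has_endo
    path.append(f"exoglucanase and endoglucanase modules present: {'yes' if both else 'no'}")
    if not both:
        return "II", path

    adhering = has_adhering_scaffold(profile, a2_requires_pair)
    path.append(f"adhering scaffoldin (A1 or paired A2): {'yes' if adhering else 'no'}")
    if adhering:
        return "I-a", path

    free_scaffold = _has_free_scaffold(profile, a2_requires_pair)
    path.append(f"free scaffoldin (A3 or unpaired A2-a): {'yes' if free_scaffold else 'no'}")
    has_b = profile.n_B >= 1
    if free_scaffold:
        path.append(f"SLH-cCBM (B) gene present: {'yes' if has_b else 'no'}")
        return ("I-b" if has_b else "I-c"), path

    path.append(f"SLH-cCBM (B) gene present: {'yes' if has_b else 'no'}")
    if has_b:
        return "I-d", path
    has_c = profile.n_C >= 1
    path.append(f"cGH-cCBM (C) gene present: {'yes' if has_c else 'no'}")
    if has_c:
        return "I-e", path
    return "I-f", path


def profile_corpus(
    genes,
    catalog: ModuleCatalog,
    genome_ids: Iterable[str] | None = None,
    strict_as: bool = True,
) -> list[GenomeProfile]:
    """Type a corpus of :class:`~celluclass.cazy_ingest.GeneRecord` objects
    and summarize per genome.

    ``genome_ids`` optionally names the full genome universe; genomes listed
    there but absent from the annotation output get an empty profile (and
    classify as NO_CAZY), mirroring corpora where some genomes yield no
    CAZyme hit at all.
    """
    from celluclass.cazy_ingest import module_abundance
    from celluclass.gene_typing import type_genes

    genes = list(genes)
    abundance = module_abundance(genes)
    profiles = type_genes(genes, catalog, strict_as=strict_as)
    by_genome: dict[str, list[GeneTypeProfile]] = {}
    for p in profiles:
        by_genome.setdefault(p.genome_id, []).append(p)

    universe = list(genome_ids) if genome_ids is not None else sorted(by_genome)
    for gid in by_genome:
        if gid not in universe:
            universe.append(gid)
    return [
        summarize_genome(by_genome.get(gid, []), abundance.get(gid, {}), catalog, genome_id=gid)
        for gid in universe
    ]


def batch_classify(
    corpus: Iterable[GenomeProfile], a2_requires_pair: bool = True
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every genome; returns the per-genome table and a per-group
    membership summary.  No genome is silently dropped."""
    rows = []
    summary: Counter = Counter()
    for profile in corpus:
        label, path = classify_genome(profile, a2_requires_pair)
        summary[label] += 1
        rows.append(
            {
                "genome_id": profile.genome_id,
                "group": label,
                "n_A1": profile.n_A1,
                "n_A2a": profile.n_A2a,
                "n_A2b": profile.n_A2b,
                "n_A3": profile.n_A3,
                "n_As": profile.n_As,
                "n_B": profile.n_B,
                "n_C": profile.n_C,
                "n_D": profile.n_D,
                "has_exo": profile.has_exo,
                "has_endo": profile.has_endo,
                "decision_path": " -> ".join(path),
            }
        )
    columns = [
        "genome_id", "group", "n_A1", "n_A2a", "n_A2b", "n_A3", "n_As",
        "n_B", "n_C", "n_D", "has_exo", "has_endo", "decision_path",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return table, {label: summary.get(label, 0) for label in GROUP_LABELS if summary.get(label, 0)}
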