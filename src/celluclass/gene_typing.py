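"""Rule-based typing of carbohydrate-active genes from module-count profiles.

Each gene is reduced to five role counts — SLH, dockerin, cohesin, cGH
(cellulolytic GH/LPMO) and cCBM (cellulose-binding CBM) occurrences — and
evaluated against eight architecture predicates:

=====  ==========================================  ==================================
type   predicate                                   product
=====  ==========================================  ==================================
A1     slh>=1 and doc=0 and coh>=3                 cell-anchored scaffoldin
A2-a   doc>=1 and coh>=3                           scaffoldin with a dockerin tail
A2-b   slh>=1 and coh>=1                           SLH carrier assembled onto A2-a
A3     slh=0 and doc=0 and coh>=3                  free (non-anchored) scaffoldin
A-s    doc>=1 and cgh>=1                           cellulosomal catalytic subunit
B      slh>=1 and ccbm>=1                          microbe-cellulose adhesion protein
C      cgh>=1 and ccbm>=1                          cellulose-binding cellulase
D      cgh>=1 and ccbm=0                           free ("solitude") cellulase
=====  ==========================================  ==================================

Scaffold predicates overlap by construction, so a precedence ladder
A1 > A2-a > A2-b > A3 retains only the highest scaffold label; the
non-scaffold labels are kept multi-label.  ``primary_type`` is the first
satisfied label in the order A1, A2-a, A2-b, A3, A-s, B, C, D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from celluclass.catalog import ModuleCatalog, roles_of
from celluclass.cazy_ingest import GeneRecord

GENE_TYPES = ("A1", "A2-a", "A2-b", "A3", "A-s", "B", "C", "D")
SCAFFOLD_TYPES = ("A1", "A2-a", "A2-b", "A3")
CELLULOSOMAL_TYPES = ("A1", "A2-a", "A2-b", "A-s")


@dataclass
class GeneTypeProfile:
    """Per-gene role counts and the assigned architecture type(s)."""

    protein_id: str
    genome_id: str
    n_slh: int = 0
    n_dockerin: int = 0
    n_cohesin: int = 0
    n_cgh: int = 0
    n_ccbm: int = 0
    satisfied_types: frozenset[str] = field(default_factory=frozenset)
    primary_type: str | None = None

    def counts(self) -> tuple[int, int, int, int, int]:
        return (self.n_slh, self.n_dockerin, self.n_cohesin, self.n_cgh, self.n_ccbm)


def profile_gene(gene: GeneRecord, catalog: ModuleCatalog) -> GeneTypeProfile:
    """Tally role occurrences of a gene's modules under ``catalog``.

    Families with no catalog role contribute nothing.  A promiscuous family
    carrying several GH roles still counts once toward cGH per occurrence.
    """
    profile = GeneTypeProfile(protein_id=gene.protein_id, genome_id=gene.genome_id)
    for hit in gene.hits:
        roles = roles_of(hit.family, catalog)
        if "slh" in roles:
            profile.n_slh += 1
        if "dockerin" in roles:
            profile.n_dockerin += 1
        if "cohesin" in roles:
            profile.n_cohesin += 1
        if "cgh" in roles:
            profile.n_cgh += 1
        if "ccbm" in roles:
            profile.n_ccbm += 1
    return profile


def _predicates(slh: int, doc: int, coh: int, cgh: int, ccbm: int, strict_as: bool = True) -> set[str]:
    satisfied: set[str] = set()
    if slh >= 1 and doc == 0 and coh >= 3:
        satisfied.add("A1")
    if doc >= 1 and coh >= 3:
        satisfied.add("A2-a")
    if slh >= 1 and coh >= 1:
        satisfied.add("A2-b")
    if slh == 0 and doc == 0 and coh >= 3:
        satisfied.add("A3")
    if strict_as:
        if doc >= 1 and cgh >= 1:
            satisfied.add("A-s")
    else:
        if doc >= 1 and (cgh >= 1 or ccbm >= 1):
            satisfied.add("A-s")
    if slh >= 1 and ccbm >= 1:
        satisfied.add("B")
    if cgh >= 1 and ccbm >= 1:
        satisfied.add("C")
    if cgh >= 1 and ccbm == 0:
        satisfied.add("D")
    return satisfied


def assign_types(profile: GeneTypeProfile, strict_as: bool = True) -> GeneTypeProfile:
    """Evaluate the eight predicates on a count profile and resolve precedence.

    ``strict_as`` selects the A-s reading ``doc>=1 and cgh>=1`` (default);
    the loose reading also admits a dockerin paired with only a cCBM.
    Returns the same profile with ``satisfied_types`` and ``primary_type``
    populated.
    """
    satisfied = _predicates(
        profile.n_slh, profile.n_dockerin, profile.n_cohesin, profile.n_cgh, profile.n_ccbm,
        strict_as=strict_as,
    )
    # scaffold precedence: keep only the highest-ranking scaffold label
    for scaffold in SCAFFOLD_TYPES:
        if scaffold in satisfied:
            satisfied -= set(SCAFFOLD_TYPES) - {scaffold}
            break
    profile.satisfied_types = frozenset(satisfied)
    profile.primary_type = next((t for t in GENE_TYPES if t in satisfied), None)
    return profile


def type_genes(
    genes: Iterable[GeneRecord], catalog: ModuleCatalog, strict_as: bool = True
) -> list[GeneTypeProfile]:
    """Profile and type every gene; the per-gene one-stop entry point."""
    return [assign_types(profile_gene(g, catalog), strict_as=strict_as) for g in genes]


def profiles_to_frame(profiles: Iterable[GeneTypeProfile]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": p.genome_id,
            "protein_id": p.protein_id,
            "n_slh": p.n_slh,
            "n_dockerin": p.n_dockerin,
            "n_cohesin": p.n_cohesin,
            "n_cgh": p.n_cgh,
            "n_ccbm": p.n_ccbm,
            "satisfied_types": ",".join(t for t in GENE_TYPES if t in p.satisfied_types),
            "primary_type": p.primary_type or "",
        }
        for p in profiles
    ]
    columns = [
        "genome_id", "protein_id", "n_slh", "n_dockerin", "n_cohesin",
        "n_cgh", "n_ccbm", "satisfied_types", "primary_type",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_type_tsv(profiles: Iterable[GeneTypeProfile], path: str | Path) -> Path:
    path = Path(path)
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)
    return path


def profiles_from_frame(frame: pd.DataFrame) -> list[GeneTypeProfile]:
    profiles = []
    for row in frame.itertuples():
        satisfied = frozenset(t for t in str(row.satisfied_types).split(",") if t in GENE_TYPES)
        primary = row.primary_type if isinstance(row.primary_type, str) and row.primary_type else None
        profiles.append(
            GeneTypeProfile(
                protein_id=str(row.protein_id),
                genome_id=str(row.genome_id),
                n_slh=int(row.n_slh),
                n_dockerin=int(row.n_dockerin),
                n_cohesin=int(row.n_cohesin),
                n_cgh=int(row.n_cgh),
                n_ccbm=int(row.n_ccbm),
                satisfied_types=satisfied,
                primary_type=primary,
            )
        )
    return profiles


def read_type_tsv(path: str | Path) -> list[GeneTypeProfile]:
    frame = pd.read_csv(
        path, sep="\t",
        dtype={"genome_id": str, "protein_id": str},
        keep_default_na=False,
    )
    return profiles_from_frame(frame)
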