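"""Module co-occurrence frequencies across a gene corpus.

For a focal module m, over all genes containing at least one m:

* ``N_m``  — total occurrences of m in those genes,
* ``n_i``  — total occurrences of partner module i in those genes,
* ``freq`` — ``100 * n_i / N_m`` percent.

Frequencies can exceed 100% when partner occurrences outnumber focal ones
(e.g. a single-GH9 gene carrying two CBM3 copies gives CBM3 a 200% row).
The heatmap rendering uses the ``log10(freq + 0.01)`` transform so that a
0% frequency maps to exactly -2.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from celluclass.catalog import ModuleCatalog, parent_family, roles_of
from celluclass.cazy_ingest import GeneRecord
from celluclass.errors import ValidationError


@dataclass
class CooccurrenceTable:
    """Co-occurrence statistics for a list of focal modules.

    ``freq`` and ``n`` are focal x partner DataFrames; ``N`` maps each focal
    module to its total occurrence count within focal-containing genes.
    Focal modules absent from the corpus keep ``N == 0`` and are listed in
    ``absent_focals``; their rows are all zero.
    """

    focal_modules: list[str]
    partners: list[str]
    N: dict[str, int]
    n: pd.DataFrame
    freq: pd.DataFrame
    absent_focals: list[str] = field(default_factory=list)


def _matches_focal(family: str, focal: str) -> bool:
    # focal labels are family-level; subfamily hits count toward the parent
    return family == focal or parent_family(family) == focal


def cooccurrence(
    genes: Iterable[GeneRecord],
    focal_modules: Sequence[str],
    include_self: bool = False,
) -> CooccurrenceTable:
    """Tally the co-occurrence table over ``genes`` for ``focal_modules``.

    Per focal module m: retrieve every gene with >=1 occurrence of m, count
    N_m = total m occurrences in those genes, n_i = total occurrences of each
    other module i in those genes, freq = 100*n_i/N_m.  Genes carrying two
    focal modules contribute independently to both rows.  With
    ``include_self`` the diagonal reports the extra-copy frequency
    ``100*(N_m - g_m)/N_m`` where g_m is the number of m-containing genes.
    """
    if not focal_modules:
        raise ValidationError("focal module list must be non-empty")
    genes = list(genes)

    partner_labels: set[str] = set()
    N: dict[str, int] = {}
    counts: dict[str, Counter] = {}
    gene_counts: dict[str, int] = {}

    for focal in focal_modules:
        focal_genes = [g for g in genes if any(_matches_focal(f, focal) for f in g.families)]
        n_focal = sum(1 for g in focal_genes for f in g.families if _matches_focal(f, focal))
        N[focal] = n_focal
        gene_counts[focal] = len(focal_genes)
        partner_counter: Counter = Counter()
        for g in focal_genes:
            for f in g.families:
                if _matches_focal(f, focal):
                    continue
                partner_counter[f] += 1
        counts[focal] = partner_counter
        partner_labels.update(partner_counter)

    partners = sorted(partner_labels)
    columns = list(partners)
    if include_self:
        columns = ["self"] + columns

    n_rows = []
    freq_rows = []
    for focal in focal_modules:
        row_n = []
        row_f = []
        if include_self:
            extra = N[focal] - gene_counts[focal]
            row_n.append(extra)
            row_f.append(100.0 * extra / N[focal] if N[focal] else 0.0)
        for p in partners:
            ni = counts[focal].get(p, 0)
            row_n.append(ni)
            row_f.append(100.0 * ni / N[focal] if N[focal] else 0.0)
        n_rows.append(row_n)
        freq_rows.append(row_f)

    index = pd.Index(list(focal_modules), name="focal")
    return CooccurrenceTable(
        focal_modules=list(focal_modules),
        partners=partners,
        N=N,
        n=pd.DataFrame(n_rows, index=index, columns=columns),
        freq=pd.DataFrame(freq_rows, index=index, columns=columns),
        absent_focals=[m for m in focal_modules if N[m] == 0],
    )


def heatmap_transform(freq: float) -> float:
    """Map a percentage to the heatmap scale ``log10(freq + 0.01)``."""
    if freq < 0:
        raise ValidationError(f"frequency must be non-negative, got {freq}")
    return math.log10(freq + 0.01)


def cgh_cbm_partnership_summary(
    genes: Iterable[GeneRecord], catalog: ModuleCatalog
) -> tuple[int, int, float | None]:
    """How often a gene pairing a cellulolytic GH with *some* CBM uses a
    cellulose-binding one.

    Returns ``(n_genes_with_cgh_and_cbm, n_of_those_with_ccbm, percent)``;
    the percentage is ``None`` when no gene carries both roles.
    """
    denominator = 0
    numerator = 0
    for gene in genes:
        has_cgh = False
        has_cbm = False
        has_ccbm = False
        for family in gene.families:
            roles = roles_of(family, catalog)
            if "cgh" in roles:
                has_cgh = True
            if parent_family(family).startswith("CBM"):
                has_cbm = True
                if "ccbm" in roles:
                    has_ccbm = True
        if has_cgh and has_cbm:
            denominator += 1
            if has_ccbm:
                numerator += 1
    fraction = 100.0 * numerator / denominator if denominator else None
    return denominator, numerator, fraction


def cooccurrence_long_frame(table: CooccurrenceTable) -> pd.DataFrame:
    """Long-format (focal, partner, N, n, freq) view of a co-occurrence table."""
    rows = []
    for focal in table.focal_modules:
        for partner in table.n.columns:
            rows.append(
                {
                    "focal": focal,
                    "partner": partner,
                    "N": table.N[focal],
                    "n": int(table.n.loc[focal, partner]),
                    "freq": float(table.freq.loc[focal, partner]),
                }
            )
    return pd.DataFrame(rows, columns=["focal", "partner", "N", "n", "freq"])


def write_cooccurrence_tsv(table: CooccurrenceTable, long_path: str | Path, wide_path: str | Path | None = None):
    cooccurrence_long_frame(table).to_csv(long_path, sep="\t", index=False)
    if wide_path is not None:
        table.freq.to_csv(wide_path, sep="\t")


def default_focal_modules(catalog: ModuleCatalog) -> list[str]:
    """The standard focal list: all exo-, endo- and xylanase GH families in
    the catalog plus cohesin, dockerin and SLH."""
    return catalog.focal_modules()
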