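"""Gene-architecture diagrams in the pipeline's visual convention.

One horizontal track per gene; each annotated module is a colored bar whose
x-extent is its residue (or nucleotide, at 3x) interval: GH modules green,
CBM modules yellow, SLH blue, dockerin pink, cohesin purple; families with
no drawn role are grey.  Output is SVG and byte-deterministic for a fixed
input, so diagrams are diffable artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from celluclass.catalog import parent_family
from celluclass.cazy_ingest import GeneRecord
from celluclass.errors import ParseError, ValidationError

DEFAULT_COLOR_MAP = {
    "GH": "#2ca02c",        # green
    "CBM": "#ffd700",       # yellow
    "SLH": "#1f77b4",       # blue
    "dockerin": "#ff69b4",  # pink
    "cohesin": "#9467bd",   # purple
    "other": "#bdbdbd",
}


@dataclass
class GeneDiagramSpec:
    """Genes (with optional type labels) plus rendering options."""

    genes: Sequence[tuple[GeneRecord, str | None]]
    color_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLOR_MAP))
    coordinate_unit: str = "aa"

    def __post_init__(self):
        if self.coordinate_unit not in {"aa", "nt"}:
            raise ValidationError(f"coordinate_unit must be 'aa' or 'nt', got {self.coordinate_unit!r}")


def module_color_key(family: str) -> str:
    """Map a family label to its color-map key."""
    fam = parent_family(family)
    if fam == "SLH":
        return "SLH"
    if fam == "dockerin":
        return "dockerin"
    if fam == "cohesin":
        return "cohesin"
    if fam.startswith("GH"):
        return "GH"
    if fam.startswith("CBM"):
        return "CBM"
    return "other"


def bar_geometry(gene: GeneRecord, coordinate_unit: str = "aa") -> list[tuple[str, float, float]]:
    """(family, x-offset, width) of every module bar, in drawing units.

    Nucleotide mode scales residue intervals by 3.
    """
    scale = 3 if coordinate_unit == "nt" else 1
    return [
        (h.family, (h.aa_start - 1) * scale + 1, (h.aa_end - h.aa_start + 1) * scale)
        for h in gene.hits
    ]


def render_gene_map(spec: GeneDiagramSpec, out: str | Path) -> Path:
    """Render the diagram to ``out`` (SVG); deterministic for fixed input."""
    genes = [(g, label) for g, label in spec.genes if g.hits]
    if not genes:
        raise ValidationError("gene diagram spec contains no gene with hits")
    out = Path(out)
    scale = 3 if spec.coordinate_unit == "nt" else 1

    n = len(genes)
    fig_height = max(1.2, 0.6 * n + 0.6)
    fig, ax = plt.subplots(figsize=(9, fig_height))
    max_x = 0
    for row, (gene, label) in enumerate(genes):
        y = n - 1 - row
        gene_end = (gene.aa_length or max(h.aa_end for h in gene.hits)) * scale
        max_x = max(max_x, gene_end)
        ax.hlines(y, 1, gene_end, color="#555555", linewidth=1.0, zorder=1)
        for family, x0, width in bar_geometry(gene, spec.coordinate_unit):
            color = spec.color_map.get(module_color_key(family), spec.color_map.get("other", "#bdbdbd"))
            ax.barh(y, width, left=x0, height=0.55, color=color, edgecolor="black", linewidth=0.4, zorder=2)
        text = gene.protein_id if label is None else f"{gene.protein_id} [{label}]"
        ax.text(1, y + 0.38, text, fontsize=7, va="bottom")

    ax.set_xlim(0, max_x * 1.05)
    ax.set_ylim(-0.6, n - 0.2 + 0.5)
    ax.set_yticks([])
    ax.set_xlabel("position (nt)" if spec.coordinate_unit == "nt" else "position (aa)")
    ax.spines[["left", "top", "right"]].set_visible(False)
    fig.tight_layout()

    # fixed hash salt + no date metadata -> byte-identical SVG re-renders
    with plt.rc_context({"svg.hashsalt": "celluclass"}):
        try:
            fig.savefig(out, format="svg", metadata={"Date": None})
        except OSError as exc:
            raise ParseError(f"cannot write diagram to {out}: {exc}") from exc
        finally:
            plt.close(fig)
    return out
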