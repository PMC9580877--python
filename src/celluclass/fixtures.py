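"""Synthetic annotated genomes with known gene types and group labels.

The generator builds genes bottom-up from the target type's predicate at its
minimal counts plus randomized surplus, with surplus drawn only from module
sets that cannot flip the intended primary type (non-catalog decoy families
and xylanase-only genes are safe for every group).  Protein sequences are
random 20-letter strings: hit coordinates, not sequence content, drive the
pipeline.  Output is written in the ingest dialects (one hmmscan-parser
table per genome, a combined amino-acid FASTA, a truth TSV and the design as
YAML), so the whole pipeline is exercisable without any download.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml

from celluclass.catalog import ModuleCatalog, load_catalog
from celluclass.cazy_ingest import ModuleHit
from celluclass.errors import ValidationError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# families outside every default role set; inert for typing and grouping
DECOY_FAMILIES = ("GT2", "GT4", "CE1", "CE4", "PL1", "PL9", "GH13", "GH23", "CBM50")

GENERATABLE_LABELS = ("I-a", "I-b", "I-c", "I-d", "I-e", "I-f", "II", "NO_CAZY")


@dataclass(frozen=True)
class CorpusDesign:
    """Declarative description of a synthetic corpus."""

    per_group_counts: dict[str, int]
    decoy_rate: float = 0.2
    seed: int = 0
    gene_length_tail: tuple[int, int] = (10, 60)
    module_length_range: tuple[int, int] = (40, 180)

    def __post_init__(self):
        if not self.per_group_counts:
            raise ValidationError("design requests no genomes")
        unknown = set(self.per_group_counts) - set(GENERATABLE_LABELS)
        if unknown:
            raise ValidationError(f"unknown group labels in design: {sorted(unknown)}")
        if any(v < 0 for v in self.per_group_counts.values()):
            raise ValidationError("per-group counts must be non-negative")
        if not 0 <= self.decoy_rate <= 1:
            raise ValidationError("decoy_rate must lie in [0,1]")


@dataclass
class SyntheticGene:
    protein_id: str
    genome_id: str
    intended_type: str | None
    modules: list[tuple[str, int, int]]  # (family, aa_start, aa_end)
    aa_length: int


@dataclass
class SyntheticGenome:
    genome_id: str
    intended_label: str
    genes: list[SyntheticGene] = field(default_factory=list)


@dataclass
class CorpusBundle:
    design: CorpusDesign
    genomes: list[SyntheticGenome]
    truth: dict[str, str]
    paths: dict[str, Path] = field(default_factory=dict)

    def all_hits(self) -> list[ModuleHit]:
        return [h for g in self.genomes for h in genome_hits(g)]


def _reps(catalog: ModuleCatalog) -> dict[str, str]:
    """Deterministic representative family per role."""
    def pick(families: frozenset[str], preferred: str) -> str | None:
        if preferred in families:
            return preferred
        return min(families) if families else None

    exo_only = catalog.exo_gh - catalog.endo_gh
    endo_only = catalog.endo_gh - catalog.exo_gh
    return {
        "exo": pick(exo_only or catalog.exo_gh, "GH48"),
        "endo": pick(endo_only or catalog.endo_gh, "GH5"),
        "exo_exclusive": bool(exo_only),
        "endo_exclusive": bool(endo_only),
        "ccbm": pick(catalog.ccbm, "CBM3"),
        "xylanase": pick(catalog.xylanase_gh - catalog.exo_gh - catalog.endo_gh, "GH10"),
    }


def _gene_modules_for_type(
    gene_type: str, reps: dict[str, str], rng: random.Random
) -> list[str]:
    """Module multiset realizing ``gene_type`` as the primary type, at the
    minimal predicate counts plus type-safe surplus."""
    coh_extra = rng.randint(0, 2)
    if gene_type == "A1":
        return ["cohesin"] * (3 + coh_extra) + ["SLH"] * rng.randint(1, 2)
    if gene_type == "A2-a":
        return ["cohesin"] * (3 + coh_extra) + ["dockerin"]
    if gene_type == "A2-b":
        # cohesin kept below 3 so the gene is not an A1/A3 scaffold backbone
        return ["SLH"] * rng.randint(1, 2) + ["cohesin"] * rng.randint(1, 2)
    if gene_type == "A3":
        return ["cohesin"] * (3 + coh_extra)
    if gene_type == "A-s":
        return ["dockerin"] * rng.randint(1, 2) + [reps["endo"]]
    if gene_type == "B":
        return ["SLH"] + [reps["ccbm"]] * rng.randint(1, 2)
    if gene_type == "C":
        return [reps["exo"]] + [reps["ccbm"]] * rng.randint(1, 2)
    if gene_type == "D":
        return [rng.choice([reps["exo"], reps["endo"]])]
    raise ValidationError(f"no generator for gene type {gene_type!r}")


def _group_gene_plan(label: str, reps: dict[str, str], rng: random.Random) -> list[tuple[str | None, list[str]]]:
    """Per-genome gene plan guaranteeing the target decision path.

    Every Group-I plan carries both an exoglucanase and an endoglucanase
    module in some gene; Group II plans lack at least one of the two roles.
    """
    plan: list[tuple[str | None, list[str]]] = []

    def add(gene_type: str):
        plan.append((gene_type, _gene_modules_for_type(gene_type, reps, rng)))

    if label == "NO_CAZY":
        return plan
    if label == "II":
        # each variant must genuinely lack one of the two glucanase roles
        variants = []
        if reps["exo_exclusive"]:
            variants.append("exo_only")
        if reps["endo_exclusive"]:
            variants.append("endo_only")
        if reps["xylanase"]:
            variants.append("xylanase_only")
        if not variants:
            raise ValidationError(
                "group II is not generatable: every catalog family carrying one "
                "glucanase role also carries the other and no xylanase family exists"
            )
        variant = rng.choice(variants)
        if variant == "exo_only":
            plan.append(("D", [reps["exo"]]))
        elif variant == "endo_only":
            plan.append(("D", [reps["endo"]]))
        if reps["xylanase"]:
            plan.append((None, [reps["xylanase"]]))
        return plan

    if label == "I-a":
        add("A1")
        if rng.random() < 0.5:
            add("A2-a"), add("A2-b")
        add("A-s")                       # endoglucanase via the catalytic subunit
        plan.append(("D", [reps["exo"]]))
    elif label == "I-b":
        add("A3"), add("A-s"), add("B"), add("C")
        plan.append(("D", [reps["endo"]]))
    elif label == "I-c":
        add("A3"), add("A-s"), add("C")
        plan.append(("D", [reps["endo"]]))
    elif label == "I-d":
        add("B"), add("C")
        plan.append(("D", [reps["endo"]]))
    elif label == "I-e":
        add("C")
        plan.append(("D", [reps["endo"]]))
    elif label == "I-f":
        plan.append(("D", [reps["exo"]]))
        plan.append(("D", [reps["endo"]]))
    else:
        raise ValidationError(f"no generator for group label {label!r}")

    # optional surplus that cannot change the group: xylanase-only genes
    if reps["xylanase"] and rng.random() < 0.5:
        plan.append((None, [reps["xylanase"]]))
    return plan


def _layout_gene(
    genome_id: str,
    protein_id: str,
    intended_type: str | None,
    families: list[str],
    design: CorpusDesign,
    rng: random.Random,
) -> SyntheticGene:
    families = list(families)
    # inert decoy modules sprinkled into genes at the design's decoy rate
    n_decoys = sum(1 for _ in families if rng.random() < design.decoy_rate)
    families += [rng.choice(DECOY_FAMILIES) for _ in range(n_decoys)]
    rng.shuffle(families)

    modules: list[tuple[str, int, int]] = []
    cursor = rng.randint(1, 15)
    for family in families:
        length = rng.randint(*design.module_length_range)
        modules.append((family, cursor, cursor + length - 1))
        cursor += length + rng.randint(2, 20)
    aa_length = (modules[-1][2] if modules else 50) + rng.randint(*design.gene_length_tail)
    return SyntheticGene(protein_id, genome_id, intended_type, modules, aa_length)


def _validate_satisfiable(design: CorpusDesign, catalog: ModuleCatalog, reps: dict[str, str]):
    requested = {g for g, n in design.per_group_counts.items() if n > 0}
    needs_ccbm = requested & {"I-b", "I-d", "I-e"}
    if needs_ccbm and reps["ccbm"] is None:
        raise ValidationError(
            f"groups {sorted(needs_ccbm)} need a cellulose-binding CBM family, "
            "but the catalog's ccbm set is empty"
        )
    if requested & {"I-c"} and reps["ccbm"] is None:
        raise ValidationError("group I-c needs a ccbm family for its C gene")


def generate_corpus(
    design: CorpusDesign,
    catalog: ModuleCatalog | None = None,
    out_dir: str | Path | None = None,
) -> CorpusBundle:
    """Generate a synthetic corpus; a pure function of ``(design, seed)``.

    With ``out_dir`` set, writes one hmmscan-parser table per genome plus
    ``proteins.faa``, ``genomes.tsv``, ``truth.tsv`` and ``design.yaml``.
    """
    catalog = catalog or load_catalog()
    reps = _reps(catalog)
    _validate_satisfiable(design, catalog, reps)
    rng = random.Random(design.seed)

    genomes: list[SyntheticGenome] = []
    for label in GENERATABLE_LABELS:  # fixed order for determinism
        for k in range(design.per_group_counts.get(label, 0)):
            genome_id = f"sim_{label.replace('-', '')}_{k:03d}"
            genome = SyntheticGenome(genome_id=genome_id, intended_label=label)
            plan = _group_gene_plan(label, reps, rng)
            for i, (gene_type, families) in enumerate(plan, start=1):
                gene = _layout_gene(genome_id, f"{genome_id}_g{i:03d}", gene_type, families, design, rng)
                genome.genes.append(gene)
            # decoy-only genes: carry no catalog role, safe in every group
            # except NO_CAZY, which must stay absent from the hit tables
            for j in range(rng.randint(0, 2) if label != "NO_CAZY" else 0):
                gene = _layout_gene(
                    genome_id,
                    f"{genome_id}_noise{j:02d}",
                    None,
                    [rng.choice(DECOY_FAMILIES)],
                    design,
                    rng,
                )
                genome.genes.append(gene)
            genomes.append(genome)

    bundle = CorpusBundle(
        design=design,
        genomes=genomes,
        truth={g.genome_id: g.intended_label for g in genomes},
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), rng)
    return bundle


def genome_hits(genome: SyntheticGenome, e_value: float = 1e-30, coverage: float = 0.9) -> list[ModuleHit]:
    """In-memory hit list for one synthetic genome (already threshold-passing)."""
    hits = []
    for gene in genome.genes:
        for family, start, end in gene.modules:
            hits.append(
                ModuleHit(
                    family=family,
                    protein_id=gene.protein_id,
                    genome_id=genome.genome_id,
                    aa_start=start,
                    aa_end=end,
                    e_value=e_value,
                    hmm_coverage=coverage,
                )
            )
    return hits


def _write_bundle(bundle: CorpusBundle, out_dir: Path, rng: random.Random):
    out_dir.mkdir(parents=True, exist_ok=True)
    faa_lines: list[str] = []
    genome_lines = ["genome_id\tintended_label"]
    for genome in bundle.genomes:
        table = out_dir / f"{genome.genome_id}.hmmtab"
        rows = []
        for gene in genome.genes:
            for family, start, end in gene.modules:
                span = end - start + 1
                rows.append(
                    "\t".join(
                        [
                            f"{family}.hmm",
                            str(span),
                            gene.protein_id,
                            str(gene.aa_length),
                            f"{10 ** rng.uniform(-60, -20):.3e}",
                            "1",
                            str(span),
                            str(start),
                            str(end),
                            f"{rng.uniform(0.5, 0.99):.3f}",
                        ]
                    )
                )
            seq = "".join(rng.choice(AA_ALPHABET) for _ in range(gene.aa_length))
            faa_lines.append(f">{genome.genome_id}|{gene.protein_id}")
            faa_lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        table.write_text("\n".join(rows) + ("\n" if rows else ""))
        genome_lines.append(f"{genome.genome_id}\t{genome.intended_label}")

    (out_dir / "proteins.faa").write_text("\n".join(faa_lines) + "\n")
    (out_dir / "genomes.tsv").write_text("\n".join(genome_lines) + "\n")
    truth_lines = ["genome_id\tprotein_id\tintended_type\tintended_label"]
    for genome in bundle.genomes:
        for gene in genome.genes:
            truth_lines.append(
                f"{genome.genome_id}\t{gene.protein_id}\t{gene.intended_type or ''}\t{genome.intended_label}"
            )
    (out_dir / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    (out_dir / "design.yaml").write_text(
        yaml.safe_dump(
            {
                "per_group_counts": dict(bundle.design.per_group_counts),
                "decoy_rate": bundle.design.decoy_rate,
                "seed": bundle.design.seed,
            },
            sort_keys=True,
        )
    )
    bundle.paths = {
        "proteins": out_dir / "proteins.faa",
        "genomes": out_dir / "genomes.tsv",
        "truth": out_dir / "truth.tsv",
        "design": out_dir / "design.yaml",
        "tables": out_dir,
    }


MUTATIONS = ("add_A1_gene", "add_B_gene", "remove_B_genes", "strip_slh_from_scaffolds")


def mutate_genome(
    genome: SyntheticGenome, edit: str, catalog: ModuleCatalog | None = None
) -> SyntheticGenome:
    """Apply a minimal deterministic genotype edit and return a new genome.

    ``add_A1_gene`` / ``add_B_gene`` append the minimal gene of that type;
    ``remove_B_genes`` drops every intended-B gene; and
    ``strip_slh_from_scaffolds`` deletes SLH modules from scaffold genes
    (turning an anchored A1 backbone into a free A3 one).
    """
    catalog = catalog or load_catalog()
    reps = _reps(catalog)
    genes = [replace(g, modules=list(g.modules)) for g in genome.genes]

    def fixed_gene(protein_id: str, intended: str, families: list[str]) -> SyntheticGene:
        modules = []
        cursor = 1
        for family in families:
            modules.append((family, cursor, cursor + 99))
            cursor += 110
        return SyntheticGene(protein_id, genome.genome_id, intended, modules, cursor + 40)

    if edit == "add_A1_gene":
        genes.append(fixed_gene(f"{genome.genome_id}_mutA1", "A1", ["cohesin"] * 3 + ["SLH"]))
    elif edit == "add_B_gene":
        if reps["ccbm"] is None:
            raise ValidationError("cannot add a B gene: catalog has no ccbm family")
        genes.append(fixed_gene(f"{genome.genome_id}_mutB", "B", ["SLH", reps["ccbm"]]))
    elif edit == "remove_B_genes":
        kept = [g for g in genes if g.intended_type != "B"]
        if len(kept) == len(genes):
            raise ValidationError(f"{genome.genome_id} has no B genes to remove")
        genes = kept
    elif edit == "strip_slh_from_scaffolds":
        touched = False
        for g in genes:
            if g.intended_type in {"A1", "A2-b"}:
                without = [m for m in g.modules if m[0] != "SLH"]
                if len(without) != len(g.modules):
                    g.modules = without
                    g.intended_type = "A3" if g.intended_type == "A1" else None
                    touched = True
        if not touched:
            raise ValidationError(f"{genome.genome_id} has no SLH-bearing scaffold genes")
    else:
        raise ValidationError(f"unknown edit {edit!r}; expected one of {MUTATIONS}")

    return SyntheticGenome(genome_id=genome.genome_id, intended_label=genome.intended_label, genes=genes)
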