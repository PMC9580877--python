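# Methods

## Scope and model

`celluclass` is a rule-based annotation-interpretation pipeline, not a
statistical model: every decision is a deterministic function of module
counts. Its unit of evidence is the *module occurrence* — one HMM hit of a
CAZy family (or of the structural SLH/cohesin/dockerin profiles) on one
protein. Genes are typed from occurrence counts alone; module order along
the protein is used only for visualization, because the underlying
architecture rules are count thresholds, not positional grammars.

The pipeline assumes its input annotation is trustworthy: it consumes
dbCAN-style HMM search tables and never runs the search itself. It equally
assumes complete gene models; truncated genes in draft assemblies can lose
modules and deflate counts (the co-occurrence statistic in particular
should be computed on complete genomes).

## Ingest and filtering

Raw hits are filtered by `e_value <= max_e_value` (default `1e-15`) and
`hmm_coverage >= min_hmm_coverage` (default `0.35`) — the commonly
recommended dbCAN HMM criteria; both are plain CLI/API parameters since
recommended cutoffs drift between dbCAN releases. Overlapping same-family
hits on one protein (interval overlap greater than half the shorter
interval) are resolved by greedy best-first acceptance on E-value, ties
broken by smaller start coordinate; the operation is idempotent and is
exposed as a policy (`best_per_region`, default) next to `keep_all`,
because either convention is defensible for counting.

Family labels are normalized by stripping the `.hmm` suffix and
canonicalizing structural-module spellings (`cohesion` → `cohesin`, `DOC` →
`dockerin`). Subfamily labels (`GH5_4`) keep their full name in every
report but collapse to the parent family (`GH5`) for role lookup, since
role vocabularies are defined at family level.

## The role catalog

All typing rules read a `ModuleCatalog` mapping families to roles:
exoglucanase GH, endoglucanase GH, xylanase GH, LPMO, cellulose-binding CBM
(cCBM), and the fixed structural set {SLH, cohesin, dockerin}. The derived
role cGH is the union of the exo-, endoglucanase and LPMO sets. The shipped
default is a curated stand-in assembled from CAZy activity documentation
(4 exo / 7 endo / 7 xylanase GH families, 3 LPMOs, 15 cCBMs); GH9 is
deliberately listed under both glucanase roles — it is predominantly an
endoglucanase but has documented exoglucanase activity, and the pipeline
follows the family-level (not EC-level) convention of counting a family
under every documented role. The engine's correctness does not depend on
any particular vocabulary: the catalog is replaceable from YAML/TSV without
code changes, and classification reports log the catalog checksum so group
labels are traceable to the vocabulary that produced them.

## Gene typing

Eight predicates over the five role counts (see README table). Two
subtleties:

* **Scaffold precedence.** The four scaffold predicates overlap by
  construction (any A1 gene also satisfies A2-b), so a precedence ladder
  A1 > A2-a > A2-b > A3 keeps exactly one scaffold label. The order is an
  implementation policy: SLH-in-backbone outranks the dockerin-tail route,
  which outranks the bare SLH-carrier, which outranks the SLH-free
  backbone. Genes carrying both SLH and dockerin never arise in real
  corpora (their same-gene co-occurrence is the zero the A2 definition
  rests on), but the resolution must still be deterministic.
* **Multi-label semantics.** Non-scaffold labels are kept multi-label
  (a dockerin+GH gene satisfies both A-s and D), and `primary_type` is the
  first satisfied label in the order A1, A2-a, A2-b, A3, A-s, B, C, D.
  Genome-level tallies count primaries only, so a cellulosomal catalytic
  subunit never inflates the free-cellulase count — cellulosomal genes and
  the non-cellulosome gene set are disjoint categories at genome level.
  The per-gene report emits both the multi-label set and the primary, so
  either counting convention can be reproduced downstream.

The A-s predicate defaults to the strict reading (dockerin ≥ 1 **and**
cGH ≥ 1); a `strict_as=False` switch admits the looser dockerin-plus-cCBM
reading.

## Genome classification

The decision sequence (NO_CAZY → II → I-a → I-b/I-c → I-d → I-e → I-f) is
evaluated in order; the first satisfied criterion assigns the label and the
evaluated path is recorded per genome. Two policy points:

* An A2-a backbone with no A2-b partner cannot acquire SLH, so it is
  treated as a *free* scaffold (routes to I-b/I-c). The
  `a2_requires_pair=False` switch counts a lone A2-a as adhering instead.
* NO_CAZY is reserved for genomes absent from the annotation output
  entirely; a genome annotated only with families outside the catalog's
  role sets still went through annotation and falls to Group II.

`has_exo`/`has_endo` are computed from the genome-wide module abundance,
not from typed genes only, so a glucanase module sitting in an otherwise
role-poor gene still counts toward Group-I eligibility.

## Co-occurrence statistic

For focal module m: retrieve all genes with ≥ 1 occurrence of m; N_m =
total occurrences of m in those genes; n_i = total occurrences of partner i
in those genes; freq = 100·n_i/N_m. Consequences worth stating: the ratio
is scale-invariant (duplicating every gene changes nothing), frequencies
can exceed 100% (two CBM3 copies next to one GH9), and a gene containing
two different focal modules contributes independently to both rows.
Self-partnership is excluded by default; `include_self` reports the
extra-copy frequency 100·(N_m − g_m)/N_m instead (g_m = number of
m-containing genes). The heatmap scale is log10(freq + 0.01), anchoring 0%
at exactly −2 and 100% at ~2. The default focal list is catalog-derived:
every exo-, endo- and xylanase-GH family plus cohesin, dockerin and SLH.

## GenBank extraction

One protein record per CDS feature. Features with a `/translation`
qualifier use it verbatim; those without are translated from the nucleotide
span with translation table 11 (bacterial) and a trailing stop trimmed;
`/pseudo` CDS and untranslatable spans are skipped and logged. Coordinates
are stored 1-based inclusive; compound (join) locations keep the minimal
start and maximal end with a multi-segment flag — sufficient for reporting,
which is all coordinates are used for. Replicons of one strain are
aggregated under one genome id, with protein-id collisions across replicons
resolved by replicon-prefixing (deterministic, no counters). FASTA output
wraps at 60 columns and encodes genome, protein, replicon and coordinates
in the header, so the extraction round-trips.

## Synthetic corpus generator

The generator emulates the *annotation output* of a genome collection, not
genomes themselves: for each requested group label it assembles the minimal
gene plan whose decision path ends at that label (e.g. I-b = A3 scaffold +
A-s subunit + B adhesion gene + C and D cellulases), realizes each gene at
its minimal predicate counts plus randomized surplus, lays modules out at
non-overlapping residue intervals (module lengths 40–180 aa by default),
and draws E-values (1e-60..1e-20) and coverages (0.5..0.99) comfortably
inside the default thresholds. Decoy modules from families outside every
role set are sprinkled in at `decoy_rate` (default 0.2) and as decoy-only
genes; they are inert for every rule by construction. Surplus is restricted
to sets that cannot flip a gene's primary type or a genome's group (e.g. an
A2-b gene caps its cohesin count at 2; Group-II genomes only ever receive
one glucanase role). NO_CAZY genomes emit no hit rows at all — they exist
only in the genome manifest, mirroring corpora where some genomes yield no
CAZyme annotation. Generation is a pure function of (design, seed).

What the generator does **not** emulate: realistic HMM score distributions,
borderline/partial hits, overlapping competing families, subfamily labels,
annotation errors, or any nucleotide-level structure. Passing tests
therefore demonstrate that the *interpretation* layers (typing, grouping,
statistics) are correct given a faithful annotation, not that any upstream
HMM search is well-tuned.

## Verification

The test suite checks the typing engine against an independently coded
brute-force predicate evaluator over all 3,125 count vectors in {0..4}^5,
the decision tree against a literal row-matcher for the published genotype
table over presence/absence sweeps, and the co-occurrence statistic against
a per-gene brute-force tally on 100 random corpora of up to 50 genes; plus
round-trip, idempotence, permutation-invariance and monotonicity
properties, and 5-seed end-to-end truth-label recovery through the on-disk
file formats. `scripts/acceptance.py` re-runs the end-to-end measurement at
8 groups × 3 genomes × 5 seeds (120 genomes, seconds on one CPU) — sizes
chosen to exercise every decision path several times per seed.

## Known limitations

* The default catalog is a stand-in, not an authority; analyses of real
  corpora should supply the catalog matching their dbCAN release.
* Non-CAZy adhesion machinery (Fn3, LysM domains, extracellular polymeric
  substances) is invisible to the pipeline, so Group I-c/I-e genomes may be
  cellulolytic through mechanisms the rules cannot see.
* Counts, not positions: a gene with three cohesins split across unrelated
  domains types as a scaffold backbone regardless of arrangement.
* Group labels are genotype categories, not phenotype predictions;
  phenotype metadata passes through reports untouched.
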