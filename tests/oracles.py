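"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately written straight off the published rule
tables — flat if-chains and per-gene scans — and shares no code with the
package implementation.
"""

from collections import Counter


def brute_force_gene_types(slh, doc, coh, cgh, ccbm):
    """Literal evaluation of the eight architecture predicates followed by
    the scaffold precedence ladder; returns (satisfied frozenset, primary)."""
    satisfied = []
    if slh >= 1 and doc == 0 and coh >= 3:
        satisfied.append("A1")
    if doc >= 1 and coh >= 3:
        satisfied.append("A2-a")
    if slh >= 1 and coh >= 1:
        satisfied.append("A2-b")
    if slh == 0 and doc == 0 and coh >= 3:
        satisfied.append("A3")
    if doc >= 1 and cgh >= 1:
        satisfied.append("A-s")
    if slh >= 1 and ccbm >= 1:
        satisfied.append("B")
    if cgh >= 1 and ccbm >= 1:
        satisfied.append("C")
    if cgh >= 1 and ccbm == 0:
        satisfied.append("D")

    scaffolds = [t for t in ("A1", "A2-a", "A2-b", "A3") if t in satisfied]
    if scaffolds:
        keep = scaffolds[0]
        satisfied = [t for t in satisfied if t not in ("A1", "A2-a", "A2-b", "A3") or t == keep]

    order = ("A1", "A2-a", "A2-b", "A3", "A-s", "B", "C", "D")
    primary = None
    for t in order:
        if t in satisfied:
            primary = t
            break
    return frozenset(satisfied), primary


# Literal rows of the genotype table: (adhering, free, B, C, D) -> group,
# where each entry is a minimum count ("0" means exactly zero).
GROUP_TABLE_ROWS = [
    ((1, 0, 0, 0, 0), (None, None, None, None, None), "I-a"),
    ((0, 1, 1, 1, 1), (0, None, None, None, None), "I-b"),
    ((0, 1, 0, 1, 1), (0, None, 0, None, None), "I-c"),
    ((0, 0, 1, 1, 1), (0, 0, None, None, None), "I-d"),
    ((0, 0, 1, 1, 0), (0, 0, None, None, None), "I-d"),
    ((0, 0, 1, 0, 1), (0, 0, None, None, None), "I-d"),
    ((0, 0, 0, 1, 1), (0, 0, 0, None, None), "I-e"),
    ((0, 0, 0, 1, 0), (0, 0, 0, None, 0), "I-e"),
    ((0, 0, 0, 0, 1), (0, 0, 0, 0, None), "I-f"),
]


def table_row_match(adhering, free, n_b, n_c, n_d):
    """Return the group printed for the first matching literal table row, or
    None when no row covers the count vector.  Assumes exo+endo present."""
    counts = (adhering, free, n_b, n_c, n_d)
    for minima, maxima, group in GROUP_TABLE_ROWS:
        ok = True
        for value, lo, hi in zip(counts, minima, maxima):
            if value < lo or (hi is not None and value > hi):
                ok = False
                break
        if ok:
            return group
    return None


def brute_force_cooccurrence(gene_families, focal):
    """Three-step tally for one focal module over a corpus given as a list
    of per-gene family lists.  Returns (N, {partner: n_i}, {partner: freq})."""
    focal_genes = [fams for fams in gene_families if focal in fams]
    N = sum(1 for fams in focal_genes for f in fams if f == focal)
    n = Counter()
    for fams in focal_genes:
        for f in fams:
            if f != focal:
                n[f] += 1
    freq = {p: 100.0 * c / N for p, c in n.items()} if N else {}
    return N, dict(n), freq
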