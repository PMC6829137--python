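"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results from first principles (literal
per-base-pair set construction) and share no code path with the package
implementations they check.
"""
from __future__ import annotations

from tefamquant.annotations import GeneModel, TEElement
from tefamquant.assign import ReadRecord
from tefamquant.intervals import GenomicInterval


def bp_set(iv: GenomicInterval) -> set[tuple[str, int]]:
    return {(iv.chrom, p) for p in range(iv.start, iv.end + 1)}


def _wins(a: TEElement, b: TEElement) -> bool:
    """Independent restatement of the per-bp priority between two elements."""
    asp, bsp = a.span, b.span
    a_subset = (
        bsp.start <= asp.start
        and asp.end <= bsp.end
        and (asp.start, asp.end) != (bsp.start, bsp.end)
    )
    b_subset = (
        asp.start <= bsp.start
        and bsp.end <= asp.end
        and (asp.start, asp.end) != (bsp.start, bsp.end)
    )
    if a_subset != b_subset:
        return a_subset  # the nested (inner) element claims the shared bp
    if asp.start != bsp.start:
        return asp.start < bsp.start
    if asp.end != bsp.end:
        return (asp.end - asp.start) > (bsp.end - bsp.start)
    return a.element_id < b.element_id


def brute_force_attribution(
    elements: list[TEElement], genes: list[GeneModel]
) -> dict[str, set[tuple[str, int]]]:
    """element_id -> attributed (chrom, bp) set after disjoin + exon mask.

    Walks every covered base-pair, finds the tournament winner among the
    covering elements, then removes exonic base-pairs.
    """
    exon_bps: set[tuple[str, int]] = set()
    for g in genes:
        for ex in g.exons:
            exon_bps |= bp_set(ex)

    covered: dict[tuple[str, int], list[TEElement]] = {}
    for el in elements:
        for bp in bp_set(el.span):
            covered.setdefault(bp, []).append(el)

    out: dict[str, set[tuple[str, int]]] = {el.element_id: set() for el in elements}
    for bp, els in covered.items():
        if bp in exon_bps:
            continue
        winners = [a for a in els if all(a is b or _wins(a, b) for b in els)]
        assert len(winners) == 1, f"no unique winner at {bp}"
        out[winners[0].element_id].add(bp)
    return out


def brute_force_feature_map(
    elements: list[TEElement], genes: list[GeneModel], chrom_allowlist: set[str]
) -> dict[tuple[str, int], set[tuple[str, str, str]]]:
    """bp -> {("te", element_id, family)} | {("gene", gene_id, "")} sets
    built from the *masked segments* and exons, literally per base-pair."""
    fmap: dict[tuple[str, int], set[tuple[str, str, str]]] = {}
    for el in elements:
        if el.span.chrom not in chrom_allowlist:
            continue
        for seg in el.segments:
            for bp in bp_set(seg):
                fmap.setdefault(bp, set()).add(("te", el.element_id, el.family))
    for g in genes:
        if g.span.chrom not in chrom_allowlist:
            continue
        for ex in g.exons:
            for bp in bp_set(ex):
                fmap.setdefault(bp, set()).add(("gene", g.gene_id, ""))
    return fmap


def brute_force_classify(
    read: ReadRecord, fmap: dict[tuple[str, int], set[tuple[str, str, str]]]
) -> tuple[str, str | None]:
    """Literal per-read classification from per-bp overlap sets.

    Returns (category value string, target) in the same vocabulary as
    ``AssignmentCategory.value``.
    """
    genes: set[str] = set()
    elements: set[str] = set()
    families: set[str] = set()
    for iv in read.alignments:
        for bp in bp_set(iv):
            for kind, ident, fam in fmap.get(bp, ()):
                if kind == "te":
                    elements.add(ident)
                    families.add(fam)
                else:
                    genes.add(ident)

    unique = read.n_hits == 1
    if unique:
        if genes and not families and len(genes) == 1:
            return "gene_unique", next(iter(genes))
        if len(families) == 1 and not genes:
            if len(elements) == 1:
                return "te_element_unique", next(iter(elements))
            return "u_te.fam", next(iter(families))
        if len(families) == 1 and genes:
            return "u_te.g", next(iter(families))
        return "unassigned", None
    if len(families) == 1 and not genes:
        return "m_te.fam", next(iter(families))
    if len(families) == 1 and genes:
        return "m_te.g", next(iter(families))
    return "unassigned", None


def brute_force_bh(pvalues: list[float]) -> list[float]:
    """Step-up BH by the definition: padj_i = min over j with p_j >= p_i of
    min(1, m * p_j / rank_j), computed with explicit loops."""
    m = len(pvalues)
    ranked = sorted(range(m), key=lambda i: pvalues[i])
    rank_of = {i: r + 1 for r, i in enumerate(ranked)}
    out = []
    for i in range(m):
        candidates = [
            min(1.0, m * pvalues[j] / rank_of[j])
            for j in range(m)
            if pvalues[j] >= pvalues[i]
        ]
        out.append(min(candidates))
    return out
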