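"""TE and gene annotation parsing, disjoining, exon masking, indexing.

The quantification method intersects reads against a single merged
annotation in which (a) every genomic base-pair belongs to at most one TE
element (nested insertions punch holes in their containers) and (b) any TE
base-pair that overlaps an exon of a gene model has been masked out, so a
read overlapping both an exon and a residual TE segment is genuinely
ambiguous.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import (
    GenomicInterval,
    IntervalIndex,
    merge_intervals,
    subtract_interval,
)

log = logging.getLogger(__name__)

#: 2-letter family-code prefix -> TE order.
ORDER_PREFIXES = {
    "RL": "LTR",
    "DT": "TIR",
    "DH": "Helitron",
    "RI": "LINE",
    "RS": "SINE",
}
UNKNOWN_ORDER = "unknown"

_FAMILY_CODE_RE = re.compile(r"^([A-Z]{3}\d{5})")


class GFF3ParseError(ValueError):
    """Raised for a malformed GFF3 record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int) -> None:
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class MissingAttributeError(ValueError):
    pass


def decode_order(family: str) -> str:
    """TE order from the family-code prefix; ``'unknown'`` when unrecognized."""
    return ORDER_PREFIXES.get(family[:2].upper(), UNKNOWN_ORDER)


@dataclass
class TEElement:
    """One structurally annotated TE copy.

    ``segments`` holds the disjoined, exon-masked pieces of the genome
    attributed to this element; empty until :func:`disjoin_te_annotations`
    has run (and possibly empty afterwards, for fully shadowed elements).
    """

    element_id: str
    family: str
    order: str
    span: GenomicInterval
    segments: list[GenomicInterval] = field(default_factory=list)

    @property
    def assignable_bp(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class TEFamily:
    name: str
    order: str
    member_count: int


@dataclass
class GeneModel:
    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons) if self.exons else []
        for ex in self.exons:
            if not self.span.contains(ex):
                raise ValueError(
                    f"exon {ex} outside span of gene {self.gene_id}"
                )


def family_registry(elements: Iterable[TEElement]) -> dict[str, TEFamily]:
    """Family -> :class:`TEFamily` with structural member counts.

    Elements whose assignable segments were emptied by disjoining/masking
    still count as members: member counts reflect the structural
    annotation, not assignable length.
    """
    counts: dict[str, int] = {}
    orders: dict[str, str] = {}
    for el in elements:
        counts[el.family] = counts.get(el.family, 0) + 1
        orders[el.family] = el.order
    return {
        fam: TEFamily(fam, orders[fam], n) for fam, n in sorted(counts.items())
    }


# ---------------------------------------------------------------------------
# GFF3 parsing (hand-rolled: the dialects involved are plain tab-separated
# GFF3 with `key=value` attributes; no need for a database-backed parser).
# ---------------------------------------------------------------------------

def _parse_attributes(raw: str, line_number: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise GFF3ParseError(f"attribute without '=': {chunk!r}", line_number)
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _iter_gff3_records(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, source, ftype, start, end, score, strand, phase, attr_raw = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GFF3ParseError(
                    f"non-integer coordinates {start!r}..{end!r}", lineno
                ) from None
            if start_i < 1 or end_i < start_i:
                raise GFF3ParseError(
                    f"invalid interval {start_i}..{end_i}", lineno
                )
            yield lineno, chrom, source, ftype, start_i, end_i, strand, _parse_attributes(
                attr_raw, lineno
            )


def parse_te_gff(
    path: str | Path,
    family_attribute: str = "Name",
    id_attribute: str = "ID",
) -> list[TEElement]:
    """Read a structural TE annotation GFF3 into :class:`TEElement` records.

    The family code is taken from ``family_attribute``; when absent it is
    recovered from the leading family-code portion of the element ID
    (e.g. ``RLG00001Zm...`` -> ``RLG00001``).  Records lacking both raise
    :class:`MissingAttributeError` naming the offending IDs.
    """
    elements: list[TEElement] = []
    missing: list[str] = []
    for lineno, chrom, _src, _ftype, start, end, strand, attrs in _iter_gff3_records(path):
        element_id = attrs.get(id_attribute) or f"te_{lineno}"
        family = attrs.get(family_attribute)
        if family is None:
            m = _FAMILY_CODE_RE.match(element_id)
            if m:
                family = m.group(1)
            else:
                missing.append(element_id)
                continue
        if strand not in ("+", "-"):
            strand = "."
        order = decode_order(family)
        if order == UNKNOWN_ORDER:
            log.warning("unknown order prefix for family %s (element %s)", family, element_id)
        elements.append(
            TEElement(
                element_id=element_id,
                family=family,
                order=order,
                span=GenomicInterval(chrom, start, end, strand),
            )
        )
    if missing:
        raise MissingAttributeError(
            f"records missing family attribute {family_attribute!r}: "
            + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else "")
        )
    return elements


def parse_gene_gff(
    path: str | Path,
    gene_types: Sequence[str] = ("gene",),
    exon_types: Sequence[str] = ("exon",),
) -> list[GeneModel]:
    """Read gene models with exons from GFF3.

    Exons are attached to genes through their ``Parent`` chain (transcript
    parents are followed one level) and merged to a disjoint set per gene.
    Genes without annotated exons get their full span as a single exon.
    """
    spans: dict[str, GenomicInterval] = {}
    parent_of: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}

    for lineno, chrom, _src, ftype, start, end, strand, attrs in _iter_gff3_records(path):
        if strand not in ("+", "-"):
            strand = "."
        iv = GenomicInterval(chrom, start, end, strand)
        fid = attrs.get("ID")
        parent = attrs.get("Parent", "").split(",")[0] or None
        if ftype in gene_types:
            if fid is None:
                raise GFF3ParseError("gene record without ID", lineno)
            spans[fid] = iv
        elif ftype in exon_types:
            if parent is None:
                raise GFF3ParseError("exon record without Parent", lineno)
            exons.setdefault(parent, []).append(iv)
        else:
            # transcript-level feature: remember the parent link
            if fid is not None and parent is not None:
                parent_of[fid] = parent

    gene_exons: dict[str, list[GenomicInterval]] = {g: [] for g in spans}
    for parent, ivs in exons.items():
        gene = parent
        seen = set()
        while gene not in spans and gene in parent_of and gene not in seen:
            seen.add(gene)
            gene = parent_of[gene]
        if gene in spans:
            gene_exons[gene].extend(ivs)
        else:
            log.warning("exon parent %s not linked to any gene; skipped", parent)

    models = []
    for gid, span in spans.items():
        exs = gene_exons.get(gid) or [span]
        models.append(GeneModel(gid, span, exs))
    models.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return models


# ---------------------------------------------------------------------------
# Disjoining
# ---------------------------------------------------------------------------

def _beats(a: TEElement, b: TEElement) -> bool:
    """True when element ``a`` claims a shared base-pair over ``b``.

    Priority: a proper sub-span (nested insertion) beats its container;
    for crossing overlaps the earlier start wins; identical spans fall
    back to the lexicographically smaller element ID.
    """
    sa, sb = a.span, b.span
    a_in_b = sb.contains(sa) and (sa.start, sa.end) != (sb.start, sb.end)
    b_in_a = sa.contains(sb) and (sa.start, sa.end) != (sb.start, sb.end)
    if a_in_b:
        return True
    if b_in_a:
        return False
    if sa.start != sb.start:
        return sa.start < sb.start
    if sa.length != sb.length:
        return sa.length > sb.length
    return a.element_id < b.element_id


def resolve_owner(candidates: Sequence[TEElement]) -> TEElement:
    """The unique element that beats every other candidate pairwise."""
    for a in candidates:
        if all(a is b or _beats(a, b) for b in candidates):
            return a
    # The priority relation is acyclic on any overlap set; reaching here
    # would indicate a comparator bug.
    raise AssertionError(
        "no tournament winner among " + ", ".join(c.element_id for c in candidates)
    )


def disjoin_te_annotations(elements: Sequence[TEElement]) -> list[TEElement]:
    """Attribute every covered base-pair to exactly one element.

    Returns new :class:`TEElement` records with ``segments`` populated.
    Nested elements claim their own span; partial (crossing) overlaps are
    resolved deterministically and logged.
    """
    out = [replace(el, segments=[]) for el in elements]
    by_chrom: dict[str, list[TEElement]] = {}
    for el in out:
        by_chrom.setdefault(el.span.chrom, []).append(el)

    for chrom, els in by_chrom.items():
        bounds = sorted({el.span.start for el in els} | {el.span.end + 1 for el in els})
        # active-set sweep over elementary segments
        events: dict[int, list[tuple[str, TEElement]]] = {}
        for el in els:
            events.setdefault(el.span.start, []).append(("add", el))
            events.setdefault(el.span.end + 1, []).append(("del", el))
        active: list[TEElement] = []
        warned: set[tuple[str, str]] = set()
        for i, pos in enumerate(bounds[:-1]):
            for op, el in events.get(pos, ()):  # noqa: B007
                if op == "add":
                    active.append(el)
                else:
                    active.remove(el)
            if not active:
                continue
            if len(active) > 1:
                owner = resolve_owner(active)
                for other in active:
                    if other is not owner:
                        key = tuple(sorted((owner.element_id, other.element_id)))
                        crossing = not (
                            owner.span.contains(other.span)
                            or other.span.contains(owner.span)
                        )
                        if crossing and key not in warned:
                            warned.add(key)
                            log.warning(
                                "partial TE overlap: %s vs %s on %s; earlier-start rule applied",
                                key[0], key[1], chrom,
                            )
            else:
                owner = active[0]
            seg = GenomicInterval(chrom, pos, bounds[i + 1] - 1, owner.span.strand)
            if owner.segments and owner.segments[-1].end + 1 == seg.start:
                prev = owner.segments[-1]
                owner.segments[-1] = GenomicInterval(chrom, prev.start, seg.end, prev.strand)
            else:
                owner.segments.append(seg)
    return out


def subtract_exons(
    elements: Sequence[TEElement], genes: Sequence[GeneModel]
) -> list[TEElement]:
    """Mask exonic base-pairs out of the (already disjoined) TE segments.

    Elements reduced to zero assignable bp are retained with empty
    ``segments`` so that family member counts are unaffected.
    """
    exons_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        for ex in g.exons:
            exons_by_chrom.setdefault(ex.chrom, []).append(ex)
    for chrom in exons_by_chrom:
        exons_by_chrom[chrom] = merge_intervals(exons_by_chrom[chrom])

    out = []
    for el in elements:
        exons = exons_by_chrom.get(el.span.chrom)
        if not exons:
            out.append(replace(el, segments=list(el.segments)))
            continue
        new_segments: list[GenomicInterval] = []
        for seg in el.segments:
            new_segments.extend(subtract_interval(seg, exons))
        out.append(replace(el, segments=new_segments))
    return out


def masking_report(before: Sequence[TEElement], after: Sequence[TEElement]) -> dict:
    """Summary of what exon masking removed."""
    bp_before = sum(el.assignable_bp for el in before)
    bp_after = sum(el.assignable_bp for el in after)
    emptied = [
        el.element_id
        for b, el in zip(before, after)
        if b.assignable_bp > 0 and el.assignable_bp == 0
    ]
    return {
        "bp_before": bp_before,
        "bp_after": bp_after,
        "bp_masked": bp_before - bp_after,
        "elements_emptied": emptied,
    }


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TEHit:
    element_id: str
    family: str


@dataclass(frozen=True)
class GeneHit:
    gene_id: str


class AnnotationIndex:
    """Merged, masked annotation supporting >=1 bp overlap queries.

    Queries return :class:`TEHit` / :class:`GeneHit` payloads for TE
    segments and gene exons overlapping the query interval.  Features on
    sequences outside the allowlist are absent entirely.
    """

    def __init__(
        self,
        elements: Sequence[TEElement],
        genes: Sequence[GeneModel],
        chrom_allowlist: Iterable[str],
    ) -> None:
        allow = set(chrom_allowlist)
        if not allow:
            raise ValueError("chrom_allowlist must not be empty")
        self.chrom_allowlist = allow
        self.elements = [el for el in elements if el.span.chrom in allow]
        self.genes = [g for g in genes if g.span.chrom in allow]
        self.families = family_registry(self.elements)
        self._index = IntervalIndex()
        for el in self.elements:
            hit = TEHit(el.element_id, el.family)
            for seg in el.segments:
                self._index.add(seg, hit)
        for g in self.genes:
            hit = GeneHit(g.gene_id)
            for ex in g.exons:
                self._index.add(ex, hit)

    def query(self, iv: GenomicInterval) -> list[TEHit | GeneHit]:
        if iv.chrom not in self.chrom_allowlist:
            return []
        return self._index.query(iv)

    def element_by_id(self, element_id: str) -> TEElement:
        for el in self.elements:
            if el.element_id == element_id:
                return el
        raise KeyError(element_id)


def build_annotation_index(
    elements: Sequence[TEElement],
    genes: Sequence[GeneModel],
    chrom_allowlist: Iterable[str],
) -> AnnotationIndex:
    """Construct the query index from exon-masked elements and gene models."""
    return AnnotationIndex(elements, genes, chrom_allowlist)


def write_merged_gff(
    path: str | Path,
    elements: Sequence[TEElement],
    genes: Sequence[GeneModel],
    chrom_allowlist: Iterable[str] | None = None,
) -> None:
    """Write the merged, masked annotation (TE segments + gene exons) as GFF3."""
    allow = set(chrom_allowlist) if chrom_allowlist is not None else None
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        rows = []
        for el in elements:
            if allow is not None and el.span.chrom not in allow:
                continue
            for seg in el.segments:
                rows.append(
                    (seg.chrom, seg.start, seg.end, "te_segment", seg.strand,
                     f"ID={el.element_id};Name={el.family};order={el.order}")
                )
        for g in genes:
            if allow is not None and g.span.chrom not in allow:
                continue
            for ex in g.exons:
                rows.append(
                    (ex.chrom, ex.start, ex.end, "exon", ex.strand, f"Parent={g.gene_id}")
                )
        rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
        for chrom, start, end, ftype, strand, attrs in rows:
            fh.write(
                f"{chrom}\ttefamquant\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


def read_merged_gff(path: str | Path) -> tuple[list[TEElement], list[GeneModel]]:
    """Read back a merged annotation written by :func:`write_merged_gff`."""
    elements: dict[str, TEElement] = {}
    gene_exons: dict[str, list[GenomicInterval]] = {}
    for lineno, chrom, _src, ftype, start, end, strand, attrs in _iter_gff3_records(path):
        iv = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
        if ftype == "te_segment":
            eid = attrs.get("ID")
            fam = attrs.get("Name")
            if eid is None or fam is None:
                raise GFF3ParseError("te_segment without ID/Name", lineno)
            el = elements.get(eid)
            if el is None:
                el = TEElement(eid, fam, attrs.get("order", decode_order(fam)), iv, [iv])
                elements[eid] = el
            else:
                el.segments.append(iv)
                el.span = GenomicInterval(
                    chrom, min(el.span.start, iv.start), max(el.span.end, iv.end),
                    el.span.strand,
                )
        elif ftype == "exon":
            gid = attrs.get("Parent") or attrs.get("ID")
            if gid is None:
                raise GFF3ParseError("exon without Parent", lineno)
            gene_exons.setdefault(gid, []).append(iv)
    genes = []
    for gid, exs in sorted(gene_exons.items()):
        merged = merge_intervals(exs)
        span = GenomicInterval(
            merged[0].chrom, merged[0].start, merged[-1].end, merged[0].strand
        )
        genes.append(GeneModel(gid, span, merged))
    return list(elements.values()), genes
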