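"""Read classification against the merged gene/TE annotation.

Every read (with all of its reported alignments) lands in exactly one
category:

==================  =====================================================
GENE_UNIQUE         unique mapper overlapping gene exon(s) only
TE_ELEMENT_UNIQUE   unique mapper overlapping exactly one TE element
                    (also credited to its family's unique column)
TE_FAMILY_UNIQUE    unique mapper overlapping 2+ elements of one family
TE_FAMILY_MULTI     multi mapper whose annotated hits are members of
                    exactly one family, no gene
AMBIG_UNIQUE        unique mapper hitting both a gene and one TE family
AMBIG_MULTI         multi mapper hitting both a gene and one TE family
UNASSIGNED          everything else (no features, several families,
                    several genes, multi-mapper with gene hits only)
==================  =====================================================

Overlap means >= 1 bp against an exon or an exon-masked TE segment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .annotations import AnnotationIndex, GeneHit, TEHit
from .intervals import GenomicInterval

log = logging.getLogger(__name__)


class AssignmentCategory(Enum):
    GENE_UNIQUE = "gene_unique"
    TE_ELEMENT_UNIQUE = "te_element_unique"
    TE_FAMILY_UNIQUE = "u_te.fam"
    TE_FAMILY_MULTI = "m_te.fam"
    AMBIG_UNIQUE = "u_te.g"
    AMBIG_MULTI = "m_te.g"
    UNASSIGNED = "unassigned"


@dataclass
class ReadRecord:
    """One sequencing read with every reported alignment location.

    ``alignments`` holds one interval per aligned block; a spliced
    alignment contributes several blocks but still counts as a single
    mapping, so ``n_hits`` (the NH-style mapping count) is carried
    explicitly.
    """

    read_id: str
    alignments: list[GenomicInterval]
    n_hits: int

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ValueError(f"read {self.read_id} has no alignments")
        if self.n_hits < 1:
            raise ValueError(f"read {self.read_id}: n_hits must be >= 1")

    @property
    def is_unique(self) -> bool:
        return self.n_hits == 1


def group_alignments(path: str | Path) -> Iterator[ReadRecord]:
    """Collate a SAM/BAM file into one :class:`ReadRecord` per read name.

    Secondary alignments are included; unmapped records are skipped.
    When the NH tag disagrees with the number of observed mapping
    records, the observed count wins with a warning.
    """
    import pysam

    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    blocks: dict[str, list[GenomicInterval]] = {}
    mappings: dict[str, int] = {}
    nh_tags: dict[str, int] = {}
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            name = aln.query_name
            mappings[name] = mappings.get(name, 0) + 1
            if aln.has_tag("NH"):
                nh_tags[name] = int(aln.get_tag("NH"))
            strand = "-" if aln.is_reverse else "+"
            lst = blocks.setdefault(name, [])
            for b_start, b_end in aln.get_blocks():
                # pysam blocks are 0-based half-open
                lst.append(
                    GenomicInterval(aln.reference_name, b_start + 1, b_end, strand)
                )
    for name, ivs in blocks.items():
        n_obs = mappings[name]
        nh = nh_tags.get(name, n_obs)
        if nh != n_obs:
            log.warning(
                "read %s: NH tag %d != %d observed alignments; using observed",
                name, nh, n_obs,
            )
        yield ReadRecord(name, ivs, n_obs)


def feature_hits(
    read: ReadRecord, index: AnnotationIndex
) -> tuple[set[str], set[str], set[str]]:
    """(gene ids, TE element ids, TE family codes) overlapped >= 1 bp by
    any of the read's aligned blocks."""
    genes: set[str] = set()
    elements: set[str] = set()
    families: set[str] = set()
    for iv in read.alignments:
        for hit in index.query(iv):
            if isinstance(hit, TEHit):
                elements.add(hit.element_id)
                families.add(hit.family)
            elif isinstance(hit, GeneHit):
                genes.add(hit.gene_id)
    return genes, elements, families


def classify_read(
    read: ReadRecord, index: AnnotationIndex
) -> tuple[AssignmentCategory, str | None]:
    """Classify one read; the target is the credited gene/element/family.

    For ambiguous reads the target is the family (the te.g ledger is kept
    per family); alignments overlapping no annotation never disqualify a
    read whose annotated hits are otherwise consistent.
    """
    genes, elements, families = feature_hits(read, index)
    n_fam = len(families)
    if read.is_unique:
        if genes and not families:
            if len(genes) == 1:
                return AssignmentCategory.GENE_UNIQUE, next(iter(genes))
            return AssignmentCategory.UNASSIGNED, None
        if n_fam == 1 and not genes:
            if len(elements) == 1:
                return AssignmentCategory.TE_ELEMENT_UNIQUE, next(iter(elements))
            return AssignmentCategory.TE_FAMILY_UNIQUE, next(iter(families))
        if n_fam == 1 and genes:
            return AssignmentCategory.AMBIG_UNIQUE, next(iter(families))
        return AssignmentCategory.UNASSIGNED, None
    # multi-mapper
    if n_fam == 1 and not genes:
        return AssignmentCategory.TE_FAMILY_MULTI, next(iter(families))
    if n_fam == 1 and genes:
        return AssignmentCategory.AMBIG_MULTI, next(iter(families))
    return AssignmentCategory.UNASSIGNED, None


#: family-table column names in output order
FAMILY_COLUMNS = ("u_te.fam", "u_te.g", "m_te.fam", "m_te.g")


@dataclass
class LibraryCounts:
    """Per-library count ledger in the method's categories."""

    library_id: str = "library"
    u_te_fam: dict[str, int] = field(default_factory=dict)
    m_te_fam: dict[str, int] = field(default_factory=dict)
    u_te_g: dict[str, int] = field(default_factory=dict)
    m_te_g: dict[str, int] = field(default_factory=dict)
    gene_unique: dict[str, int] = field(default_factory=dict)
    element_unique: dict[str, int] = field(default_factory=dict)
    element_te_g: dict[str, int] = field(default_factory=dict)
    gene_te_g: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    unassigned: int = 0

    def category_total(self, category: AssignmentCategory) -> int:
        if category is AssignmentCategory.GENE_UNIQUE:
            return sum(self.gene_unique.values())
        if category is AssignmentCategory.TE_ELEMENT_UNIQUE:
            return sum(self.element_unique.values())
        if category is AssignmentCategory.TE_FAMILY_UNIQUE:
            return sum(self.u_te_fam.values())
        if category is AssignmentCategory.TE_FAMILY_MULTI:
            return sum(self.m_te_fam.values())
        if category is AssignmentCategory.AMBIG_UNIQUE:
            return sum(self.u_te_g.values())
        if category is AssignmentCategory.AMBIG_MULTI:
            return sum(self.m_te_g.values())
        return self.unassigned

    @property
    def summary(self) -> dict[str, int]:
        """The one-line per-library totals mirroring the method's summary file."""
        return {
            "total_reads": self.total_reads,
            "gene_unique": sum(self.gene_unique.values()),
            "u_te.fam": sum(self.u_te_fam.values()),
            "u_te.g": sum(self.u_te_g.values()),
            "m_te.fam": sum(self.m_te_fam.values()),
            "m_te.g": sum(self.m_te_g.values()),
            "unassigned": self.unassigned,
        }


def count_library(
    reads: Iterable[ReadRecord],
    index: AnnotationIndex,
    library_id: str = "library",
) -> LibraryCounts:
    """Classify every read exactly once and tally the category ledgers."""
    counts = LibraryCounts(library_id=library_id)
    for read in reads:
        counts.total_reads += 1
        genes, elements, families = feature_hits(read, index)
        category, target = classify_read(read, index)
        if category is AssignmentCategory.GENE_UNIQUE:
            counts.gene_unique[target] = counts.gene_unique.get(target, 0) + 1
        elif category is AssignmentCategory.TE_ELEMENT_UNIQUE:
            counts.element_unique[target] = counts.element_unique.get(target, 0) + 1
            fam = next(iter(families))  # single family by construction
            counts.u_te_fam[fam] = counts.u_te_fam.get(fam, 0) + 1
        elif category is AssignmentCategory.TE_FAMILY_UNIQUE:
            counts.u_te_fam[target] = counts.u_te_fam.get(target, 0) + 1
        elif category is AssignmentCategory.TE_FAMILY_MULTI:
            counts.m_te_fam[target] = counts.m_te_fam.get(target, 0) + 1
        elif category is AssignmentCategory.AMBIG_UNIQUE:
            counts.u_te_g[target] = counts.u_te_g.get(target, 0) + 1
            # the element/gene unique table carries te.g for unique reads only
            if len(elements) == 1:
                el = next(iter(elements))
                counts.element_te_g[el] = counts.element_te_g.get(el, 0) + 1
            if len(genes) == 1:
                g = next(iter(genes))
                counts.gene_te_g[g] = counts.gene_te_g.get(g, 0) + 1
        elif category is AssignmentCategory.AMBIG_MULTI:
            counts.m_te_g[target] = counts.m_te_g.get(target, 0) + 1
        else:
            counts.unassigned += 1
    return counts


def write_library_counts(counts: LibraryCounts, outdir: str | Path) -> None:
    """Write the two per-library count files plus the summary line.

    ``family_counts.tsv``: family, u_te.fam, u_te.g, m_te.fam, m_te.g.
    ``element_counts.tsv``: feature, unique, te.g (TE elements and genes).
    ``te_mapping_summary.txt``: appended single line of category totals.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    families = sorted(
        set(counts.u_te_fam) | set(counts.u_te_g) | set(counts.m_te_fam) | set(counts.m_te_g)
    )
    with open(outdir / "family_counts.tsv", "w") as fh:
        fh.write("family\tu_te.fam\tu_te.g\tm_te.fam\tm_te.g\n")
        for fam in families:
            fh.write(
                f"{fam}\t{counts.u_te_fam.get(fam, 0)}\t{counts.u_te_g.get(fam, 0)}"
                f"\t{counts.m_te_fam.get(fam, 0)}\t{counts.m_te_g.get(fam, 0)}\n"
            )

    features = sorted(
        set(counts.element_unique) | set(counts.element_te_g)
        | set(counts.gene_unique) | set(counts.gene_te_g)
    )
    with open(outdir / "element_counts.tsv", "w") as fh:
        fh.write("feature\tunique\tte.g\n")
        for feat in features:
            uniq = counts.element_unique.get(feat, counts.gene_unique.get(feat, 0))
            teg = counts.element_te_g.get(feat, counts.gene_te_g.get(feat, 0))
            fh.write(f"{feat}\t{uniq}\t{teg}\n")

    summary = counts.summary
    summary_path = outdir / "te_mapping_summary.txt"
    header_needed = not summary_path.exists()
    with open(summary_path, "a") as fh:
        if header_needed:
            fh.write(
                "library\ttotal_reads\tgene_unique\tu_te.fam\tu_te.g\tm_te.fam\tm_te.g\tunassigned\n"
            )
        fh.write(
            f"{counts.library_id}\t{summary['total_reads']}\t{summary['gene_unique']}"
            f"\t{summary['u_te.fam']}\t{summary['u_te.g']}\t{summary['m_te.fam']}"
            f"\t{summary['m_te.g']}\t{summary['unassigned']}\n"
        )


def read_library_counts(libdir: str | Path, library_id: str | None = None) -> LibraryCounts:
    """Load a per-library count directory written by :func:`write_library_counts`."""
    from .annotations import UNKNOWN_ORDER, decode_order

    libdir = Path(libdir)
    counts = LibraryCounts(library_id=library_id or libdir.name)
    with open(libdir / "family_counts.tsv") as fh:
        next(fh)
        for line in fh:
            fam, u, ug, m, mg = line.rstrip("\n").split("\t")
            if int(u):
                counts.u_te_fam[fam] = int(u)
            if int(ug):
                counts.u_te_g[fam] = int(ug)
            if int(m):
                counts.m_te_fam[fam] = int(m)
            if int(mg):
                counts.m_te_g[fam] = int(mg)
    with open(libdir / "element_counts.tsv") as fh:
        next(fh)
        for line in fh:
            feat, uniq, teg = line.rstrip("\n").split("\t")
            # TE element IDs carry family-code prefixes; everything else is a gene
            if decode_order(feat) != UNKNOWN_ORDER:
                if int(uniq):
                    counts.element_unique[feat] = int(uniq)
                if int(teg):
                    counts.element_te_g[feat] = int(teg)
            else:
                if int(uniq):
                    counts.gene_unique[feat] = int(uniq)
                if int(teg):
                    counts.gene_te_g[feat] = int(teg)
    summary_path = libdir / "te_mapping_summary.txt"
    if summary_path.exists():
        with open(summary_path) as fh:
            header = next(fh).rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                if row["library"] == counts.library_id or library_id is None:
                    counts.total_reads = int(row["total_reads"])
                    counts.unassigned = int(row["unassigned"])
    return counts
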