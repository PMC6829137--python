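"""Synthetic annotations and alignments with exact ground truth.

No nucleotide sequences are generated: the quantification method
consumes alignments, so reads are *placed* directly (full-length match
CIGAR) at positions that realize an intended assignment category by
construction.  This keeps fixtures tiny and the truth exact:

* unique TE reads lie entirely within one element's masked segment;
* multi-mapper TE reads get one alignment inside a segment of each of
  several members of the same family;
* ambiguous reads span an exon / TE-segment boundary (the TE was placed
  overlapping a gene exon, so its masked segment abuts the exon);
* gene reads lie entirely within an exon.

Family copy numbers from one to thousands, nested insertions, and TEs
inside genes are all expressible through :class:`FamilySpec`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    AnnotationIndex,
    GeneHit,
    GeneModel,
    TEElement,
    TEHit,
    build_annotation_index,
    decode_order,
    disjoin_te_annotations,
    family_registry,
    subtract_exons,
)
from .assign import ReadRecord
from .intervals import GenomicInterval

MAX_REPORTED_HITS = 20  # mapping-position cap emulated by the generator


@dataclass
class FamilySpec:
    name: str
    n_members: int = 1
    member_length: int = 1500
    nesting_prob: float = 0.0
    inside_gene_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


@dataclass
class GeneSpec:
    n_genes: int = 5
    n_exons: int = 3
    exon_length: int = 300
    intron_length: int = 400


@dataclass
class LibrarySpec:
    library_id: str
    total_reads: int = 1000
    read_length: int = 100
    tissue: str = "leaf"
    genotype: str = "B73"
    replicate: str = "1"
    dataset: str = "sim"
    family_weights: dict[str, float] = field(default_factory=dict)
    gene_weight: float = 1.0
    expressed_member_mode: str = "uniform"  # single_member | uniform | mixed
    multimap_rate: float = 0.0
    ambig_rate: float = 0.0
    expressed_elements: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        if any(w < 0 for w in self.family_weights.values()) or self.gene_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.expressed_member_mode not in ("single_member", "uniform", "mixed"):
            raise ValueError(f"unknown expressed_member_mode {self.expressed_member_mode!r}")


@dataclass
class SimConfig:
    families: list[FamilySpec]
    genes: GeneSpec = field(default_factory=GeneSpec)
    libraries: list[LibrarySpec] = field(default_factory=list)
    n_chromosomes: int = 1
    chromosome_length: int = 2_000_000
    seed: int = 0


@dataclass
class SimAnnotation:
    elements: list[TEElement]  # disjoined + exon-masked
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    index: AnnotationIndex
    #: element_id -> exon-boundary position usable for ambiguous reads
    ambig_boundaries: dict[str, tuple[str, int]]

    @property
    def registry(self):
        return family_registry(self.elements)


@dataclass
class SimTruth:
    """Per-library intended category counts; totals equal generated reads."""

    library_id: str
    family_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    gene_unique: dict[str, int] = field(default_factory=dict)
    element_unique: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0

    def add_family(self, category: str, family: str) -> None:
        self.family_counts.setdefault(family, {c: 0 for c in
                                               ("u_te.fam", "u_te.g", "m_te.fam", "m_te.g")})
        self.family_counts[family][category] += 1

    def category_totals(self) -> dict[str, int]:
        totals = {c: 0 for c in ("u_te.fam", "u_te.g", "m_te.fam", "m_te.g")}
        for per_cat in self.family_counts.values():
            for c, n in per_cat.items():
                totals[c] += n
        totals["gene_unique"] = sum(self.gene_unique.values())
        return totals


def simulate_annotation(config: SimConfig, seed: int | None = None) -> SimAnnotation:
    """Deterministically place genes and TE members on synthetic chromosomes."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chromosome_length for c in chroms}
    cursors = {c: 1000 for c in chroms}

    genes: list[GeneModel] = []
    gs = config.genes
    for gi in range(gs.n_genes):
        chrom = chroms[gi % len(chroms)]
        start = cursors[chrom] + int(rng.integers(100, 500))
        exons = []
        pos = start
        for _ in range(gs.n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + gs.exon_length - 1))
            pos += gs.exon_length + gs.intron_length
        end = exons[-1].end
        if end > chrom_lengths[chrom]:
            raise ValueError("gene placement exceeds chromosome length")
        genes.append(GeneModel(f"gene{gi + 1:04d}", GenomicInterval(chrom, start, end), exons))
        cursors[chrom] = end + 1

    raw_elements: list[TEElement] = []
    ambig_boundaries: dict[str, tuple[str, int]] = {}
    last_placed: dict[str, TEElement] = {}
    gene_cycle = 0
    for fam in config.families:
        order = decode_order(fam.name)
        n_inside = int(round(fam.inside_gene_frac * fam.n_members))
        for mi in range(fam.n_members):
            eid = f"{fam.name}_m{mi + 1}"
            length = fam.member_length
            placed = False
            if mi < n_inside and genes:
                # overlap the downstream half of an exon and extend past it,
                # leaving a masked segment abutting the exon boundary
                gene = genes[gene_cycle % len(genes)]
                gene_cycle += 1
                exon = gene.exons[0]
                start = exon.end - min(length // 3, exon.length - 1) + 1
                end = start + length - 1
                span = GenomicInterval(exon.chrom, start, end)
                raw_elements.append(TEElement(eid, fam.name, order, span))
                ambig_boundaries[eid] = (exon.chrom, exon.end)
                placed = True
            elif fam.nesting_prob > 0 and rng.random() < fam.nesting_prob:
                container = last_placed.get("any")
                if container is not None and container.span.length >= length + 20:
                    off = int(rng.integers(5, container.span.length - length - 5))
                    start = container.span.start + off
                    span = GenomicInterval(container.span.chrom, start, start + length - 1)
                    raw_elements.append(TEElement(eid, fam.name, order, span))
                    placed = True
            if not placed:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                start = cursors[chrom] + int(rng.integers(50, 300))
                end = start + length - 1
                if end > chrom_lengths[chrom]:
                    raise ValueError(
                        f"element {eid} exceeds chromosome length {chrom_lengths[chrom]}"
                    )
                span = GenomicInterval(chrom, start, end)
                raw_elements.append(TEElement(eid, fam.name, order, span))
                cursors[chrom] = end + 1
                last_placed["any"] = raw_elements[-1]

    disjoined = disjoin_te_annotations(raw_elements)
    masked = subtract_exons(disjoined, genes)
    index = build_annotation_index(masked, genes, chroms)

    # keep only boundaries where a read spanning the exon edge is guaranteed
    # to hit exactly (that element, one gene): disjoining may have handed the
    # flanking segment to a different element
    validated: dict[str, tuple[str, int]] = {}
    for eid, (chrom, bpos) in ambig_boundaries.items():
        te_side = index.query(GenomicInterval(chrom, bpos + 1, bpos + 60))
        exon_side = index.query(GenomicInterval(chrom, max(1, bpos - 39), bpos))
        te_ok = (
            len(te_side) == 1
            and isinstance(te_side[0], TEHit)
            and te_side[0].element_id == eid
        )
        gene_ok = len(exon_side) == 1 and isinstance(exon_side[0], GeneHit)
        if te_ok and gene_ok:
            validated[eid] = (chrom, bpos)
    return SimAnnotation(masked, genes, chrom_lengths, index, validated)


def _usable_segments(el: TEElement, read_length: int) -> list[GenomicInterval]:
    return [s for s in el.segments if s.length >= read_length]


def simulate_library(
    ann: SimAnnotation,
    spec: LibrarySpec,
    seed: int = 0,
    sam_path: str | Path | None = None,
) -> tuple[list[ReadRecord], SimTruth]:
    """Generate placed alignments realizing the library spec.

    Returns the in-memory read records plus exact truth; optionally also
    writes a SAM file (with NH tags) for file-based workflows.
    """
    rng = np.random.default_rng(seed)
    truth = SimTruth(library_id=spec.library_id)
    L = spec.read_length

    by_family: dict[str, list[TEElement]] = {}
    for el in ann.elements:
        by_family.setdefault(el.family, []).append(el)

    # per-family usable members and their sampling weights
    fam_members: dict[str, list[TEElement]] = {}
    fam_member_w: dict[str, np.ndarray] = {}
    for fam, weight in spec.family_weights.items():
        if weight <= 0:
            continue
        members = [
            el for el in by_family.get(fam, []) if _usable_segments(el, L)
        ]
        if spec.expressed_elements and fam in spec.expressed_elements:
            chosen = set(spec.expressed_elements[fam])
            members = [el for el in members if el.element_id in chosen]
        if not members:
            raise ValueError(f"family {fam} has no member with a segment >= read length")
        if spec.expressed_member_mode == "single_member" and not spec.expressed_elements:
            members = members[:1]
        fam_members[fam] = members
        if spec.expressed_member_mode == "mixed":
            w = 1.0 / np.arange(1, len(members) + 1)
        else:
            w = np.ones(len(members))
        fam_member_w[fam] = w / w.sum()

    sources = [f for f in fam_members] + ["__gene__"]
    weights = np.array(
        [spec.family_weights[f] for f in fam_members] + [spec.gene_weight], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("all source weights are zero")
    weights = weights / weights.sum()

    usable_exons = [
        (g, ex) for g in ann.genes for ex in g.exons if ex.length >= L
    ]
    if spec.gene_weight > 0 and not usable_exons:
        raise ValueError("gene reads requested but no exon is >= read length")

    reads: list[ReadRecord] = []
    for ri in range(spec.total_reads):
        rid = f"{spec.library_id}_r{ri + 1:07d}"
        src = sources[int(rng.choice(len(sources), p=weights))]
        if src == "__gene__":
            gene, exon = usable_exons[int(rng.integers(0, len(usable_exons)))]
            start = exon.start + int(rng.integers(0, exon.length - L + 1))
            reads.append(
                ReadRecord(rid, [GenomicInterval(exon.chrom, start, start + L - 1)], 1)
            )
            truth.gene_unique[gene.gene_id] = truth.gene_unique.get(gene.gene_id, 0) + 1
            truth.total_reads += 1
            continue

        members = fam_members[src]
        want_multi = rng.random() < spec.multimap_rate
        want_ambig = rng.random() < spec.ambig_rate
        boundary_members = [
            el for el in members if el.element_id in ann.ambig_boundaries
        ]
        if want_ambig and not boundary_members:
            want_ambig = False
        if want_multi and len(members) < 2:
            want_multi = False  # downgraded to unique

        intervals: list[GenomicInterval] = []
        if want_ambig:
            el = boundary_members[int(rng.integers(0, len(boundary_members)))]
            chrom, bpos = ann.ambig_boundaries[el.element_id]
            # span the exon/TE-segment boundary: >=1 bp each side
            into_exon = int(rng.integers(1, min(L - 1, 40) + 1))
            start = bpos - into_exon + 1
            iv = GenomicInterval(chrom, start, start + L - 1)
            hits = ann.index.query(iv)
            n_gene = sum(isinstance(h, GeneHit) for h in hits)
            te_ids = {h.element_id for h in hits if isinstance(h, TEHit)}
            if n_gene != 1 or te_ids != {el.element_id}:
                want_ambig = False  # boundary unusable at this read length
            else:
                intervals.append(iv)
        if want_ambig:
            if want_multi:
                others = [m for m in members if m is not el] or [el]
                k = min(len(others), int(rng.integers(1, MAX_REPORTED_HITS)), 19)
                pick = rng.choice(len(others), size=k, replace=False)
                for pi in sorted(pick):
                    seg = _pick_segment(others[pi], L, rng)
                    intervals.append(seg)
                truth.add_family("m_te.g", src)
            else:
                truth.add_family("u_te.g", src)
        elif want_multi:
            k = min(len(members), int(rng.integers(2, MAX_REPORTED_HITS + 1)))
            pick = rng.choice(len(members), size=k, replace=False)
            for pi in sorted(pick):
                intervals.append(_pick_segment(members[pi], L, rng))
            truth.add_family("m_te.fam", src)
        else:
            idx = int(rng.choice(len(members), p=fam_member_w[src]))
            el = members[idx]
            intervals.append(_pick_segment(el, L, rng))
            truth.add_family("u_te.fam", src)
            truth.element_unique[el.element_id] = (
                truth.element_unique.get(el.element_id, 0) + 1
            )
        reads.append(ReadRecord(rid, intervals, len(intervals)))
        truth.total_reads += 1

    if sam_path is not None:
        write_sam(sam_path, reads, ann.chrom_lengths)
    return reads, truth


def _pick_segment(el: TEElement, read_length: int, rng: np.random.Generator) -> GenomicInterval:
    segs = _usable_segments(el, read_length)
    seg = segs[int(rng.integers(0, len(segs)))]
    start = seg.start + int(rng.integers(0, seg.length - read_length + 1))
    return GenomicInterval(seg.chrom, start, start + read_length - 1)


def write_sam(
    path: str | Path,
    reads: Sequence[ReadRecord],
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write placed alignments as SAM with NH tags (full-length match CIGAR)."""
    import pysam

    chroms = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for read in reads:
            for ai, iv in enumerate(read.alignments):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = read.read_id
                a.reference_id = tid[iv.chrom]
                a.reference_start = iv.start - 1
                a.cigarstring = f"{iv.length}M"
                a.mapping_quality = 50 if read.n_hits == 1 else 1
                a.flag = 0 if ai == 0 else 256
                if iv.strand == "-":
                    a.flag |= 16
                a.set_tag("NH", read.n_hits)
                fh.write(a)


def write_truth(path: str | Path, truth: SimTruth) -> None:
    rows = []
    for fam, cats in sorted(truth.family_counts.items()):
        rows.append({"feature": fam, "kind": "family", **cats})
    for gene, n in sorted(truth.gene_unique.items()):
        rows.append({"feature": gene, "kind": "gene", "gene_unique": n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def metadata_frame(specs: Sequence[LibrarySpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "library_id": [s.library_id for s in specs],
            "tissue": [s.tissue for s in specs],
            "genotype": [s.genotype for s in specs],
            "replicate": [s.replicate for s in specs],
            "dataset": [s.dataset for s in specs],
        }
    ).set_index("library_id")


# ---------------------------------------------------------------------------
# RIL panel
# ---------------------------------------------------------------------------

def simulate_ril_panel(
    ann: SimAnnotation,
    expressed_elements: Mapping[str, Sequence[tuple[str, str, float]]],
    n_rils: int,
    seed: int = 0,
    reads_per_library: int = 2000,
    read_length: int = 100,
    gene_weight: float = 5.0,
    genotype_matrix: pd.DataFrame | None = None,
) -> tuple[list[tuple[LibrarySpec, list[ReadRecord], SimTruth]], pd.DataFrame]:
    """Simulate a RIL panel segregating expressed TE elements.

    ``expressed_elements`` maps family -> [(element_id, parent_of_origin,
    weight)].  Elements tagged ``"both"`` are present in every RIL;
    otherwise each RIL inherits each element independently with
    probability 0.5 (or per the supplied 0/1 ``genotype_matrix``,
    elements x RILs).  Returns the per-RIL libraries (spec, reads, truth)
    and the realized genotype matrix.
    """
    if n_rils < 2:
        raise ValueError("n_rils must be >= 2")
    rng = np.random.default_rng(seed)
    all_elements = [
        (fam, eid, origin, w)
        for fam, members in expressed_elements.items()
        for (eid, origin, w) in members
    ]
    ril_ids = [f"RIL{i + 1:03d}" for i in range(n_rils)]
    if genotype_matrix is None:
        geno = pd.DataFrame(
            {
                rid: [
                    1 if origin == "both" else int(rng.random() < 0.5)
                    for (_f, _e, origin, _w) in all_elements
                ]
                for rid in ril_ids
            },
            index=[e for (_f, e, _o, _w) in all_elements],
        )
    else:
        geno = genotype_matrix.copy()

    out = []
    for rid in ril_ids:
        inherited: dict[str, list[str]] = {}
        fam_w: dict[str, float] = {}
        for fam, eid, _origin, w in all_elements:
            if geno.loc[eid, rid]:
                inherited.setdefault(fam, []).append(eid)
                fam_w[fam] = fam_w.get(fam, 0.0) + w
        spec = LibrarySpec(
            library_id=rid,
            total_reads=reads_per_library,
            read_length=read_length,
            tissue="shoot_apex",
            genotype=rid,
            dataset="ril",
            family_weights=fam_w,
            gene_weight=gene_weight,
            expressed_elements=inherited,
        )
        reads, truth = simulate_library(ann, spec, seed=int(rng.integers(0, 2**31)))
        out.append((spec, reads, truth))
    return out, geno
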