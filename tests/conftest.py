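from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from tefamquant.annotations import (
    GeneModel,
    TEElement,
    build_annotation_index,
    decode_order,
    disjoin_te_annotations,
    subtract_exons,
)
from tefamquant.assign import ReadRecord
from tefamquant.intervals import GenomicInterval


def make_element(eid: str, family: str, chrom: str, start: int, end: int) -> TEElement:
    return TEElement(eid, family, decode_order(family), GenomicInterval(chrom, start, end))


@pytest.fixture
def schematic_annotation():
    """Hand-built annotation realizing the method's schematic: a gene with
    a TE inserted across one exon boundary, a two-member TE family, and a
    standalone TE element.

    Layout on chr1 (1-based inclusive):
      gene g1: exons 1000-1299 and 1800-2099
      TE RLC10001_in: span 1200-1700 (overlaps exon1 tail; masked segment
        1300-1700 abuts the exon boundary at 1299)
      family RLG20002 members m1: 5000-6999, m2: 9000-10999
      element RLX30003_solo: 13000-14999
    """
    gene = GeneModel(
        "g1",
        GenomicInterval("chr1", 1000, 2099),
        [GenomicInterval("chr1", 1000, 1299), GenomicInterval("chr1", 1800, 2099)],
    )
    elements = [
        make_element("RLC10001_in", "RLC10001", "chr1", 1200, 1700),
        make_element("RLG20002_m1", "RLG20002", "chr1", 5000, 6999),
        make_element("RLG20002_m2", "RLG20002", "chr1", 9000, 10999),
        make_element("RLX30003_solo", "RLX30003", "chr1", 13000, 14999),
    ]
    masked = subtract_exons(disjoin_te_annotations(elements), [gene])
    index = build_annotation_index(masked, [gene], {"chr1"})
    return masked, [gene], index


@pytest.fixture
def fig_schematic_reads():
    """Five reads realizing the schematic categories A-E:

    A: unique in an exon               -> gene_unique
    B: unique across exon/TE boundary  -> u_te.g
    C: multi, one hit across boundary, one in a family member -> m_te.g
    D: multi in two members of one family -> m_te.fam
    E: unique inside one TE element    -> u_te.fam (element credit)
    """
    read_a = ReadRecord("A", [GenomicInterval("chr1", 1050, 1149)], 1)
    read_b = ReadRecord("B", [GenomicInterval("chr1", 1250, 1349)], 1)
    read_c = ReadRecord(
        "C",
        [GenomicInterval("chr1", 1280, 1379), GenomicInterval("chr1", 1400, 1499)],
        2,
    )
    read_d = ReadRecord(
        "D",
        [GenomicInterval("chr1", 5100, 5199), GenomicInterval("chr1", 9100, 9199)],
        2,
    )
    read_e = ReadRecord("E", [GenomicInterval("chr1", 13500, 13599)], 1)
    return [read_a, read_b, read_c, read_d, read_e]


def random_annotation(rng: np.random.Generator, n_elements=12, n_genes=3, span=20000):
    """Random, possibly nested/overlapping annotation set for oracle tests."""
    elements = []
    fams = ["RLG%05d" % i for i in range(1, 5)] + ["DTA00009", "DHH00007"]
    for i in range(n_elements):
        start = int(rng.integers(1, span - 300))
        length = int(rng.integers(80, 2500))
        fam = fams[int(rng.integers(0, len(fams)))]
        elements.append(
            make_element(f"{fam}_e{i}", fam, "chr1", start, min(start + length - 1, span))
        )
    genes = []
    for gi in range(n_genes):
        gstart = int(rng.integers(1, span - 2000))
        exons = []
        pos = gstart
        for _ in range(int(rng.integers(1, 4))):
            elen = int(rng.integers(100, 400))
            exons.append(GenomicInterval("chr1", pos, pos + elen - 1))
            pos += elen + int(rng.integers(100, 500))
        genes.append(
            GeneModel(f"g{gi}", GenomicInterval("chr1", gstart, exons[-1].end), exons)
        )
    return elements, genes


def random_reads(rng: np.random.Generator, n_reads=150, span=20000, read_len=80):
    """Arbitrary reads: random positions, random multiplicity; exercises
    every category including unassigned and multi-family."""
    reads = []
    for i in range(n_reads):
        n_hits = int(rng.choice([1, 1, 1, 2, 3, 5]))
        ivs = []
        for _ in range(n_hits):
            start = int(rng.integers(1, span - read_len))
            ivs.append(GenomicInterval("chr1", start, start + read_len - 1))
        reads.append(ReadRecord(f"r{i}", ivs, n_hits))
    return reads
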