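"""Normalization, expression calling, and per-library contribution summaries.

RPM uses the total of reads assigned unambiguously to genes (unique) or
TE families (u_te.fam + m_te.fam) as the library-size denominator;
ambiguous te.g reads are excluded from the denominator but are included
in the per-category TE read-fraction summary, which reports the share of
all assigned reads (including ambiguous) that touch TEs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

TE_CATEGORIES = ("u_te.fam", "u_te.g", "m_te.fam", "m_te.g")


@dataclass
class ExpressionMatrix:
    """Features x libraries RPM values plus per-library sample metadata.

    ``metadata`` is indexed by library id with (at least) columns
    ``tissue``, ``genotype``, ``replicate``, ``dataset``.
    """

    rpm: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    denominators: pd.Series | None = None
    feature_kind: pd.Series | None = None  # "family" or "gene" per feature

    def __post_init__(self) -> None:
        if (self.rpm.to_numpy() < 0).any():
            raise ValueError("RPM values must be non-negative")
        if not self.metadata.empty:
            missing = set(self.rpm.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"libraries missing from metadata: {sorted(missing)}")

    @property
    def libraries(self) -> list[str]:
        return list(self.rpm.columns)

    def families(self) -> pd.DataFrame:
        if self.feature_kind is None:
            return self.rpm
        return self.rpm.loc[self.feature_kind == "family"]

    def genes(self) -> pd.DataFrame:
        if self.feature_kind is None:
            return self.rpm.iloc[0:0]
        return self.rpm.loc[self.feature_kind == "gene"]


def rpm_normalize(
    family_sum: pd.DataFrame,
    gene_unique: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """RPM-normalize family sums and gene unique counts jointly.

    Denominator per library = sum of gene unique counts + sum of family
    (u+m) counts.  Libraries with a zero denominator are an error.
    """
    if list(family_sum.columns) != list(gene_unique.columns):
        common = [c for c in family_sum.columns if c in set(gene_unique.columns)]
        if len(common) != len(family_sum.columns) or len(common) != len(gene_unique.columns):
            raise ValueError("family and gene matrices must share the library axis")
        gene_unique = gene_unique[common]
    denom = family_sum.sum(axis=0) + gene_unique.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"zero assigned-read denominator for libraries: {list(zero.index)}")
    counts = pd.concat([family_sum, gene_unique])
    if counts.index.has_duplicates:
        raise ValueError("family and gene identifiers overlap")
    rpm = counts * 1e6 / denom
    kind = pd.Series(
        ["family"] * len(family_sum) + ["gene"] * len(gene_unique), index=counts.index
    )
    return ExpressionMatrix(
        rpm=rpm,
        metadata=metadata if metadata is not None else pd.DataFrame(),
        denominators=denom,
        feature_kind=kind,
    )


def rpm_from_counts(counts: pd.DataFrame, denominators: pd.Series) -> pd.DataFrame:
    """Normalize any count matrix (e.g. per-element) by the same library sizes."""
    return counts * 1e6 / denominators.loc[counts.columns]


def call_expressed(
    matrix: pd.DataFrame,
    mode: Literal["atlas", "replicate_mean", "single_library"] = "atlas",
    min_rpm: float = 1.0,
    min_libraries: int = 3,
    replicate_groups: Mapping[str, Sequence[str]] | None = None,
) -> set[str]:
    """Expressed-feature set under one of the three calling modes.

    atlas: RPM strictly > ``min_rpm`` in at least ``min_libraries``
    libraries.  replicate_mean: mean RPM >= ``min_rpm`` within at least
    one replicate group (groups map name -> library columns).
    single_library: RPM >= ``min_rpm`` in at least one library.
    """
    if mode == "atlas":
        n_over = (matrix > min_rpm).sum(axis=1)
        return set(matrix.index[n_over >= min_libraries])
    if mode == "replicate_mean":
        if not replicate_groups:
            raise ValueError("replicate_mean mode requires replicate_groups")
        expressed: set[str] = set()
        for _name, libs in replicate_groups.items():
            means = matrix[list(libs)].mean(axis=1)
            expressed |= set(matrix.index[means >= min_rpm])
        return expressed
    if mode == "single_library":
        return set(matrix.index[(matrix >= min_rpm).any(axis=1)])
    raise ValueError(f"unknown expression-calling mode {mode!r}")


def te_read_fraction(summary: pd.DataFrame, include_ambiguous: bool = True) -> pd.DataFrame:
    """Percent of assigned reads attributed to TEs, per category and total.

    ``summary`` is the per-library totals table (rows = libraries) with
    columns gene_unique, u_te.fam, u_te.g, m_te.fam, m_te.g.  With
    ``include_ambiguous`` the denominator counts all five assigned
    categories (the figure-style percent); without it both numerator and
    denominator drop the te.g columns (the RPM universe).
    """
    if include_ambiguous:
        te_cols = list(TE_CATEGORIES)
    else:
        te_cols = ["u_te.fam", "m_te.fam"]
    denom = summary["gene_unique"] + summary[te_cols].sum(axis=1)
    out = pd.DataFrame(index=summary.index)
    for cat in te_cols:
        out[f"pct_{cat}"] = np.where(denom > 0, 100.0 * summary[cat] / denom, np.nan)
    out["pct_te_total"] = np.where(
        denom > 0, 100.0 * summary[te_cols].sum(axis=1) / denom, np.nan
    )
    return out


def top_family_contribution(family_sum: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Percent of TE family reads captured by each library's top-k families.

    Ties in the ranking are broken lexicographically by family name.
    Libraries with no TE reads report NaN.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    for lib in family_sum.columns:
        col = family_sum[lib]
        total = col.sum()
        ranked = col.sort_index().sort_values(ascending=False, kind="mergesort")
        top = ranked.iloc[:k]
        rows.append(
            {
                "library": lib,
                "top_k_percent": (100.0 * top.sum() / total) if total > 0 else np.nan,
                "top_family": ranked.index[0] if total > 0 else None,
                "top_family_percent": (100.0 * ranked.iloc[0] / total) if total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("library")


def log2_rpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """The log2(1 + RPM) transform used ahead of tau/relative expression."""
    return np.log2(1.0 + matrix)


def relative_expression(rpm: pd.DataFrame) -> pd.DataFrame:
    """Row-scale log2(1+RPM) by each row's maximum; all-zero rows -> NaN."""
    transformed = log2_rpm(rpm)
    row_max = transformed.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = transformed.div(row_max, axis=0)
    scaled[row_max == 0] = np.nan
    return scaled


def replicate_mean_by_tissue(
    matrix: pd.DataFrame, metadata: pd.DataFrame, tissues: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean RPM per tissue (columns) over each tissue's replicate libraries."""
    if tissues is None:
        tissues = list(dict.fromkeys(metadata["tissue"]))
    out = {}
    for tissue in tissues:
        libs = metadata.index[metadata["tissue"] == tissue]
        libs = [l for l in libs if l in matrix.columns]
        if not libs:
            raise ValueError(f"tissue {tissue!r} has no libraries in the matrix")
        out[tissue] = matrix[libs].mean(axis=1)
    return pd.DataFrame(out)


def tissue_specific_sets(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    tissue_subset: Sequence[str],
    min_rpm: float = 1.0,
) -> dict[str, set[str]]:
    """Constitutive and per-tissue-specific feature sets over a tissue subset.

    Constitutive: replicate-mean RPM >= ``min_rpm`` in every tissue of the
    subset.  Tissue-specific: the threshold is met in exactly one tissue.
    Returns ``{"constitutive": ..., "specific:<tissue>": ...}``.
    """
    means = replicate_mean_by_tissue(matrix, metadata, tissue_subset)
    over = means >= min_rpm
    n_over = over.sum(axis=1)
    out: dict[str, set[str]] = {
        "constitutive": set(means.index[n_over == len(tissue_subset)])
    }
    single = n_over == 1
    for tissue in tissue_subset:
        out[f"specific:{tissue}"] = set(means.index[single & over[tissue]])
    return out


def read_metadata(path) -> pd.DataFrame:
    """Sample-metadata TSV: library_id, tissue, genotype, replicate, dataset."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "tissue", "genotype", "replicate", "dataset"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta.set_index("library_id")
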