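"""Cross-library count matrices.

Combines per-library ledgers into the four matrices the workflow emits:
the four-category family table, the element/gene unique table, the
family sum (u_te.fam + m_te.fam), and the per-family proportion of that
sum contributed by unique mappers.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import TEFamily
from .assign import FAMILY_COLUMNS, LibraryCounts

_CATEGORY_ATTR = {
    "u_te.fam": "u_te_fam",
    "u_te.g": "u_te_g",
    "m_te.fam": "m_te_fam",
    "m_te.g": "m_te_g",
}


def _check_library_ids(libraries: Sequence[LibraryCounts]) -> list[str]:
    if not libraries:
        raise ValueError("at least one library is required")
    ids = [lib.library_id for lib in libraries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate library names: {dupes}")
    return ids


def combine_family_counts(
    libraries: Sequence[LibraryCounts],
    registry: Mapping[str, TEFamily] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(four-column matrix, family-sum matrix, proportion-unique matrix).

    The four-column matrix has MultiIndex columns (library, category).
    With a family registry supplied, never-observed families are emitted
    as zero rows (the "not expressed" denominator needs them); without
    one they are dropped.  prop_unique is NaN where the family sum is 0.
    """
    ids = _check_library_ids(libraries)
    if registry is not None:
        families = sorted(registry)
    else:
        families = sorted(
            set().union(
                *(
                    set(lib.u_te_fam) | set(lib.u_te_g) | set(lib.m_te_fam) | set(lib.m_te_g)
                    for lib in libraries
                )
            )
        )
    columns = pd.MultiIndex.from_product([ids, FAMILY_COLUMNS], names=["library", "category"])
    data = np.zeros((len(families), len(columns)), dtype=np.int64)
    fam_pos = {f: i for i, f in enumerate(families)}
    for j, lib in enumerate(libraries):
        for k, cat in enumerate(FAMILY_COLUMNS):
            for fam, n in getattr(lib, _CATEGORY_ATTR[cat]).items():
                if fam in fam_pos:
                    data[fam_pos[fam], j * len(FAMILY_COLUMNS) + k] = n
    four_col = pd.DataFrame(data, index=pd.Index(families, name="family"), columns=columns)

    fam_sum = (
        four_col.xs("u_te.fam", axis=1, level="category")
        + four_col.xs("m_te.fam", axis=1, level="category")
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = four_col.xs("u_te.fam", axis=1, level="category") / fam_sum
    return four_col, fam_sum, prop


def combine_element_counts(
    libraries: Sequence[LibraryCounts],
) -> pd.DataFrame:
    """Element+gene matrix with (library, {unique, te.g}) columns."""
    ids = _check_library_ids(libraries)
    feats: set[str] = set()
    for lib in libraries:
        feats |= set(lib.element_unique) | set(lib.element_te_g)
        feats |= set(lib.gene_unique) | set(lib.gene_te_g)
    features = sorted(feats)
    columns = pd.MultiIndex.from_product([ids, ["unique", "te.g"]], names=["library", "category"])
    data = np.zeros((len(features), len(columns)), dtype=np.int64)
    pos = {f: i for i, f in enumerate(features)}
    for j, lib in enumerate(libraries):
        for feat, n in {**lib.gene_unique, **lib.element_unique}.items():
            data[pos[feat], 2 * j] = n
        for feat, n in {**lib.gene_te_g, **lib.element_te_g}.items():
            data[pos[feat], 2 * j + 1] = n
    return pd.DataFrame(data, index=pd.Index(features, name="feature"), columns=columns)


def gene_unique_matrix(libraries: Sequence[LibraryCounts]) -> pd.DataFrame:
    """Genes x libraries matrix of unique counts (RPM denominator input)."""
    ids = _check_library_ids(libraries)
    genes = sorted(set().union(*(set(lib.gene_unique) for lib in libraries)))
    data = np.zeros((len(genes), len(ids)), dtype=np.int64)
    pos = {g: i for i, g in enumerate(genes)}
    for j, lib in enumerate(libraries):
        for g, n in lib.gene_unique.items():
            data[pos[g], j] = n
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=ids)


def summary_table(libraries: Sequence[LibraryCounts]) -> pd.DataFrame:
    """Per-library category totals (rows = libraries)."""
    ids = _check_library_ids(libraries)
    return pd.DataFrame([lib.summary for lib in libraries], index=pd.Index(ids, name="library"))


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def _flatten_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if isinstance(out.columns, pd.MultiIndex):
        out.columns = [":".join(map(str, c)) for c in out.columns]
    return out


def write_tables(
    outdir: str | Path,
    four_col: pd.DataFrame,
    element: pd.DataFrame,
    fam_sum: pd.DataFrame,
    prop_unique: pd.DataFrame,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _flatten_columns(four_col).to_csv(outdir / "multi_combined_counts.txt", sep="\t")
    _flatten_columns(element).to_csv(outdir / "element_combined_counts.txt", sep="\t")
    fam_sum.to_csv(outdir / "family_sum_combined_counts.txt", sep="\t")
    prop_unique.to_csv(outdir / "family_prop_unique.txt", sep="\t", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix written by :func:`write_tables` (flat columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if any(":" in str(c) for c in df.columns):
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(str(c).split(":", 1)) for c in df.columns],
            names=["library", "category"],
        )
    return df
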