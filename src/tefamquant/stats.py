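"""Statistical layer: tissue specificity, unimodality, differential
expression, and hybrid additivity.

The differential-expression test is a deliberately simple, fully
specified stand-in for the DESeq2 workflow it replaces: median-of-ratios
size factors, a per-feature method-of-moments negative-binomial
dispersion, a Wald test on the log2 fold-change of normalized group
means, and Benjamini-Hochberg adjustment.  The thresholds applied
downstream (|FC| >= 2, FDR < 0.05) are the method; the estimator details
are not.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._dip import dip_statistic

__all__ = [
    "TauResult",
    "DipResult",
    "DEResult",
    "TrioResult",
    "tau",
    "tau_table",
    "dip_statistic",
    "dip_null_distribution",
    "dip_test",
    "bh_adjust",
    "size_factors",
    "nb_differential_test",
    "call_de_families",
    "midparent_deviation",
    "classify_additivity",
    "ril_segregation",
]


# ---------------------------------------------------------------------------
# tau tissue-specificity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TauResult:
    feature: str
    tau: float | None
    n_conditions: int


def tau(profile: Sequence[float], feature: str = "") -> TauResult:
    """Tissue-specificity index of a per-condition expression profile.

    tau = sum_i(1 - x_i / max(x)) / (N - 1) over N >= 2 conditions of
    non-negative (already transformed) expression values; ``None`` when
    the profile is all-zero.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau requires a 1-D profile with >= 2 conditions")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("tau requires finite, non-negative values")
    m = x.max()
    if m == 0:
        return TauResult(feature, None, x.size)
    val = float(np.sum(1.0 - x / m) / (x.size - 1))
    return TauResult(feature, val, x.size)


def tau_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise tau of a features x conditions matrix of transformed values."""
    results = [tau(matrix.loc[f].to_numpy(), feature=str(f)) for f in matrix.index]
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "tau": [np.nan if r.tau is None else r.tau for r in results],
            "n_conditions": [r.n_conditions for r in results],
        }
    ).set_index("feature")


# ---------------------------------------------------------------------------
# Dip test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DipResult:
    statistic: float
    p_value: float
    n_sim: int
    seed: int
    n: int
    unimodal_call: bool


def dip_null_distribution(
    n: int, n_sim: int, seed: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Dip statistics of ``n_sim`` uniform(0,1) samples of size ``n``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.empty(n_sim)
    for i in range(n_sim):
        out[i] = dip_statistic(np.sort(rng.uniform(size=n)))
    return out


def dip_test(
    sample: Sequence[float],
    n_sim: int = 2000,
    seed: int = 0,
    call_convention: Literal["standard", "p_lt_alpha_is_unimodal"] = "standard",
    alpha: float = 0.05,
    null_dips: np.ndarray | None = None,
) -> DipResult:
    """Monte-Carlo dip test against uniform(0,1) samples of matched size.

    The p-value is the proportion of simulated uniform samples whose dip
    meets or exceeds the observed dip.  Under ``call_convention
    "standard"`` (null: unimodal) a small p rejects unimodality, so
    ``unimodal_call`` is ``p >= alpha``.  The convention
    ``"p_lt_alpha_is_unimodal"`` reproduces the originating study's
    operational rule verbatim (it labels a family unimodal when
    p < alpha) and is provided behind this explicit flag.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    x = np.asarray(sample, dtype=float)
    stat = dip_statistic(x)
    if null_dips is None:
        null_dips = dip_null_distribution(x.size, n_sim, seed)
    else:
        null_dips = np.asarray(null_dips, dtype=float)
        n_sim = null_dips.size
    p = float(np.mean(null_dips >= stat))
    if call_convention == "standard":
        unimodal = p >= alpha
    elif call_convention == "p_lt_alpha_is_unimodal":
        unimodal = p < alpha
    else:
        raise ValueError(f"unknown call convention {call_convention!r}")
    return DipResult(stat, p, int(n_sim), int(seed), int(x.size), bool(unimodal))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested features) are passed through unchanged and do
    not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# Size factors + NB differential test
# ---------------------------------------------------------------------------

def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features x libraries counts).

    For each library, the median over features positive in *all*
    libraries of count / geometric-mean-across-libraries.
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("size factors require >= 2 libraries")
    counts = count_matrix.to_numpy(dtype=float)
    all_pos = np.all(counts > 0, axis=1)
    if not all_pos.any():
        raise ValueError("no feature has positive counts in every library")
    sub = counts[all_pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=count_matrix.columns, name="size_factor")


@dataclass(frozen=True)
class DEResult:
    feature: str
    log2fc: float
    p: float
    padj: float
    call: Literal["up", "down", "ns"]


def nb_differential_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    sf: pd.Series | None = None,
    pseudocount: float = 0.5,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Per-feature NB Wald test of group B vs group A counts.

    ``log2fc`` is log2((mean normalized B + pc) / (mean normalized A + pc)),
    so positive values mean higher in B.  With fewer than 2 replicates in
    either group the dispersion falls back to Poisson (alpha = 0).
    All-zero features get call ``ns`` with missing p.
    """
    if not group_a.index.equals(group_b.index):
        raise ValueError("groups must share the feature axis")
    joint = pd.concat([group_a, group_b], axis=1)
    if sf is None:
        sf = size_factors(joint)
    sf_a = sf.loc[group_a.columns].to_numpy(dtype=float)
    sf_b = sf.loc[group_b.columns].to_numpy(dtype=float)
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    qa = a / sf_a  # normalized counts
    qb = b / sf_b
    na, nb = qa.shape[1], qb.shape[1]
    mu_a = qa.mean(axis=1)
    mu_b = qb.mean(axis=1)

    log2fc = np.log2((mu_b + pseudocount) / (mu_a + pseudocount))

    # method-of-moments dispersion pooled across the two groups
    if na >= 2 and nb >= 2:
        var_w = (qa.var(axis=1, ddof=1) * (na - 1) + qb.var(axis=1, ddof=1) * (nb - 1)) / (
            na + nb - 2
        )
        mu_pool = (mu_a * na + mu_b * nb) / (na + nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(mu_pool > 0, (var_w - mu_pool) / mu_pool**2, 0.0)
        alpha = np.clip(alpha, 0.0, None)
    else:
        alpha = np.zeros(qa.shape[0])

    # delta-method variance of log2(mean normalized + pc) per group
    def _se2(mu: np.ndarray, sfs: np.ndarray, n: int) -> np.ndarray:
        var_mean = mu * np.sum(1.0 / sfs) / n**2 + alpha * mu**2 / n
        return var_mean / ((mu + pseudocount) ** 2 * math.log(2.0) ** 2)

    se = np.sqrt(_se2(mu_a, sf_a, na) + _se2(mu_b, sf_b, nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    tested = (a.sum(axis=1) + b.sum(axis=1)) > 0
    p = np.where(tested, p, np.nan)
    padj = bh_adjust(p)

    call = np.full(len(p), "ns", dtype=object)
    sig = tested & (padj < fdr_max) & (np.abs(log2fc) >= np.log2(fc_min))
    call[sig & (log2fc > 0)] = "up"
    call[sig & (log2fc < 0)] = "down"

    return pd.DataFrame(
        {
            "log2fc": np.where(tested, log2fc, 0.0),
            "p": p,
            "padj": padj,
            "call": call,
        },
        index=group_a.index,
    )


def call_de_families(
    results: pd.DataFrame,
    expressed_a: Iterable[str] | None = None,
    expressed_b: Iterable[str] | None = None,
) -> dict[str, list[str]]:
    """DE family sets from an :func:`nb_differential_test` table.

    ``up_in_b``/``up_in_a`` follow the sign convention of ``log2fc``
    (positive = higher in B).  Exclusive sets additionally require the
    family to be expression-called in exactly one group.
    """
    up_in_b = sorted(results.index[results["call"] == "up"])
    up_in_a = sorted(results.index[results["call"] == "down"])
    out = {"up_in_a": up_in_a, "up_in_b": up_in_b}
    if expressed_a is not None and expressed_b is not None:
        ea, eb = set(expressed_a), set(expressed_b)
        out["exclusive_to_a"] = sorted(f for f in up_in_a if f in ea and f not in eb)
        out["exclusive_to_b"] = sorted(f for f in up_in_b if f in eb and f not in ea)
    return out


# ---------------------------------------------------------------------------
# Hybrid additivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrioResult:
    feature: str
    deviation: float
    klass: Literal["above_both", "below_both", "additive_range"]


def midparent_deviation(
    f1: float, p1: float, p2: float, pseudocount: float = 0.5
) -> float:
    """log2 of hybrid expression over the mid-parent mean."""
    mid = (p1 + p2) / 2.0
    return math.log2((f1 + pseudocount) / (mid + pseudocount))


def classify_additivity(
    de_vs_p1: pd.DataFrame,
    de_vs_p2: pd.DataFrame,
    f1_rpm: pd.Series | None = None,
    p1_rpm: pd.Series | None = None,
    p2_rpm: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Non-additivity classes from the two F1-vs-parent contrasts.

    Both inputs must use the convention log2fc > 0 == higher in F1.
    ``above_both`` requires an "up" call against each parent;
    ``below_both`` a "down" call against each; everything else is within
    the additive range.
    """
    common = de_vs_p1.index.intersection(de_vs_p2.index)
    skipped = de_vs_p1.index.symmetric_difference(de_vs_p2.index)
    if len(skipped):
        import logging

        logging.getLogger(__name__).warning(
            "%d features missing one contrast; skipped", len(skipped)
        )
    c1 = de_vs_p1.loc[common, "call"]
    c2 = de_vs_p2.loc[common, "call"]
    klass = pd.Series("additive_range", index=common, dtype=object)
    klass[(c1 == "up") & (c2 == "up")] = "above_both"
    klass[(c1 == "down") & (c2 == "down")] = "below_both"
    out = pd.DataFrame({"class": klass})
    if f1_rpm is not None and p1_rpm is not None and p2_rpm is not None:
        out["deviation"] = [
            midparent_deviation(
                float(f1_rpm.get(f, 0.0)),
                float(p1_rpm.get(f, 0.0)),
                float(p2_rpm.get(f, 0.0)),
                pseudocount,
            )
            for f in common
        ]
    return out


def nonadditive_counts(per_tissue_classes: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-tissue tally of non-additive families (above/below both parents)."""
    rows = []
    for tissue, df in per_tissue_classes.items():
        rows.append(
            {
                "tissue": tissue,
                "above_both": int((df["class"] == "above_both").sum()),
                "below_both": int((df["class"] == "below_both").sum()),
            }
        )
    out = pd.DataFrame(rows).set_index("tissue")
    out["non_additive"] = out["above_both"] + out["below_both"]
    return out


# ---------------------------------------------------------------------------
# RIL segregation
# ---------------------------------------------------------------------------

def ril_segregation(
    matrix: pd.DataFrame,
    de_families: Iterable[str],
    n_sim: int = 2000,
    seed: int = 0,
    min_rpm: float = 1.0,
    call_convention: Literal["standard", "p_lt_alpha_is_unimodal"] = "standard",
) -> pd.DataFrame:
    """Dip-test each DE family's expression across a RIL panel.

    ``matrix`` is families x RIL libraries (RPM).  Returns dip statistic,
    Monte-Carlo p-value, the modality call under the requested
    convention, and the fraction of RILs with RPM >= ``min_rpm`` (the
    segregation-presence statistic).  Families absent from the matrix are
    skipped.
    """
    if matrix.shape[1] < 20:
        raise ValueError("RIL segregation analysis requires >= 20 libraries")
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for fam in de_families:
        if fam not in matrix.index:
            continue
        vals = matrix.loc[fam].to_numpy(dtype=float)
        n = vals.size
        if n not in null_cache:
            null_cache[n] = dip_null_distribution(n, n_sim, seed, rng=rng)
        res = dip_test(
            vals,
            n_sim=n_sim,
            seed=seed,
            call_convention=call_convention,
            null_dips=null_cache[n],
        )
        rows.append(
            {
                "feature": fam,
                "dip": res.statistic,
                "p": res.p_value,
                "unimodal": res.unimodal_call,
                "presence_fraction": float(np.mean(vals >= min_rpm)),
            }
        )
    return pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["dip", "p", "unimodal", "presence_fraction"]
    )
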