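"""Hartigan & Hartigan dip statistic.

Computes the maximum distance between the empirical CDF and the closest
unimodal CDF via the classical iterative greatest-convex-minorant /
least-concave-majorant construction over the sorted sample.  The
statistic is bounded below by 1/(2n) for samples with at least two
distinct values and is invariant under strictly increasing (in
particular affine) transformations of the data.

A numba-jitted kernel is used when numba is importable; the pure-Python
kernel is the reference implementation and is always available.
"""
from __future__ import annotations

import numpy as np


def _dip_kernel(x: np.ndarray) -> float:
    """Dip of a sorted 1-based sample ``x[1..n]`` (``x[0]`` is padding)."""
    n = x.shape[0] - 1
    low = 1
    high = n
    dip = 1.0  # in 2n*dip units; yields the exact 1/(2n) lower bound

    if n < 2 or x[n] == x[1]:
        return dip / (2.0 * n)

    # Greatest convex minorant touch predecessors over the full sample.
    mn = np.empty(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (
                j - mnj
            ):
                break
            mn[j] = mnmnj

    # Least concave majorant touch successors.
    mj = np.empty(n + 2, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (
                k - mjk
            ):
                break
            mj[k] = mjmjk

    gcm = np.empty(n + 2, dtype=np.int64)
    lcm = np.empty(n + 2, dtype=np.int64)

    while True:
        # GCM change points from high down to low; LCM from low up to high.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        ix = ig - 1

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i
        iv = 2

        # Largest distance between the GCM and the LCM over [low, high].
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next change point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # Dip within the convex-minorant side.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Dip within the concave-majorant side.
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew

        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


try:  # optional speedup; the pure-Python kernel is the reference
    from numba import njit

    _dip_kernel_fast = njit(cache=False, fastmath=False)(_dip_kernel)
except Exception:  # pragma: no cover - numba always present in CI image
    _dip_kernel_fast = None


def dip_statistic_sorted(x_sorted: np.ndarray, use_fast: bool = True) -> float:
    """Dip of an already-sorted 1-D float array."""
    n = x_sorted.shape[0]
    if n < 2:
        raise ValueError("dip statistic requires at least 2 observations")
    padded = np.empty(n + 1, dtype=np.float64)
    padded[0] = np.nan
    padded[1:] = x_sorted
    if use_fast and _dip_kernel_fast is not None:
        return float(_dip_kernel_fast(padded))
    return float(_dip_kernel(padded))


def dip_statistic(sample, use_fast: bool = True) -> float:
    """Dip statistic of an arbitrary numeric sample (n >= 2)."""
    x = np.asarray(sample, dtype=np.float64)
    if x.ndim != 1:
        x = x.ravel()
    if x.shape[0] < 2:
        raise ValueError("dip statistic requires at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite values")
    return dip_statistic_sorted(np.sort(x), use_fast=use_fast)
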