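"""Smoothing and between-library normalization for count data.

Contains the local-linear (loess) smoother used by the abundance filters and
dispersion trends, the MA-style loess normalization that converts
intensity-dependent biases between Hi-C libraries into GLM offsets, and TMM
scaling factors for RNA-seq style count matrices.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import log_cpm

logger = logging.getLogger(__name__)

__all__ = ["loess_fit", "loess_normalization_offsets", "tmm_factors"]

LN2 = np.log(2.0)


def _window_starts(xs: np.ndarray, r: int) -> np.ndarray:
    """For each point of sorted ``xs``, the start of the length-``r`` contiguous
    window of nearest neighbours (minimizing the maximum distance)."""
    n = len(xs)
    starts = np.empty(n, dtype=np.int64)
    s = 0
    for i in range(n):
        lo = max(0, i - r + 1)
        hi = min(i, n - r)
        s = min(max(s, lo), hi)
        # slide right while it shrinks the window's maximum distance
        while s < hi and max(xs[i] - xs[s + 1], xs[s + r] - xs[i]) < max(
            xs[i] - xs[s], xs[s + r - 1] - xs[i]
        ):
            s += 1
        starts[i] = s
    return starts


def _loess_at(xs, ys, starts, r, targets_idx, chunk=2048, rw=None):
    """Tricube-weighted local-linear fit at sorted points ``targets_idx``.

    ``rw`` are optional per-point robustness weights multiplying the tricube
    kernel.
    """
    fitted = np.empty(len(targets_idx), dtype=float)
    for c0 in range(0, len(targets_idx), chunk):
        idx = targets_idx[c0 : c0 + chunk]
        win = starts[idx][:, None] + np.arange(r)[None, :]
        xw = xs[win]
        yw = ys[win]
        x0 = xs[idx][:, None]
        d = np.abs(xw - x0)
        dmax = d.max(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(dmax > 0, (1 - np.clip(d / dmax, 0, 1) ** 3) ** 3, 1.0)
        if rw is not None:
            w = w * rw[win]
        xc = xw - x0  # centre so the fitted value is the intercept
        sw = w.sum(axis=1)
        swx = (w * xc).sum(axis=1)
        swy = (w * yw).sum(axis=1)
        swxx = (w * xc * xc).sum(axis=1)
        swxy = (w * xc * yw).sum(axis=1)
        denom = sw * swxx - swx**2
        ok = denom > 1e-12 * np.maximum(sw * swxx, 1e-300)
        out = np.where(
            ok,
            (swy * swxx - swx * swxy) / np.where(ok, denom, 1.0),
            swy / sw,
        )
        fitted[c0 : c0 + chunk] = out
    return fitted


def loess_fit(
    x, y, span: float = 0.3, grid: int | None = None, robust_iter: int = 0
) -> np.ndarray:
    """Local linear regression with tricube weights, evaluated at ``x``.

    Each point is fitted from its ``ceil(span * n)`` nearest neighbours
    (widened to 3 when the span window would be smaller).  With ``grid`` set,
    the curve is fitted exactly at that many quantile points of ``x`` and
    linearly interpolated in between -- the standard lowess "delta" shortcut
    for large inputs.  Exact on affine data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"loess_fit requires >= 10 points, got {n}")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    r = int(np.ceil(span * n))
    if r < 3:
        logger.info("loess window of %d point(s) widened to 3", r)
        r = 3
    r = min(r, n)

    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    starts = _window_starts(xs, r)

    def one_pass(rw):
        if grid is None or grid >= n:
            return _loess_at(xs, ys, starts, r, np.arange(n), rw=rw)
        gidx = np.unique(np.linspace(0, n - 1, grid).round().astype(int))
        fg = _loess_at(xs, ys, starts, r, gidx, rw=rw)
        return np.interp(xs, xs[gidx], fg)

    fitted_sorted = one_pass(None)
    for _ in range(robust_iter):
        # lowess-style bisquare robustness weights on the residuals
        resid = ys - fitted_sorted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        rw = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
        fitted_sorted = one_pass(rw)

    fitted = np.empty(n, dtype=float)
    fitted[order] = fitted_sorted
    return fitted


def loess_normalization_offsets(
    counts,
    lib_sizes,
    strata=None,
    span: float = 0.3,
    prior: float = 0.5,
    min_stratum: int = 50,
    grid: int | None = 200,
    robust_iter: int = 2,
) -> np.ndarray:
    """Loess-based MA normalization offsets on the natural-log scale.

    Within each stratum, each library's log2CPM deviation (M) from the
    per-observation mean abundance (A) is smoothed against A with a robust
    (bisquare-reweighted) loess, so that genuinely differential features do
    not drag the technical trend; the fitted trends, centred so they sum to
    zero across libraries per observation, become GLM offsets (to be added to
    ``log(lib_size)``).  Strata with fewer than ``min_stratum`` observations
    fall back to a constant median offset.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be (observations, >=2 libraries)")
    lc = log_cpm(counts, lib_sizes, prior=prior)
    abundance = lc.mean(axis=1)
    m = lc - abundance[:, None]

    if strata is None:
        strata = np.zeros(len(counts), dtype=int)
    strata = np.asarray(strata)
    offsets = np.zeros_like(m)
    for s in np.unique(strata):
        sel = strata == s
        nsel = int(sel.sum())
        if nsel < min_stratum:
            logger.info(
                "stratum %r has %d observation(s) < %d: constant median offset",
                s, nsel, min_stratum,
            )
            offsets[sel] = np.median(m[sel], axis=0, keepdims=True)
            continue
        a = abundance[sel]
        for j in range(m.shape[1]):
            offsets[sel, j] = loess_fit(
                a, m[sel, j], span=span, grid=grid, robust_iter=robust_iter
            )
    offsets -= offsets.mean(axis=1, keepdims=True)
    return offsets * LN2


def tmm_factors(
    counts,
    lib_sizes=None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    ref_column: int | None = None,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean normalized to 1.

    M values (log2 ratio vs the reference library) are trimmed two-sided by
    ``logratio_trim`` and A values (average abundance) by ``sum_trim``; the
    factor is the precision-weighted mean of the surviving M values.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be (features, >=2 libraries)")
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("a library has all-zero counts")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)

    if ref_column is None:
        # library whose upper-quartile CPM is closest to the mean upper quartile
        uq = np.array(
            [np.quantile(counts[:, j] / lib_sizes[j], 0.75) for j in range(counts.shape[1])]
        )
        ref_column = int(np.argmin(np.abs(uq - uq.mean())))

    yr = counts[:, ref_column]
    nr = lib_sizes[ref_column]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_column:
            continue
        y = counts[:, j]
        n = lib_sizes[j]
        keep = (y > 0) & (yr > 0)
        if keep.sum() == 0:
            continue
        m = np.log2((y[keep] / n) / (yr[keep] / nr))
        a = 0.5 * np.log2((y[keep] / n) * (yr[keep] / nr))
        w = (n - y[keep]) / (n * y[keep]) + (nr - yr[keep]) / (nr * yr[keep])

        k = len(m)
        mrank = m.argsort().argsort()
        arank = a.argsort().argsort()
        lo_m, hi_m = np.floor(k * logratio_trim) + 1, k - np.floor(k * logratio_trim)
        lo_a, hi_a = np.floor(k * sum_trim) + 1, k - np.floor(k * sum_trim)
        keep2 = (
            (mrank + 1 >= lo_m) & (mrank + 1 <= hi_m)
            & (arank + 1 >= lo_a) & (arank + 1 <= hi_a)
        )
        if keep2.sum() == 0:
            continue
        f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
        factors[j] = 2.0**f
    return factors / np.exp(np.mean(np.log(factors)))
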