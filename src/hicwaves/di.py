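"""Differential interaction (DI) detection on binned Hi-C contact pairs.

Bin pairs are pre-filtered against the inter-chromosomal background ligation
frequency, normalized with distance-stratified loess offsets, tested per
consecutive stage transition with the quasi-likelihood framework, and merged
into clusters in two-dimensional interaction space with cluster-level FDR
control.  The module also provides the stratum-adjusted correlation
coefficient (SCC) reproducibility metric and the leading-log-fold-change
distances used for multidimensional-scaling overviews.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinPairCountTable, ave_log_cpm
from .normalize import loess_normalization_offsets
from .qlstats import (
    bh_adjust,
    estimate_trended_dispersion,
    fit_nb_glm,
    oneway_design,
    ql_f_test,
    squeeze_ql_dispersions,
    transition_contrasts,
)
from .simulate import pair_ids

logger = logging.getLogger(__name__)

__all__ = [
    "filter_by_background",
    "detect_dis",
    "DICluster",
    "cluster_dis",
    "scc",
    "mds_distances",
]


def filter_by_background(
    table: BinPairCountTable,
    background: BinPairCountTable,
    fold: float = 4.0,
    min_count: int = 10,
    per_library: bool = False,
    prior: float = 0.5,
) -> BinPairCountTable:
    """Keep pairs well above the inter-chromosomal ligation background.

    Drops diagonal and inter-chromosomal pairs and pairs with total count
    below ``min_count`` (per library when ``per_library``), then retains pairs
    whose average log2CPM strictly exceeds the background estimate plus
    ``log2(fold)``.  The background is the mean abundance of inter-chromosomal
    pairs in the coarse-bin table, rescaled to the working bin size by the
    bin-area ratio.
    """
    inter = ~background.is_intra
    if not inter.any():
        raise ValueError(
            "no inter-chromosomal pairs in the background table: provide "
            "counts from at least two chromosomes"
        )
    bg_ave = ave_log_cpm(background.counts[inter], background.lib_sizes, prior=prior)
    # rescale the coarse-bin abundance to the working bin size by bin area
    area_log2 = 2 * np.log2(table.binning.bin_width / background.binning.bin_width)
    threshold = float(np.mean(bg_ave)) + area_log2 + np.log2(fold)

    keep = table.is_intra & (table.anchor1 != table.anchor2)
    if per_library:
        keep &= (table.counts >= min_count).all(axis=1)
    else:
        keep &= table.counts.sum(axis=1) >= min_count
    ave = ave_log_cpm(table.counts, table.lib_sizes, prior=prior)
    keep &= ave > threshold
    return table.subset(keep)


def detect_dis(
    table: BinPairCountTable,
    alpha: float = 0.05,
    near_span: int = 1_500_000,
    norm_span: float = 0.3,
) -> dict[str, pd.DataFrame]:
    """Quasi-likelihood tests of every pair at each consecutive transition.

    Counts are normalized with loess offsets computed separately for pairs
    closer than ``near_span`` to the diagonal; the NB dispersion follows an
    abundance trend; QL dispersions are squeezed toward a second trend; BH
    adjustment is applied within each transition.  A DI is a pair with
    ``fdr < alpha``.
    """
    groups = [lib.group for lib in table.libraries]
    design, levels = oneway_design(groups)
    lib_sizes = table.lib_sizes

    strata = (table.spans < near_span).astype(int)
    norm = loess_normalization_offsets(
        table.counts, lib_sizes, strata=strata, span=norm_span
    )
    offsets = np.log(lib_sizes)[None, :] + norm

    abundance = ave_log_cpm(table.counts, lib_sizes)
    dispersion = _trended_dispersion(table.counts, design, offsets, abundance)
    fit = fit_nb_glm(
        table.counts, design, offsets=offsets, dispersion=dispersion,
        feature_ids=pair_ids(table),
    )
    ql = squeeze_ql_dispersions(fit, abundance=abundance, trend="loess")

    results = {}
    for name, contrast in transition_contrasts(levels).items():
        res = ql_f_test(fit, ql, contrast)
        res["di"] = res["fdr"] < alpha
        results[name] = res
    return results


def _trended_dispersion(counts, design, offsets, abundance, max_features: int = 2000):
    """Abundance-dependent dispersion, estimated on a deterministic feature
    subsample and interpolated along the abundance axis."""
    nf = counts.shape[0]
    if nf <= max_features:
        return estimate_trended_dispersion(counts, design, offsets, abundance)
    order = np.argsort(abundance, kind="stable")
    sub = order[np.linspace(0, nf - 1, max_features).round().astype(int)]
    disp_sub = estimate_trended_dispersion(
        counts[sub], design, offsets[sub], abundance[sub]
    )
    srt = np.argsort(abundance[sub], kind="stable")
    return np.exp(
        np.interp(abundance, abundance[sub][srt], np.log(disp_sub)[srt])
    )


@dataclass
class DICluster:
    """A merged group of adjacent significant bin pairs in interaction space."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    members: np.ndarray  # indices into the tested table
    n_up: int
    n_down: int
    p: float  # Sidak-corrected min member p
    fdr: float

    @property
    def direction(self) -> str:
        if self.n_up and not self.n_down:
            return "up"
        if self.n_down and not self.n_up:
            return "down"
        return "mixed"


def _build_clusters(table, idx, max_size_bins):
    """Single-linkage components of pairs adjacent in interaction space,
    partitioned so no bounding-box side exceeds ``max_size_bins`` bins."""
    a1, a2 = table.anchor1[idx], table.anchor2[idx]
    pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(a1, a2))}
    parent = list(range(len(idx)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for k, (i, j) in enumerate(zip(a1, a2)):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                other = pos.get((int(i) + di, int(j) + dj))
                if other is not None and other != k:
                    union(k, other)

    comps: dict[int, list[int]] = {}
    for k in range(len(idx)):
        comps.setdefault(find(k), []).append(k)

    clusters = []
    for members in comps.values():
        mi = a1[members]
        mj = a2[members]
        # partition oversized components on a grid of max_size_bins tiles
        ti = (mi - mi.min()) // max_size_bins
        tj = (mj - mj.min()) // max_size_bins
        for t in set(zip(ti.tolist(), tj.tolist())):
            sub = [m for m, key in zip(members, zip(ti.tolist(), tj.tolist())) if key == t]
            clusters.append(np.asarray(sub, dtype=int))
    return clusters


def cluster_dis(
    table: BinPairCountTable,
    results: pd.DataFrame,
    max_size: int = 500_000,
    cluster_alpha: float = 0.05,
) -> list[DICluster]:
    """Merge significant pairs into clusters with cluster-level FDR control.

    The pair-level p threshold is found by binary search over the observed
    p-values such that the estimated cluster-level FDR -- the mean of the
    Sidak-corrected minimum member p-values, an upper bound on the expected
    fraction of null clusters -- stays at or below ``cluster_alpha``.
    Components whose bounding box would exceed ``max_size`` per side are
    partitioned into max_size tiles.
    """
    p = results["p"].to_numpy()
    logfc = results["logFC"].to_numpy()
    bw = table.binning.bin_width
    max_size_bins = max(1, max_size // bw)

    def clusters_at(threshold):
        idx = np.flatnonzero(p <= threshold)
        if len(idx) == 0:
            return [], np.array([])
        cl = _build_clusters(table, idx, max_size_bins)
        pc = np.array(
            [1.0 - (1.0 - p[idx][m].min()) ** len(m) for m in cl]
        )
        return [(idx, m) for m in cl], pc

    candidates = np.unique(p)
    lo, hi = 0, len(candidates) - 1
    best_threshold = None
    while lo <= hi:
        mid = (lo + hi) // 2
        _, pc = clusters_at(candidates[mid])
        if len(pc) and pc.mean() <= cluster_alpha:
            best_threshold = candidates[mid]
            lo = mid + 1
        else:
            hi = mid - 1
    if best_threshold is None:
        return []

    built, pc = clusters_at(best_threshold)
    fdrs = bh_adjust(pc)
    b = table.binning
    out = []
    for ((idx, members), pcl, fdr) in zip(built, pc, fdrs):
        rows = idx[members]
        a1, a2 = table.anchor1[rows], table.anchor2[rows]
        out.append(
            DICluster(
                chrom1=str(b.chrom_of(a1[:1])[0]),
                start1=int(b.start[a1].min()),
                end1=int(b.end[a1].max()),
                chrom2=str(b.chrom_of(a2[:1])[0]),
                start2=int(b.start[a2].min()),
                end2=int(b.end[a2].max()),
                members=rows,
                n_up=int((logfc[rows] > 0).sum()),
                n_down=int((logfc[rows] < 0).sum()),
                p=float(pcl),
                fdr=float(fdr),
            )
        )
    return out


def scc(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    h: int = 3,
    max_dist: int = 5_000_000,
    resolution: int = 50_000,
) -> float:
    """Stratum-adjusted correlation coefficient between two contact matrices.

    Both matrices are mean-filter smoothed with half-width ``h``; Pearson
    correlations are computed within each diagonal distance stratum up to
    ``max_dist`` and combined with weights ``N_k * sd_k(A) * sd_k(B)``.
    Degenerate (zero-variance) strata are skipped.
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    size = 2 * h + 1
    sa = ndimage.uniform_filter(a, size=size, mode="nearest")
    sb = ndimage.uniform_filter(b, size=size, mode="nearest")

    kmax = min(a.shape[0] - 1, max_dist // resolution)
    num = 0.0
    den = 0.0
    for k in range(1, kmax + 1):
        xa = np.diagonal(sa, k)
        xb = np.diagonal(sb, k)
        if len(xa) < 2:
            continue
        va, vb = xa.var(), xb.var()
        if va <= 0 or vb <= 0:
            logger.info("SCC stratum %d skipped (zero variance)", k)
            continue
        r = np.corrcoef(xa, xb)[0, 1]
        w = len(xa) * np.sqrt(va * vb)
        num += w * r
        den += w
    if den == 0:
        raise ValueError("no usable distance strata (all degenerate)")
    return float(num / den)


def mds_distances(log_cpm_matrix: np.ndarray, top: int = 500) -> np.ndarray:
    """Leading log-fold-change distances between libraries.

    Entry (i, j) is the root-mean-square of the ``top`` largest absolute
    log2 differences between libraries i and j (all features when fewer).
    """
    m = np.asarray(log_cpm_matrix, dtype=float)
    n = m.shape[1]
    k = min(top, m.shape[0])
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2 = (m[:, i] - m[:, j]) ** 2
            if k < len(d2):
                d2 = np.partition(d2, len(d2) - k)[-k:]
            out[i, j] = out[j, i] = np.sqrt(d2.mean())
    return out
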