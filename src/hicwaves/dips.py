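"""Differentially interacting promoters (DIPs).

The promoter-centric interrogation of Hi-C data: a 10 kb window is placed
around every retained TSS, all contacts between the window and 10 kb "second
regions" genome-wide are collected, interactions are filtered by a
distance-dependent abundance rule (loess of average log2CPM against log
distance plus a multiple of the mean absolute residual), aggregated into one
count per promoter per library, filtered for abundance, normalized with
loess offsets, and tested per stage transition with the quasi-likelihood
framework using a single common NB dispersion.  Significant promoters are
classified into {-1, 0, +1} patterns across the transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinPairCountTable, RegionSet, ave_log_cpm
from .normalize import loess_fit, loess_normalization_offsets
from .qlstats import (
    classify_patterns,
    estimate_common_dispersion,
    fit_nb_glm,
    oneway_design,
    ql_f_test,
    squeeze_ql_dispersions,
    transition_contrasts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterWindow",
    "define_promoter_windows",
    "connect_promoter_counts",
    "distance_abundance_filter",
    "aggregate_promoter_counts",
    "filter_promoters",
    "detect_dips",
    "DipResults",
]


@dataclass(frozen=True)
class PromoterWindow:
    """A 10 kb promoter window centred on the TSS (strand-aware)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int


def define_promoter_windows(
    genes: pd.DataFrame,
    chrom_sizes: dict,
    up: int = 5000,
    down: int = 5000,
    exclude_ids=(),
) -> list[PromoterWindow]:
    """Windows [TSS-up, TSS+down) on the plus strand (mirrored on minus).

    ``genes`` carries gene_id, chrom, tss and strand.  Genes on the exclusion
    list get no window; windows poking past a chromosome end are clipped.
    """
    exclude = set(exclude_ids)
    out = []
    for row in genes.itertuples():
        if row.gene_id in exclude:
            continue
        if row.strand == "+":
            start, end = row.tss - up, row.tss + down
        else:
            start, end = row.tss - down, row.tss + up
        size = chrom_sizes[row.chrom]
        if start < 0 or end > size:
            logger.info("promoter window of %s clipped to chromosome bounds", row.gene_id)
            start, end = max(start, 0), min(end, size)
        out.append(PromoterWindow(row.gene_id, row.chrom, row.tss, row.strand, start, end))
    return out


def connect_promoter_counts(
    contacts: BinPairCountTable,
    windows: list[PromoterWindow],
    blacklist: RegionSet | None = None,
    allow_double: bool = False,
) -> pd.DataFrame:
    """Collect promoter-window vs second-region interactions.

    Every intra-chromosomal pair with at least one anchor overlapping a
    window and at least one read is reported with its per-library counts.
    Inter-chromosomal pairs, pairs with a blacklisted anchor and
    self-interactions (both anchors in the same window) are dropped.  When a
    second region overlaps another promoter's window, the interaction is
    assigned to the promoter with the lower window start only, unless
    ``allow_double``.

    Returns a tidy frame: gene_id, chrom, second_start, second_end, span and
    one count column per library.
    """
    b = contacts.binning
    intra = contacts.is_intra
    keep = intra & (contacts.counts.sum(axis=1) > 0)
    if blacklist is not None and len(blacklist):
        for anchor in (contacts.anchor1, contacts.anchor2):
            keep &= ~blacklist.overlaps(
                b.chrom_of(anchor), b.start[anchor], b.end[anchor]
            )
    idx = np.flatnonzero(keep)
    a1, a2 = contacts.anchor1[idx], contacts.anchor2[idx]

    # map every bin to the windows overlapping it
    win_sorted = sorted(windows, key=lambda w: (w.chrom, w.start))
    bin_windows: dict[int, list[PromoterWindow]] = {}
    for w in win_sorted:
        lo = b.bin_index(w.chrom, w.start)
        hi = b.bin_index(w.chrom, min(w.end - 1, b.chrom_sizes[w.chrom] - 1))
        for bin_ix in range(lo, hi + 1):
            bin_windows.setdefault(bin_ix, []).append(w)

    rows = []
    counts_rows = []
    mid = b.mid
    for k, (i, j) in enumerate(zip(a1, a2)):
        w1 = bin_windows.get(int(i), [])
        w2 = bin_windows.get(int(j), [])
        if not w1 and not w2:
            continue
        if w1 and w2 and any(w in w2 for w in w1):
            continue  # self-interaction within one window
        assignments = []
        if w1:
            assignments.append((w1[0], j))
        if w2:
            assignments.append((w2[0], i))
        if len(assignments) == 2 and not allow_double:
            assignments.sort(key=lambda t: (t[0].chrom, t[0].start))
            assignments = assignments[:1]
        for w, second in assignments:
            rows.append(
                (
                    w.gene_id,
                    w.chrom,
                    int(b.start[second]),
                    int(b.end[second]),
                    float(abs((w.start + w.end) // 2 - mid[second])),
                )
            )
            counts_rows.append(contacts.counts[idx[k]])
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "second_start", "second_end", "span"]
    )
    cm = (
        np.vstack(counts_rows)
        if counts_rows
        else np.empty((0, contacts.n_libraries), dtype=np.int64)
    )
    for c, lib in enumerate(contacts.libraries):
        df[lib.name] = cm[:, c] if len(df) else np.array([], dtype=np.int64)
    df.attrs["lib_names"] = [lib.name for lib in contacts.libraries]
    df.attrs["lib_sizes"] = contacts.lib_sizes.tolist()
    return df


def _interaction_counts(table: pd.DataFrame) -> np.ndarray:
    return table[table.attrs["lib_names"]].to_numpy()


def distance_abundance_filter(
    table: pd.DataFrame, span: float = 0.05, k: float = 2.0
) -> pd.DataFrame:
    """Keep interactions whose abundance clears the distance trend.

    A loess curve of average log2CPM against ``log10(genomic span + 1)`` is
    fitted over all interactions; an interaction is retained iff its average
    log2CPM strictly exceeds the fitted value plus ``k`` times the mean
    absolute loess residual.  ``k=2`` for the DIP analysis; ``k=3`` for the
    stricter motif-enrichment variant.
    """
    if len(table) < 10:
        raise ValueError("distance-abundance filter requires >= 10 interactions")
    counts = _interaction_counts(table)
    lib_sizes = np.asarray(table.attrs["lib_sizes"], dtype=float)
    abundance = ave_log_cpm(counts, lib_sizes)
    x = np.log10(table["span"].to_numpy() + 1.0)
    fitted = loess_fit(x, abundance, span=span, grid=400)
    resid_scale = np.mean(np.abs(abundance - fitted))
    keep = abundance > fitted + k * resid_scale
    out = table.loc[keep].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out


def aggregate_promoter_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Sum retained interaction counts per promoter per library.

    Promoters with no retained interactions are absent from the matrix.
    """
    lib_names = table.attrs["lib_names"]
    out = table.groupby("gene_id", sort=True)[lib_names].sum()
    out.attrs = dict(table.attrs)
    # downstream filtering/normalization treats the aggregated matrix as its
    # own count data set, so library sizes become its column totals
    out.attrs["lib_sizes"] = out.to_numpy().sum(axis=0).astype(float).tolist()
    return out


def filter_promoters(
    matrix: pd.DataFrame,
    groups,
    min_count: int = 200,
    min_total: int = 200,
    lib_sizes=None,
    exclude_ids=(),
) -> pd.DataFrame:
    """Abundance filter for aggregated promoter counts.

    Keeps promoters whose CPM exceeds the CPM equivalent of ``min_count`` at
    the median library size in at least as many libraries as the smallest
    group, and whose total count reaches ``min_total``; excluded gene ids are
    dropped.
    """
    counts = matrix.to_numpy(dtype=float)
    if lib_sizes is None:
        lib_sizes = np.asarray(matrix.attrs.get("lib_sizes", counts.sum(axis=0)), float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    groups = list(groups)
    min_group = min(pd.Series(groups).value_counts())
    cpm_cutoff = min_count / np.median(lib_sizes) * 1e6
    cpm = counts / lib_sizes[None, :] * 1e6
    keep = (
        ((cpm >= cpm_cutoff).sum(axis=1) >= min_group)
        & (counts.sum(axis=1) >= min_total)
        & ~matrix.index.isin(set(exclude_ids))
    )
    if not keep.any():
        raise ValueError(
            "no promoter passes the abundance filter; check min_count/min_total "
            f"against the observed totals (max {counts.sum(axis=1).max():.0f})"
        )
    out = matrix.loc[keep]
    out.attrs = dict(matrix.attrs)
    return out


@dataclass
class DipResults:
    """Per-transition differential results plus the pattern classification."""

    per_transition: dict[str, pd.DataFrame]
    patterns: pd.DataFrame
    dispersion: float
    norm_offsets: np.ndarray


def detect_dips(
    matrix: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    norm_span: float = 0.3,
) -> DipResults:
    """Quasi-likelihood DIP tests per consecutive transition + patterns.

    The aggregated matrix is normalized with loess offsets, a single common
    NB dispersion is estimated across promoters (no abundance trend, matching
    the promoter analysis design), QL dispersions are squeezed toward a
    constant, and each transition is tested with the moderated QL F-test
    (df 1, i.e. a moderated t-test).  DIP = fdr strictly below ``alpha``.
    """
    counts = matrix.to_numpy(dtype=float)
    lib_sizes = np.asarray(matrix.attrs.get("lib_sizes", counts.sum(axis=0)), float)
    design, levels = oneway_design(list(groups))

    norm = loess_normalization_offsets(counts, lib_sizes, span=norm_span)
    offsets = np.log(lib_sizes)[None, :] + norm

    dispersion = estimate_common_dispersion(counts, design, offsets)
    fit = fit_nb_glm(
        counts, design, offsets=offsets, dispersion=dispersion,
        feature_ids=matrix.index.to_numpy(),
    )
    ql = squeeze_ql_dispersions(fit, trend="none")

    results = {}
    for name, contrast in transition_contrasts(levels).items():
        res = ql_f_test(fit, ql, contrast)
        res["dip"] = res["fdr"] < alpha
        results[name] = res
    patterns = classify_patterns(results, alpha=alpha)
    return DipResults(results, patterns, float(dispersion), norm)
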