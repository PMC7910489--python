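"""Differential TAD boundaries (DTBs) from up/down intensity contrasts.

The strength of a putative TAD boundary at a genomic region is summarised by
the ratio of Hi-C read pairs anchored in the region that reach upstream
versus downstream (within a fixed flank).  A change of that ratio between
condition groups indicates a boundary strengthening or weakening.  Counts of
upstream- and downstream-reaching pairs per library enter one NB GLM per
region with library baseline terms and a per-stage up/down log-ratio
coefficient; the tested contrast is the change of the log-ratio between
consecutive stages, assessed with a fold-change-threshold (TREAT) QL test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinPairCountTable, ave_log_cpm
from .qlstats import (
    estimate_common_dispersion,
    fit_nb_glm,
    squeeze_ql_dispersions,
    treat_test,
)

__all__ = ["BoundaryContrast", "boundary_contrast_counts", "detect_dtbs"]


@dataclass
class BoundaryContrast:
    """Per-region upstream/downstream anchored read counts per library."""

    regions: pd.DataFrame  # chrom, start, end
    up: np.ndarray  # (n_regions, n_libraries)
    down: np.ndarray
    libraries: list

    @property
    def log_ratio(self) -> np.ndarray:
        """Display log2 up/down ratio with a half-count continuity correction."""
        return np.log2((self.up + 0.5) / (self.down + 0.5))


def boundary_contrast_counts(
    contacts: BinPairCountTable,
    region_width: int = 100_000,
    flank: int = 1_000_000,
) -> BoundaryContrast:
    """Count pairs anchored in each tiled region reaching up- or downstream.

    For every ``region_width`` tile, ``up`` counts pairs with one anchor in
    the region and the other anchor's midpoint within ``flank`` bp before the
    region start; ``down`` counts the analogue past the region end.  Regions
    within a flank of a chromosome end are dropped.  A qualifying pair
    contributes once to a given region (as up or down).
    """
    b = contacts.binning
    rows = []
    bounds = {}
    for chrom, size in b.chrom_sizes.items():
        n_r = size // region_width
        for r in range(n_r):
            start = r * region_width
            end = start + region_width
            if start - flank < 0 or end + flank > size:
                continue
            bounds[(chrom, start)] = len(rows)
            rows.append((chrom, start, end))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    nl = contacts.n_libraries
    up = np.zeros((len(rows), nl), dtype=np.int64)
    down = np.zeros((len(rows), nl), dtype=np.int64)

    intra = contacts.is_intra
    mid = b.mid
    a1, a2 = contacts.anchor1[intra], contacts.anchor2[intra]
    counts = contacts.counts[intra]
    chroms = b.chrom_of(a1)
    m1, m2 = mid[a1], mid[a2]  # m1 >= m2 in canonical order within a chrom
    for anchor_mid, other_mid in ((m1, m2), (m2, m1)):
        region_start = (anchor_mid // region_width) * region_width
        upstream = (other_mid >= region_start - flank) & (other_mid < region_start)
        downstream = (other_mid >= region_start + region_width) & (
            other_mid < region_start + region_width + flank
        )
        for k in np.flatnonzero(upstream | downstream):
            ridx = bounds.get((chroms[k], int(region_start[k])))
            if ridx is None:
                continue
            target = up if upstream[k] else down
            target[ridx] += counts[k]
    return BoundaryContrast(regions, up, down, list(contacts.libraries))


def _ratio_design(libraries, stages):
    """Design for stacked (up, down) observations: per-library baselines plus
    a per-stage coefficient on the upstream observations, so that stage
    coefficient = natural-log up/down ratio in that stage."""
    nl = len(libraries)
    ns = len(stages)
    X = np.zeros((2 * nl, nl + ns))
    for i, lib in enumerate(libraries):
        s = stages.index(lib.group)
        X[i, i] = 1.0  # up observation, library baseline
        X[i, nl + s] = 1.0  # ratio coefficient
        X[nl + i, i] = 1.0  # down observation
    return X


def detect_dtbs(
    contrasts: BoundaryContrast,
    fc_threshold: float = 1.1,
    alpha: float = 0.05,
    min_logcpm: float = 1.0,
) -> pd.DataFrame:
    """TREAT tests for changes of boundary ratio between consecutive stages.

    Low-abundance regions (average log2CPM of the stacked counts below
    ``min_logcpm``) are removed; each transition's contrast is the change in
    the per-stage up/down log-ratio, tested against ``fc_threshold`` with BH
    adjustment per transition.  A DTB has ``fdr < alpha``; its direction is
    "strengthening" when the fitted |log-ratio| grows across the transition
    and "weakening" when it shrinks.

    Returns a tidy frame over regions x transitions.
    """
    libs = contrasts.libraries
    stages = list(dict.fromkeys(lib.group for lib in libs))
    y = np.concatenate([contrasts.up, contrasts.down], axis=1).astype(float)
    lib_sizes = np.tile([lib.lib_size for lib in libs], 2).astype(float)

    abundance = ave_log_cpm(y, lib_sizes)
    keep = abundance >= min_logcpm
    y = y[keep]
    regions = contrasts.regions.loc[keep].reset_index(drop=True)
    abundance = abundance[keep]

    X = _ratio_design(libs, stages)
    nl = len(libs)
    offsets = np.log(lib_sizes)[None, :] * 0.0  # library baselines absorb depth
    dispersion = estimate_common_dispersion(y, X, offsets)
    fit = fit_nb_glm(y, X, offsets=offsets, dispersion=dispersion)
    ql = squeeze_ql_dispersions(fit, abundance=abundance, trend="loess")

    ratios = fit.coefficients[:, nl:] / np.log(2.0)  # per-stage log2 up/down ratio
    out = []
    for t, (a, bstage) in enumerate(zip(stages[:-1], stages[1:])):
        c = np.zeros(X.shape[1])
        c[nl + t + 1] = 1.0
        c[nl + t] = -1.0
        res = treat_test(fit, ql, c, fc_threshold=fc_threshold)
        res = pd.concat([regions, res.drop(columns="feature_id")], axis=1)
        res["transition"] = f"{a}->{bstage}"
        res["dtb"] = res["fdr"] < alpha
        grow = np.abs(ratios[:, t + 1]) > np.abs(ratios[:, t])
        res["direction"] = np.where(grow, "strengthening", "weakening")
        out.append(res)
    return pd.concat(out, ignore_index=True)
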