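"""Loop calling by local (donut) enrichment and the loop/DE association test.

Focal looping interactions are detected in a reference condition from dense
contact matrices: the expected count for each pixel combines the chromosome's
distance-decay profile with the mean observed/expected level in a surrounding
ring ("donut") neighbourhood, and enrichment is the stabilized log2 ratio of
observed over expected.  A chi-square test (df = 2) associates differential
expression status of genes with presence of their promoters in loop anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = ["Loop", "call_loops", "loop_de_association"]


@dataclass
class Loop:
    """A called looping pixel between two bins of one chromosome."""

    chrom: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    enrichment: float  # log2 (obs+1)/(expected+1), averages across libraries
    avg_count: float
    genes: tuple = ()


def _distance_expected(avg: np.ndarray) -> np.ndarray:
    """Per-pixel expectation from the mean of each diagonal."""
    n = avg.shape[0]
    exp = np.zeros_like(avg)
    for k in range(n):
        d = np.diagonal(avg, k)
        m = d.mean()
        idx = np.arange(n - k)
        exp[idx, idx + k] = m
        exp[idx + k, idx] = m
    return exp


def call_loops(
    matrices: list[np.ndarray],
    chrom: str,
    bin_width: int = 20_000,
    enrichment_min: float = 0.5,
    count_min: float = 5.0,
    min_offset: int = 60_000,
    donut_halfwidth: int = 5,
    inner_exclusion: int = 1,
) -> list[Loop]:
    """Detect focal pixels enriched over their distance-matched local field.

    ``matrices`` are the replicate contact matrices of one chromosome in the
    reference condition.  The expected value of a pixel is the mean
    observed/expected ratio in a ring of half-width ``donut_halfwidth`` bins
    (excluding the centre row/column cross and an inner square of
    ``inner_exclusion``), multiplied by the diagonal-mean expectation at its
    distance.  A loop requires ``log2((avg+1)/(exp+1)) > enrichment_min``,
    mean count across libraries > ``count_min`` and anchors more than
    ``min_offset`` apart.
    """
    if not matrices:
        raise ValueError("at least one contact matrix is required")
    avg = np.mean([np.asarray(m, dtype=float) for m in matrices], axis=0)
    n = avg.shape[0]

    dist_exp = _distance_expected(avg)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(dist_exp > 0, avg / dist_exp, 0.0)

    w, inner = donut_halfwidth, inner_exclusion
    kernel = np.ones((2 * w + 1, 2 * w + 1))
    kernel[w, :] = 0.0  # centre cross excluded
    kernel[:, w] = 0.0
    kernel[w - inner : w + inner + 1, w - inner : w + inner + 1] = 0.0
    num = ndimage.convolve(oe, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(oe), kernel, mode="constant", cval=0.0)
    local_oe = np.where(den > 0, num / den, 1.0)

    expected = local_oe * dist_exp
    enrich = np.log2((avg + 1.0) / (expected + 1.0))

    min_k = int(min_offset // bin_width) + 1
    iu = np.triu_indices(n, k=min_k)
    sel = (enrich[iu] > enrichment_min) & (avg[iu] > count_min)
    loops = []
    for i, j in zip(iu[0][sel], iu[1][sel]):
        loops.append(
            Loop(
                chrom=chrom,
                start_a=int(i * bin_width),
                end_a=int((i + 1) * bin_width),
                start_b=int(j * bin_width),
                end_b=int((j + 1) * bin_width),
                enrichment=float(enrich[i, j]),
                avg_count=float(avg[i, j]),
            )
        )
    return loops


def annotate_loops(loops: list[Loop], genes: pd.DataFrame, window: int = 5000) -> list[Loop]:
    """Attach gene ids whose TSS +/- window overlaps either loop anchor."""
    out = []
    for lp in loops:
        hit = []
        for row in genes.itertuples():
            if row.chrom != lp.chrom:
                continue
            lo, hi = row.tss - window, row.tss + window
            if (lo < lp.end_a and hi > lp.start_a) or (lo < lp.end_b and hi > lp.start_b):
                hit.append(row.gene_id)
        out.append(
            Loop(lp.chrom, lp.start_a, lp.end_a, lp.start_b, lp.end_b,
                 lp.enrichment, lp.avg_count, tuple(hit))
        )
    return out


def loop_de_association(
    in_anchor: np.ndarray, de_status: np.ndarray
) -> tuple[float, int, float, np.ndarray]:
    """Pearson chi-square (df 2) of DE direction vs loop-anchor membership.

    ``in_anchor`` is boolean per gene; ``de_status`` is one of
    {"up", "down", "non"} per gene.  The 2x3 contingency table is tested with
    no continuity correction.  Returns (statistic, df, p, table).
    """
    in_anchor = np.asarray(in_anchor, dtype=bool)
    de_status = np.asarray(de_status)
    cats = ["up", "down", "non"]
    if not set(np.unique(de_status)) <= set(cats):
        raise ValueError("de_status entries must be 'up', 'down' or 'non'")
    table = np.array(
        [
            [np.sum((in_anchor == flag) & (de_status == c)) for c in cats]
            for flag in (True, False)
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate margin in the 2x3 association table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected < 1):
        logger.warning("chi-square expected cell below 1; result may be unstable")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p), table
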