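"""Downstream association stages.

Motif enrichment in the distal anchors of promoters that change
interactivity (Fisher exact against sampled control anchors, Bonferroni
corrected, restricted to expressed transcription factors), ChIP-peak overlap
contrasts (Yates chi-square), differential gene expression (TMM-normalized
quasi-likelihood TREAT tests with pattern classification) and a permutation
gene-set association linking interactivity changes to expression changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import RegionSet
from .normalize import tmm_factors
from .qlstats import (
    classify_patterns,
    estimate_common_dispersion,
    fit_nb_glm,
    oneway_design,
    squeeze_ql_dispersions,
    transition_contrasts,
    treat_test,
)

__all__ = [
    "EnrichmentResult",
    "sample_control_anchors",
    "motif_enrichment",
    "chip_overlap_test",
    "detect_de_genes",
    "DEResults",
    "geneset_association",
]


@dataclass
class EnrichmentResult:
    """One motif's enrichment in a pattern's anchors vs control anchors."""

    motif: str
    pattern: str
    odds_ratio: float
    p: float
    bonferroni_p: float
    n_pattern: int
    n_control: int


def sample_control_anchors(all_anchors, exclude, n: int = 1500, seed: int = 1):
    """Seeded sample of anchors from interactions that are not differential."""
    pool = [a for a in all_anchors if a not in set(exclude)]
    if not pool:
        raise ValueError("no non-differential anchors available as controls")
    rng = np.random.default_rng(seed)
    n = min(n, len(pool))
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def motif_enrichment(
    pattern_anchors,
    control_anchors,
    hits: pd.DataFrame,
    rpkm: pd.Series | None = None,
    min_rpkm: float = 1.0,
    pattern: str = "",
    n_tests: int | None = None,
) -> list[EnrichmentResult]:
    """One-sided Fisher exact tests of motif presence in pattern vs control.

    ``hits`` is a binary anchors x motifs matrix.  Motifs whose transcription
    factor is not expressed (``rpkm < min_rpkm``) are excluded before
    testing; the Bonferroni factor is the number of tests performed (or
    ``n_tests`` when the caller tests several patterns in one analysis).
    """
    pattern_anchors = list(pattern_anchors)
    if not pattern_anchors:
        raise ValueError("the pattern anchor set is empty")
    control_anchors = list(control_anchors)
    motifs = [
        m for m in hits.columns
        if rpkm is None or rpkm.get(m, 0.0) >= min_rpkm
    ]
    factor = n_tests if n_tests is not None else len(motifs)
    hp = hits.loc[pattern_anchors, motifs].to_numpy(dtype=bool)
    hc = hits.loc[control_anchors, motifs].to_numpy(dtype=bool)
    out = []
    for k, m in enumerate(motifs):
        a = int(hp[:, k].sum())
        b = len(pattern_anchors) - a
        c = int(hc[:, k].sum())
        d = len(control_anchors) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        out.append(
            EnrichmentResult(
                motif=m, pattern=pattern, odds_ratio=float(odds), p=float(p),
                bonferroni_p=float(min(1.0, p * factor)),
                n_pattern=len(pattern_anchors), n_control=len(control_anchors),
            )
        )
    return out


def chip_overlap_test(
    anchors_increasing, anchors_decreasing, peaks: RegionSet
) -> tuple[float, int, float, np.ndarray]:
    """Yates-corrected chi-square (df 1) of peak overlap vs anchor direction.

    Anchors are (chrom, start, end) regions tied to promoters of increasing
    vs decreasing interactivity.  Returns (statistic, df, p, 2x2 table).
    """
    def overlap_counts(anchors):
        anchors = list(anchors)
        if not anchors:
            raise ValueError("an anchor set is empty")
        chroms = [a[0] for a in anchors]
        starts = [a[1] for a in anchors]
        ends = [a[2] for a in anchors]
        ov = peaks.overlaps(chroms, starts, ends)
        return int(ov.sum()), int((~ov).sum())

    table = np.array(
        [overlap_counts(anchors_increasing), overlap_counts(anchors_decreasing)],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margin in the overlap table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), int(df), float(p), table


@dataclass
class DEResults:
    """Per-transition differential-expression results plus patterns."""

    per_transition: dict[str, pd.DataFrame]
    patterns: pd.DataFrame
    dispersion: float
    tmm: np.ndarray


def detect_de_genes(
    expression: pd.DataFrame,
    groups,
    treat_fc: float = 1.5,
    alpha: float = 0.05,
    exclude_ids=(),
) -> DEResults:
    """TMM-normalized QL TREAT tests per transition, with patterns.

    ``expression`` is a genes x libraries count table.  TMM factors scale the
    library sizes (effective sizes enter as offsets); each consecutive-stage
    contrast is tested against a fold change of ``treat_fc``; BH adjustment
    is applied per transition and DE means ``fdr < alpha``.
    """
    expr = expression.loc[~expression.index.isin(set(exclude_ids))]
    counts = expr.to_numpy(dtype=float)
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    ids = expr.index.to_numpy()[keep]
    lib_sizes = counts.sum(axis=0)
    tmm = tmm_factors(counts, lib_sizes)
    eff = lib_sizes * tmm

    design, levels = oneway_design(list(groups))
    offsets = np.broadcast_to(np.log(eff), counts.shape)
    dispersion = estimate_common_dispersion(counts, design, offsets)
    fit = fit_nb_glm(counts, design, offsets=offsets, dispersion=dispersion,
                     feature_ids=ids)
    abundance = np.log2(counts.mean(axis=1) + 0.5)
    ql = squeeze_ql_dispersions(fit, abundance=abundance, trend="loess")

    results = {}
    for name, contrast in transition_contrasts(levels).items():
        res = treat_test(fit, ql, contrast, fc_threshold=treat_fc)
        res["de"] = res["fdr"] < alpha
        results[name] = res
    patterns = classify_patterns(results, alpha=alpha)
    return DEResults(results, patterns, float(dispersion), tmm)


def geneset_association(
    statistics: pd.Series,
    gene_set,
    n_perm: int = 10_000,
    seed: int = 1,
) -> tuple[float, str]:
    """Permutation test of a gene set against per-gene statistics.

    The observed statistic is the mean of the set members' (centred)
    gene-level statistics; the null is built by drawing ``n_perm`` random
    sets of the same size from the universe.  Returns the two-sided p-value
    with the +1 correction and the direction ("up"/"down") of the observed
    mean.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("gene set is empty")
    missing = set(gene_set) - set(statistics.index)
    if missing:
        raise ValueError(f"gene set members absent from the universe: {sorted(missing)[:5]}")
    if len(gene_set) >= len(statistics):
        raise ValueError("gene set must be a strict subset of the universe")
    values = statistics.to_numpy(dtype=float)
    centred = values - values.mean()
    obs = centred[statistics.index.isin(gene_set)].mean()

    rng = np.random.default_rng(seed)
    k = len(gene_set)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = centred[rng.choice(len(centred), size=k, replace=False)].mean()
    p = (1.0 + np.sum(np.abs(perm) >= abs(obs))) / (n_perm + 1.0)
    direction = "up" if obs >= 0 else "down"
    return float(p), direction
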