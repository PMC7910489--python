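"""Synthetic multi-stage Hi-C + expression experiments with ground truth.

Emulates the statistical structure of a staged B-cell differentiation Hi-C
study: six ordered condition groups (naive, 3 h and 10 h post-activation,
imminent division, expanded, plasmablast) in biological duplicate,
distance-decaying intra-chromosomal contact counts with negative-binomial
overdispersion, TAD blocks, promoter-anchored loops, a flat inter-chromosomal
ligation background, and designed stage-specific gains or losses of
interaction ("spikes") recorded in a truth table so every pipeline stage can
be validated against known effects.

Spikes are step changes: a spike at transition ``t`` multiplies the expected
intensity of its target in stages ``t+1, t+2, ...`` by ``fold**direction``,
mirroring the dominant change-then-stay-changed patterns of staged
differentiation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Binning, BinPairCountTable, LibraryInfo, RegionSet

__all__ = [
    "STAGES",
    "TadBlock",
    "LoopSpec",
    "SpikeSpec",
    "SimConfig",
    "SimulatedExperiment",
    "simulate_experiment",
    "expected_matrix",
    "simulate_dense_matrices",
    "simulate_expression",
    "pair_ids",
]

STAGES = ("naive", "act_3h", "act_10h", "imminent_division", "expanded", "plasmablast")


@dataclass(frozen=True)
class TadBlock:
    """A self-interacting block; pairs with both anchors inside are enriched
    ``fold``-fold, optionally rescaled per stage via ``stage_folds``."""

    chrom: str
    start: int
    end: int
    fold: float = 3.0
    stage_folds: tuple | None = None  # one multiplier per stage


@dataclass(frozen=True)
class LoopSpec:
    """A focal point interaction between two loci, ``fold`` above the decay."""

    chrom: str
    pos_a: int
    pos_b: int
    fold: float = 8.0


@dataclass(frozen=True)
class SpikeSpec:
    """A designed differential effect switched on at one stage transition.

    ``kind`` is "pair" (target: (chrom, pos1, pos2) at the working bin width),
    "promoter" (target: gene id; scales the promoter's whole interaction
    profile) or "gene" (target: gene id; expression only).  ``transition`` is
    the 0-based index of the transition (between stages t and t+1) at which
    the step change occurs.
    """

    kind: str
    target: object
    transition: int
    direction: int = 1
    fold: float = 3.0
    couple_expression: bool = False


def _default_tads() -> tuple:
    out = []
    for chrom in ("chr1", "chr2"):
        out += [
            TadBlock(chrom, 5_000_000, 7_500_000, 3.0),
            TadBlock(chrom, 14_000_000, 16_000_000, 2.5),
            TadBlock(chrom, 30_000_000, 33_000_000, 3.0),
        ]
    return tuple(out)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment."""

    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000})
    bin_width: int = 50_000
    stages: Sequence[str] = STAGES
    replicates: int = 2
    mean_depth: float = 2_000_000.0  # expected read pairs per library
    decay_exponent: float = -1.0  # power-law slope of contact frequency vs distance
    nb_dispersion: float = 0.02
    max_span: int = 5_000_000  # longest enumerated intra-chromosomal span
    inter_fraction: float = 0.05  # depth fraction in the inter-chromosomal background
    inter_bin_width: int = 1_000_000
    tad_blocks: Sequence[TadBlock] = field(default_factory=_default_tads)
    loops: Sequence[LoopSpec] = ()
    spikes: Sequence[SpikeSpec] = ()
    # promoter-anchored 10 kb contact table
    n_genes: int = 200
    promoter_bin_width: int = 10_000
    promoter_max_span: int = 1_000_000
    promoter_depth_fraction: float = 0.1
    anchors_per_promoter: int = 8
    anchor_fold: float = 20.0
    anchor_span: tuple = (30_000, 300_000)  # enhancer-like anchor distances
    promoter_strength_sd: float = 0.6  # log-normal sd of per-promoter interactivity
    # expression
    expression_baseline_mean: float = 200.0
    expression_dispersion: float = 0.01  # BCV ~0.1: inbred-mouse biological duplicates
    # annotation side-channels
    n_motifs: int = 20
    motif_background_rate: float = 0.1
    motif_enriched_rate: float = 0.5
    chip_enriched_rate: float = 0.4
    chip_background_rate: float = 0.1
    blacklist_margin: int = 200_000  # telomere-like exclusion at chromosome ends
    seed: int = 1

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.decay_exponent >= 0:
            raise ValueError("decay_exponent must be negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        for s in self.spikes:
            if not 0 <= s.transition < len(self.stages) - 1:
                raise ValueError(f"spike transition {s.transition} out of range")

    @property
    def n_transitions(self) -> int:
        return len(self.stages) - 1

    def libraries(self) -> list[LibraryInfo]:
        """Library metadata with placeholder sizes (filled after sampling)."""
        return [
            LibraryInfo(f"{stage}_r{rep + 1}", stage, rep + 1, 1)
            for stage in self.stages
            for rep in range(self.replicates)
        ]


@dataclass
class SimulatedExperiment:
    """All generated tables, annotations and ground truth."""

    config: SimConfig
    pairs: BinPairCountTable  # intra-chromosomal pairs at the working bin width
    background_pairs: BinPairCountTable  # inter-chromosomal pairs at 1 Mb
    promoter_pairs: BinPairCountTable  # promoter-anchored pairs at 10 kb
    genes: pd.DataFrame  # gene_id, chrom, tss, strand
    expression: pd.DataFrame  # genes x libraries counts
    truth: pd.DataFrame  # feature_id, feature_type, transition, direction, fold
    blacklist: RegionSet
    promoter_anchors: dict  # gene_id -> list of (chrom, start, end)
    motif_hits: pd.DataFrame  # anchors x motifs binary
    motif_rpkm: pd.Series  # per-motif TF expression level
    chip_peaks: RegionSet
    libraries: list[LibraryInfo]


def pair_ids(table: BinPairCountTable) -> np.ndarray:
    """Stable string ids for bin pairs, usable as result feature ids."""
    b = table.binning
    c1 = b.chrom_of(table.anchor1)
    c2 = b.chrom_of(table.anchor2)
    return np.array(
        [
            f"{c1[i]}:{b.start[table.anchor1[i]]}-{b.end[table.anchor1[i]]}"
            f"_{c2[i]}:{b.start[table.anchor2[i]]}-{b.end[table.anchor2[i]]}"
            for i in range(len(table))
        ]
    )


def _nb_sample(rng, mu, dispersion):
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mu))


def _decay(offsets_bins, exponent):
    k = np.maximum(np.asarray(offsets_bins, dtype=float), 0.5)
    return k**exponent


def _enumerate_intra(binning: Binning, max_span: int):
    """Upper-triangle intra pairs with bin-offset <= max_span / bin_width."""
    w = binning.bin_width
    kmax = max(1, max_span // w)
    a1, a2 = [], []
    for chrom in binning.chroms:
        off = binning._offset[chrom]
        nb = int(np.sum(binning.chrom_id == binning.chroms.index(chrom)))
        for k in range(0, kmax + 1):
            j = np.arange(0, nb - k, dtype=np.int64)
            a1.append(off + j + k)
            a2.append(off + j)
    return np.concatenate(a1), np.concatenate(a2)


def _pair_expected_base(config: SimConfig, binning: Binning, a1, a2):
    """Stage-independent expected intensity (unnormalized) per pair."""
    w = binning.bin_width
    k = a1 - a2
    base = _decay(k, config.decay_exponent)
    start1, start2 = binning.start[a1], binning.start[a2]
    chrom = binning.chrom_of(a1)
    for tad in config.tad_blocks:
        inside = (
            (chrom == tad.chrom)
            & (start1 >= tad.start) & (start1 + w <= tad.end)
            & (start2 >= tad.start) & (start2 + w <= tad.end)
        )
        base = np.where(inside, base * tad.fold, base)
    for loop in config.loops:
        ia = binning.bin_index(loop.chrom, loop.pos_a)
        ib = binning.bin_index(loop.chrom, loop.pos_b)
        hit = ((a1 == max(ia, ib)) & (a2 == min(ia, ib)))
        base = np.where(hit, base * loop.fold, base)
    return base


def _stage_multipliers(config: SimConfig, binning: Binning, a1, a2):
    """(n_stages, n_pairs) stage-specific multiplier (TAD stage folds + spikes)."""
    w = binning.bin_width
    n_stages = len(config.stages)
    mult = np.ones((n_stages, len(a1)))
    start1, start2 = binning.start[a1], binning.start[a2]
    chrom = binning.chrom_of(a1)
    for tad in config.tad_blocks:
        if tad.stage_folds is None:
            continue
        if len(tad.stage_folds) != n_stages:
            raise ValueError("stage_folds must have one entry per stage")
        inside = (
            (chrom == tad.chrom)
            & (start1 >= tad.start) & (start1 + w <= tad.end)
            & (start2 >= tad.start) & (start2 + w <= tad.end)
        )
        for s, f in enumerate(tad.stage_folds):
            mult[s, inside] *= f
    for spike in config.spikes:
        if spike.kind != "pair":
            continue
        chrom_s, p1, p2 = spike.target
        i1 = binning.bin_index(chrom_s, p1)
        i2 = binning.bin_index(chrom_s, p2)
        hit = (a1 == max(i1, i2)) & (a2 == min(i1, i2))
        if not hit.any():
            raise ValueError(f"pair spike {spike.target} matches no enumerated pair")
        factor = spike.fold ** float(spike.direction)
        for s in range(spike.transition + 1, n_stages):
            mult[s, hit] *= factor
    return mult


def _gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Deterministic bin-aligned gene/TSS annotation (no randomness)."""
    chroms = list(config.chrom_sizes)
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    pw = config.promoter_bin_width
    rows = []
    gid = 0
    for chrom in chroms:
        size = config.chrom_sizes[chrom]
        lo = config.blacklist_margin + config.promoter_max_span
        hi = size - config.blacklist_margin - config.promoter_max_span
        pos = np.linspace(lo, hi, per_chrom)
        for p in pos:
            if gid >= config.n_genes:
                break
            tss = (int(p) // pw) * pw + pw // 2  # centre of a 10 kb bin
            rows.append(
                {"gene_id": f"g{gid:04d}", "chrom": chrom, "tss": tss,
                 "strand": "+" if gid % 2 == 0 else "-"}
            )
            gid += 1
    return pd.DataFrame(rows)


def expected_matrix(config: SimConfig, stage: str, chrom: str, bin_width: int | None = None) -> np.ndarray:
    """Closed-form expected-count matrix for one chromosome and stage.

    Deterministic oracle used by tests: no sampling.  Entry (i, j) is the
    expected count of the bin pair; the matrix is symmetric, and expectations
    over the upper triangle of all chromosomes (spans <= max_span) sum to the
    per-library intra-chromosomal depth share.
    """
    if stage not in config.stages:
        raise ValueError(f"unknown stage {stage!r}")
    bw = bin_width or config.bin_width
    binning = Binning(config.chrom_sizes, bw)
    a1, a2 = _enumerate_intra(binning, config.max_span)
    base = _pair_expected_base(config, binning, a1, a2)
    mult = _stage_multipliers(config, binning, a1, a2)
    target = config.mean_depth * (1.0 - config.inter_fraction)
    scale = target / base.sum()
    mu = base * scale * mult[list(config.stages).index(stage)]

    sel = binning.chrom_of(a1) == chrom
    off = binning._offset[chrom]
    nb = int(np.sum(binning.chrom_id == binning.chroms.index(chrom)))
    m = np.zeros((nb, nb))
    i, j = a1[sel] - off, a2[sel] - off
    m[i, j] = mu[sel]
    m[j, i] = mu[sel]
    return m


def simulate_dense_matrices(
    config: SimConfig, stage: str, chrom: str, bin_width: int,
    n_replicates: int | None = None, seed: int | None = None,
):
    """Sample dense per-replicate contact matrices for one chromosome.

    Used by the reproducibility (SCC) and loop-calling stages.  Returns
    ``(matrices, expected)``; each matrix is symmetric with NB noise applied
    to the upper triangle.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    exp = expected_matrix(config, stage, chrom, bin_width)
    n_rep = n_replicates or config.replicates
    iu = np.triu_indices_from(exp)
    out = []
    for _ in range(n_rep):
        m = np.zeros_like(exp)
        vals = _nb_sample(rng, exp[iu], config.nb_dispersion)
        m[iu] = vals
        m.T[iu] = vals
        out.append(m)
    return out, exp


def _promoter_interaction_layout(config: SimConfig, genes: pd.DataFrame, rng):
    """Enumerate promoter-anchored 10 kb pairs, expected base intensity and
    the designed interacting-anchor list per promoter."""
    pw = config.promoter_bin_width
    binning = Binning(config.chrom_sizes, pw)
    kmax = config.promoter_max_span // pw
    a1_all, a2_all, base_all, gene_of = [], [], [], []
    anchors: dict[str, list] = {}
    window_bins = {binning.bin_index(r.chrom, r.tss) for r in genes.itertuples()}
    for row in genes.itertuples():
        wbin = binning.bin_index(row.chrom, row.tss)
        nb_off = binning._offset[row.chrom]
        nb = int(np.sum(binning.chrom_id == binning.chroms.index(row.chrom)))
        lo = max(nb_off, wbin - kmax)
        hi = min(nb_off + nb - 1, wbin + kmax)
        others = np.arange(lo, hi + 1)
        # promoter-window bins are excluded so each pair has one unambiguous
        # anchoring promoter (promoter-promoter contacts are not emitted)
        others = others[[o not in window_bins for o in others]]
        k = np.abs(others - wbin)
        base = _decay(k, config.decay_exponent)
        # designed interacting anchors: strong focal contacts above the decay,
        # placed at enhancer-like distances from the promoter
        klo = max(1, config.anchor_span[0] // pw)
        khi = max(klo + 1, config.anchor_span[1] // pw)
        eligible = np.flatnonzero((k >= klo) & (k <= khi))
        n_anch = min(config.anchors_per_promoter, len(eligible))
        pick = eligible[rng.choice(len(eligible), size=n_anch, replace=False)]
        base[pick] *= config.anchor_fold
        # promoters differ in overall interactivity, as real promoters do
        base *= np.exp(rng.normal(0.0, config.promoter_strength_sd))
        anchors[row.gene_id] = [
            (row.chrom, int(binning.start[o]), int(binning.end[o]))
            for o in others[pick]
        ]
        a1_all.append(np.maximum(others, wbin))
        a2_all.append(np.minimum(others, wbin))
        base_all.append(base)
        gene_of.append(np.repeat(row.gene_id, len(others)))
    return (
        binning,
        np.concatenate(a1_all),
        np.concatenate(a2_all),
        np.concatenate(base_all),
        np.concatenate(gene_of),
        anchors,
    )


def simulate_expression(config: SimConfig, rng=None):
    """NB gene-expression counts with designed stage-specific fold changes.

    Returns ``(counts DataFrame, truth DataFrame)``.  Gene spikes come from
    SpikeSpec entries of kind "gene", plus promoter spikes flagged
    ``couple_expression`` (same transition/direction/fold), which designs in
    the promoter-interactivity / expression correlation.
    """
    rng = np.random.default_rng(config.seed + 104729) if rng is None else rng
    genes = _gene_annotation(config)
    libs = config.libraries()
    n_stages = len(config.stages)
    baseline = np.exp(rng.normal(np.log(config.expression_baseline_mean), 1.0, len(genes)))
    mult = np.ones((n_stages, len(genes)))
    truth_rows = []
    gene_index = {g: i for i, g in enumerate(genes.gene_id)}
    for spike in config.spikes:
        if spike.kind == "gene" or (spike.kind == "promoter" and spike.couple_expression):
            gi = gene_index.get(spike.target)
            if gi is None:
                raise ValueError(f"spiked gene {spike.target!r} not in annotation")
            factor = spike.fold ** float(spike.direction)
            for s in range(spike.transition + 1, n_stages):
                mult[s, gi] *= factor
            truth_rows.append(
                {"feature_id": spike.target, "feature_type": "gene",
                 "transition": spike.transition, "direction": spike.direction,
                 "fold": spike.fold}
            )
    counts = np.empty((len(genes), len(libs)), dtype=np.int64)
    for j, lib in enumerate(libs):
        s = list(config.stages).index(lib.group)
        counts[:, j] = _nb_sample(rng, baseline * mult[s], config.expression_dispersion)
    df = pd.DataFrame(counts, index=genes.gene_id, columns=[l.name for l in libs])
    return df, pd.DataFrame(
        truth_rows, columns=["feature_id", "feature_type", "transition", "direction", "fold"]
    )


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate the complete synthetic experiment (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    libs_meta = config.libraries()
    stage_of = [list(config.stages).index(l.group) for l in libs_meta]
    n_stages = len(config.stages)

    # ------- intra-chromosomal working-resolution table -------
    binning = Binning(config.chrom_sizes, config.bin_width)
    a1, a2 = _enumerate_intra(binning, config.max_span)
    base = _pair_expected_base(config, binning, a1, a2)
    mult = _stage_multipliers(config, binning, a1, a2)
    intra_target = config.mean_depth * (1.0 - config.inter_fraction)
    scale = intra_target / base.sum()
    counts = np.empty((len(a1), len(libs_meta)), dtype=np.int64)
    for j, s in enumerate(stage_of):
        counts[:, j] = _nb_sample(rng, base * scale * mult[s], config.nb_dispersion)
    keep = counts.sum(axis=1) > 0
    pairs = BinPairCountTable(binning, a1[keep], a2[keep], counts[keep], libs_meta)

    # ------- inter-chromosomal 1 Mb background table -------
    bg_binning = Binning(config.chrom_sizes, config.inter_bin_width)
    cid = bg_binning.chrom_id
    ii, jj = np.meshgrid(np.arange(bg_binning.n_bins), np.arange(bg_binning.n_bins), indexing="ij")
    inter = (ii > jj) & (cid[ii] != cid[jj])
    b1, b2 = ii[inter], jj[inter]
    if len(b1) == 0:
        raise ValueError("at least two chromosomes are required for the background table")
    bg_mu = config.mean_depth * config.inter_fraction / len(b1)
    bg_counts = np.empty((len(b1), len(libs_meta)), dtype=np.int64)
    for j in range(len(libs_meta)):
        bg_counts[:, j] = _nb_sample(rng, np.full(len(b1), bg_mu), config.nb_dispersion)
    background = BinPairCountTable(bg_binning, b1, b2, bg_counts, libs_meta)

    # genome-wide library sizes shared by both tables
    totals = pairs.counts.sum(axis=0) + background.counts.sum(axis=0)
    libs = [
        LibraryInfo(l.name, l.group, l.replicate, int(t))
        for l, t in zip(libs_meta, totals)
    ]
    pairs.libraries = libs
    background.libraries = libs

    # ------- promoter-anchored 10 kb table -------
    genes = _gene_annotation(config)
    pbin, pa1, pa2, pbase, gene_of, anchors = _promoter_interaction_layout(config, genes, rng)
    pmult = np.ones((n_stages, len(pa1)))
    truth_rows = []
    for spike in config.spikes:
        if spike.kind != "promoter":
            continue
        hit = gene_of == spike.target
        if not hit.any():
            raise ValueError(f"spiked promoter {spike.target!r} not in annotation")
        factor = spike.fold ** float(spike.direction)
        for s in range(spike.transition + 1, n_stages):
            pmult[s, hit] *= factor
        truth_rows.append(
            {"feature_id": spike.target, "feature_type": "promoter",
             "transition": spike.transition, "direction": spike.direction,
             "fold": spike.fold}
        )
    for spike in config.spikes:
        if spike.kind == "pair":
            truth_rows.append(
                {"feature_id": _pair_spike_id(config, spike), "feature_type": "pair",
                 "transition": spike.transition, "direction": spike.direction,
                 "fold": spike.fold}
            )
    p_target = config.mean_depth * config.promoter_depth_fraction
    pscale = p_target / pbase.sum()
    pcounts = np.empty((len(pa1), len(libs)), dtype=np.int64)
    for j, s in enumerate(stage_of):
        pcounts[:, j] = _nb_sample(rng, pbase * pscale * pmult[s], config.nb_dispersion)
    pkeep = pcounts.sum(axis=1) > 0
    promoter_pairs = BinPairCountTable(pbin, pa1[pkeep], pa2[pkeep], pcounts[pkeep], libs)

    # ------- expression, blacklist, motif hits, ChIP peaks -------
    expression, expr_truth = simulate_expression(config, rng)
    frames = [
        df for df in (pd.DataFrame(truth_rows, columns=expr_truth.columns), expr_truth)
        if len(df)
    ]
    truth = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=expr_truth.columns)
    )

    bl = []
    for chrom, size in config.chrom_sizes.items():
        bl.append((chrom, 0, config.blacklist_margin, "telomere_5p"))
        bl.append((chrom, size - config.blacklist_margin, size, "telomere_3p"))
    blacklist = RegionSet(bl)

    spiked_genes = {
        s.target for s in config.spikes if s.kind == "promoter" and s.direction > 0
    }
    anchor_records = sorted(
        {(a, g) for g, lst in anchors.items() for a in lst},
    )
    anchor_ids = [f"{c}:{s}-{e}" for ((c, s, e), _g) in anchor_records]
    motifs = [f"M{k:03d}" for k in range(config.n_motifs)]
    hit_p = np.full((len(anchor_records), config.n_motifs), config.motif_background_rate)
    in_spiked = np.array([g in spiked_genes for (_a, g) in anchor_records])
    hit_p[in_spiked, 0] = config.motif_enriched_rate  # motif M000 is the planted one
    motif_hits = pd.DataFrame(
        rng.random(hit_p.shape) < hit_p, index=anchor_ids, columns=motifs
    )
    motif_rpkm = pd.Series(
        np.exp(rng.normal(np.log(5.0), 1.0, config.n_motifs)), index=motifs
    )

    peak_p = np.where(in_spiked, config.chip_enriched_rate, config.chip_background_rate)
    take = rng.random(len(anchor_records)) < peak_p
    chip_peaks = RegionSet(
        [(c, s, e, f"peak{k}") for k, ((c, s, e), _g) in enumerate(anchor_records) if take[k]]
    )

    return SimulatedExperiment(
        config=config,
        pairs=pairs,
        background_pairs=background,
        promoter_pairs=promoter_pairs,
        genes=genes,
        expression=expression,
        truth=truth,
        blacklist=blacklist,
        promoter_anchors=anchors,
        motif_hits=motif_hits,
        motif_rpkm=motif_rpkm,
        chip_peaks=chip_peaks,
        libraries=libs,
    )


def _pair_spike_id(config: SimConfig, spike: SpikeSpec) -> str:
    chrom, p1, p2 = spike.target
    w = config.bin_width
    s1, s2 = (p1 // w) * w, (p2 // w) * w
    hi, lo = max(s1, s2), min(s1, s2)
    size = config.chrom_sizes[chrom]
    return (
        f"{chrom}:{hi}-{min(hi + w, size)}_{chrom}:{lo}-{min(lo + w, size)}"
    )
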