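import numpy as np
import pandas as pd
import pytest

from hicwaves import (
    BinPairCountTable,
    Binning,
    LibraryInfo,
    RegionSet,
    aggregate_promoter_counts,
    connect_promoter_counts,
    define_promoter_windows,
    detect_dips,
    distance_abundance_filter,
    filter_promoters,
)
from hicwaves.dips import PromoterWindow
from hicwaves.normalize import loess_fit
from hicwaves.core import ave_log_cpm
from hicwaves.simulate import SimConfig, simulate_experiment
from conftest import make_promoter_spikes


GENES = pd.DataFrame(
    {
        "gene_id": ["gA", "gB", "gC"],
        "chrom": ["chr1", "chr1", "chr1"],
        "tss": [100_000, 300_000, 500_000],
        "strand": ["+", "-", "+"],
    }
)
SIZES = {"chr1": 1_000_000}


class TestPromoterWindows:
    def test_plus_strand_definition(self):
        (w, *_) = define_promoter_windows(GENES, SIZES)
        assert (w.start, w.end) == (95_000, 105_000)

    def test_minus_strand_same_span_when_symmetric(self):
        wins = define_promoter_windows(GENES, SIZES)
        wb = [w for w in wins if w.gene_id == "gB"][0]
        assert wb.end - wb.start == 10_000 and wb.strand == "-"

    def test_asymmetric_window_respects_strand(self):
        wins = define_promoter_windows(GENES, SIZES, up=8000, down=2000)
        wa = [w for w in wins if w.gene_id == "gA"][0]
        wb = [w for w in wins if w.gene_id == "gB"][0]
        assert (wa.start, wa.end) == (92_000, 102_000)
        assert (wb.start, wb.end) == (298_000, 308_000)

    def test_excluded_gene_gets_no_window(self):
        wins = define_promoter_windows(GENES, SIZES, exclude_ids={"gB"})
        assert [w.gene_id for w in wins] == ["gA", "gC"]

    def test_window_clipped_at_chromosome_edge(self):
        genes = GENES.assign(tss=[2_000, 300_000, 500_000])
        (w, *_) = define_promoter_windows(genes, SIZES)
        assert w.start == 0


def _contacts(pairs_counts, n_libs=4, bin_width=10_000, chrom_sizes=None):
    chrom_sizes = chrom_sizes or {"chr1": 1_000_000, "chr2": 1_000_000}
    binning = Binning(chrom_sizes, bin_width)
    libs = [LibraryInfo(f"l{j}", f"g{j // 2}", j % 2 + 1, 1_000_000) for j in range(n_libs)]
    a1 = [p[0] for p in pairs_counts]
    a2 = [p[1] for p in pairs_counts]
    counts = np.array([p[2] for p in pairs_counts])
    return BinPairCountTable(binning, a1, a2, counts, libs)


class TestConnectCounts:
    WINDOWS = [PromoterWindow("gA", "chr1", 105_000, "+", 100_000, 110_000)]

    def test_single_read_pair_counted(self):
        contacts = _contacts([(10, 50, [1, 0, 0, 0])])  # bin 10 is the window
        tab = connect_promoter_counts(contacts, self.WINDOWS)
        assert len(tab) == 1
        assert tab.iloc[0]["gene_id"] == "gA"
        assert tab.iloc[0]["second_start"] == 500_000
        assert tab.iloc[0][["l0", "l1", "l2", "l3"]].tolist() == [1, 0, 0, 0]

    def test_interchromosomal_excluded(self):
        contacts = _contacts([(150, 10, [5, 5, 5, 5])])  # chr2 x chr1(window)
        tab = connect_promoter_counts(contacts, self.WINDOWS)
        assert len(tab) == 0

    def test_self_interaction_dropped(self):
        contacts = _contacts([(10, 10, [7, 7, 7, 7])])
        tab = connect_promoter_counts(contacts, self.WINDOWS)
        assert len(tab) == 0

    def test_blacklisted_anchor_dropped(self):
        contacts = _contacts([(10, 50, [3, 0, 0, 0])])
        bl = RegionSet([("chr1", 500_000, 510_000)])
        tab = connect_promoter_counts(contacts, self.WINDOWS, blacklist=bl)
        assert len(tab) == 0

    def test_promoter_promoter_assigned_once_by_default(self):
        windows = self.WINDOWS + [PromoterWindow("gB", "chr1", 505_000, "+", 500_000, 510_000)]
        contacts = _contacts([(50, 10, [2, 0, 0, 0])])
        tab = connect_promoter_counts(contacts, windows)
        assert len(tab) == 1 and tab.iloc[0]["gene_id"] == "gA"
        tab2 = connect_promoter_counts(contacts, windows, allow_double=True)
        assert sorted(tab2["gene_id"]) == ["gA", "gB"]

    def test_adding_a_library_group_preserves_shared_columns(self):
        """The counting path is independent of the design composition."""
        pairs = [(10, 50, [1, 2, 3, 4, 9, 9]), (10, 60, [5, 0, 1, 2, 9, 9])]
        full = _contacts(pairs, n_libs=6)
        reduced = full.subset(np.ones(len(full), dtype=bool))
        reduced.counts = full.counts[:, :4]
        reduced.libraries = full.libraries[:4]
        t_full = connect_promoter_counts(full, self.WINDOWS)
        t_red = connect_promoter_counts(reduced, self.WINDOWS)
        shared = ["l0", "l1", "l2", "l3"]
        assert t_full[shared].equals(t_red[shared])


class TestDistanceAbundanceFilter:
    def _table(self, spans, counts):
        df = pd.DataFrame(
            {"gene_id": "gA", "chrom": "chr1",
             "second_start": 0, "second_end": 10_000, "span": spans}
        )
        counts = np.asarray(counts)
        for j in range(counts.shape[1]):
            df[f"l{j}"] = counts[:, j]
        df.attrs["lib_names"] = [f"l{j}" for j in range(counts.shape[1])]
        df.attrs["lib_sizes"] = [1e6] * counts.shape[1]
        return df

    def test_identical_abundances_retain_nothing(self):
        spans = np.linspace(10_000, 500_000, 30)
        tab = self._table(spans, np.full((30, 2), 20))
        out = distance_abundance_filter(tab, k=2.0)
        assert len(out) == 0

    def test_strong_interaction_above_flat_background_retained(self):
        spans = np.linspace(10_000, 500_000, 30)
        counts = np.full((30, 2), 20)
        counts[7] = 20 * 1024  # 10 log2 units above
        tab = self._table(spans, counts)
        # span sized so the window is not dominated by the outlier itself
        out = distance_abundance_filter(tab, span=0.5, k=2.0)
        assert out["span"].tolist() == [spans[7]]

    def test_matches_pointwise_rule_oracle(self):
        rng = np.random.default_rng(13)
        spans = rng.uniform(10_000, 1_000_000, 200)
        counts = rng.poisson(30, size=(200, 3)) + 1
        tab = self._table(spans, counts)
        out = distance_abundance_filter(tab, span=0.3, k=2.0)
        # oracle: apply the fitted-curve + k*mean|resid| rule pointwise
        ab = ave_log_cpm(counts.astype(float), np.array([1e6] * 3))
        fit = loess_fit(np.log10(spans + 1), ab, span=0.3, grid=400)
        resid = np.mean(np.abs(ab - fit))
        keep = ab > fit + 2.0 * resid
        assert out["span"].tolist() == spans[keep].tolist()

    def test_stricter_multiplier_never_enlarges(self):
        rng = np.random.default_rng(14)
        spans = rng.uniform(10_000, 1_000_000, 300)
        counts = rng.poisson(25, size=(300, 2)) + 1
        tab = self._table(spans, counts)
        k2 = distance_abundance_filter(tab, k=2.0)
        k3 = distance_abundance_filter(tab, k=3.0)
        assert set(k3["span"]) <= set(k2["span"])

    def test_too_few_interactions_rejected(self):
        tab = self._table([10_000] * 5, np.full((5, 2), 10))
        with pytest.raises(ValueError):
            distance_abundance_filter(tab)


class TestAggregation:
    def _table(self):
        df = pd.DataFrame(
            {
                "gene_id": ["gA", "gA", "gB"],
                "chrom": "chr1",
                "second_start": [0, 10_000, 20_000],
                "second_end": [10_000, 20_000, 30_000],
                "span": [50_000.0, 60_000.0, 70_000.0],
                "l0": [3, 4, 5],
                "l1": [1, 0, 2],
            }
        )
        df.attrs["lib_names"] = ["l0", "l1"]
        df.attrs["lib_sizes"] = [1e6, 1e6]
        return df

    def test_sums_per_promoter(self):
        agg = aggregate_promoter_counts(self._table())
        assert agg.loc["gA"].tolist() == [7, 1]
        assert agg.loc["gB"].tolist() == [5, 2]

    def test_promoter_without_interactions_absent(self):
        agg = aggregate_promoter_counts(self._table())
        assert "gC" not in agg.index

    def test_order_invariance(self):
        tab = self._table()
        shuffled = tab.iloc[[2, 0, 1]].reset_index(drop=True)
        shuffled.attrs = dict(tab.attrs)
        assert aggregate_promoter_counts(tab).equals(aggregate_promoter_counts(shuffled))

    def test_counts_conserved(self):
        tab = self._table()
        agg = aggregate_promoter_counts(tab)
        assert agg.to_numpy().sum() == tab[["l0", "l1"]].to_numpy().sum()


class TestFilterPromoters:
    def _matrix(self, rows):
        df = pd.DataFrame(rows).T
        df.columns = [f"l{j}" for j in range(df.shape[1])]
        df.attrs["lib_sizes"] = [1e6] * df.shape[1]
        return df

    def test_low_total_removed(self):
        m = self._matrix({"p1": [50, 50, 25, 25], "p2": [300] * 4})
        out = filter_promoters(m, ["a", "a", "b", "b"], min_count=100, min_total=200)
        assert list(out.index) == ["p2"]

    def test_high_everywhere_kept(self):
        m = self._matrix({"p1": [300] * 4})
        out = filter_promoters(m, ["a", "a", "b", "b"])
        assert list(out.index) == ["p1"]

    def test_single_library_burst_removed_by_group_rule(self):
        # 12 libraries, smallest group 2: one high library is not enough
        row = [0] * 12
        row[3] = 300
        m = self._matrix({"p1": row, "p2": [300] * 12})
        groups = [g for g in "abcdef" for _ in range(2)]
        out = filter_promoters(m, groups, min_count=200, min_total=200)
        assert list(out.index) == ["p2"]

    def test_excluded_ids_dropped(self):
        m = self._matrix({"p1": [300] * 4, "p2": [300] * 4})
        out = filter_promoters(m, ["a", "a", "b", "b"], exclude_ids={"p1"})
        assert list(out.index) == ["p2"]

    def test_empty_result_is_an_error(self):
        m = self._matrix({"p1": [1, 1, 1, 1]})
        with pytest.raises(ValueError):
            filter_promoters(m, ["a", "a", "b", "b"])


@pytest.fixture(scope="module")
def dip_run():
    cfg = SimConfig(
        chrom_sizes={"chr1": 25_000_000, "chr2": 25_000_000},
        mean_depth=2_000_000, max_span=2_000_000, n_genes=150,
        spikes=make_promoter_spikes(150, 30, transition=4),
        seed=21,
    )
    exp = simulate_experiment(cfg)
    windows = define_promoter_windows(exp.genes, cfg.chrom_sizes)
    tab = connect_promoter_counts(exp.promoter_pairs, windows, exp.blacklist)
    filt = distance_abundance_filter(tab, k=2.0)
    agg = aggregate_promoter_counts(filt)
    groups = [l.group for l in exp.libraries]
    kept = filter_promoters(agg, groups)
    return exp, detect_dips(kept, groups)


class TestDetectDips:
    def test_spiked_promoters_recovered(self, dip_run):
        exp, res = dip_run
        truth = set(exp.truth[exp.truth.feature_type == "promoter"].feature_id)
        r = res.per_transition["expanded->plasmablast"]
        assert r[r.dip].feature_id.isin(truth).sum() >= 0.8 * len(truth)

    def test_decreasing_spike_pattern_minus_one_at_final_transition(self, dip_run):
        exp, res = dip_run
        truth = exp.truth[exp.truth.feature_type == "promoter"]
        down = truth[truth.direction == -1].feature_id
        pats = res.patterns
        final = "expanded->plasmablast"
        hit = [g for g in down if g in pats.index and pats.loc[g, final] != 0]
        assert hit and all(pats.loc[g, final] == -1 for g in hit)

    def test_few_calls_outside_spiked_transition(self, dip_run):
        exp, res = dip_run
        others = [k for k in res.per_transition if k != "expanded->plasmablast"]
        total = sum(int(res.per_transition[k].dip.sum()) for k in others)
        assert total <= 3
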