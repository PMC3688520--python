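"""Delta tracks, the empirical null, change-interval calling and gene classes."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polystate import (
    ChangeCallParams,
    DifferentialOccupancy,
    GeneModel,
    Interval,
    NullStats,
    call_change_intervals,
    category_percentages,
    classify_gene_changes,
    delta_track,
    elongation_ratio,
    integrated_gene_delta,
    null_stats,
    pause_index,
)
from polystate.errors import DegenerateNullError, NoSharedProbesError, NullShiftWarning

from ._oracles import window_scan_runs
from .conftest import make_track


class TestDeltaTrack:
    def test_probe_wise_difference(self):
        control = make_track([0, 35], [1.0, 1.0])
        depleted = make_track([0, 35], [3.0, 0.0])
        delta = delta_track(control, depleted)
        assert delta.scores("chr2L").tolist() == [2.0, -1.0]

    def test_identical_tracks_give_zero(self):
        t = make_track([0, 35, 70], [1.0, 2.0, 3.0])
        assert delta_track(t, t).all_scores().tolist() == [0.0, 0.0, 0.0]

    def test_unshared_probes_dropped_and_counted(self):
        control = make_track([0, 35, 70], [1.0, 1.0, 1.0])
        depleted = make_track([35, 70, 105], [2.0, 2.0, 2.0])
        delta = delta_track(control, depleted)
        assert delta.starts("chr2L").tolist() == [35, 70]
        assert delta.meta["n_dropped_control"] == 1
        assert delta.meta["n_dropped_depleted"] == 1

    def test_disjoint_probe_sets_error(self):
        a = make_track([0], [1.0])
        b = make_track([35], [1.0])
        with pytest.raises(NoSharedProbesError):
            delta_track(a, b)


class TestNullStats:
    def test_hand_example(self):
        delta = make_track([0, 35, 70], [-1.0, 0.0, 1.0])
        null = null_stats(delta)
        assert null.median == 0.0
        assert null.mean == 0.0
        assert null.sd == pytest.approx(1.0)  # sample SD, ddof=1
        assert null.n == 3

    def test_degenerate_null_is_an_error(self):
        delta = make_track([0, 35, 70], [2.0, 2.0, 2.0])
        with pytest.raises(DegenerateNullError):
            null_stats(delta)

    def test_shifted_median_warns(self):
        rng = np.random.default_rng(0)
        values = rng.normal(1.0, 0.5, size=1000)  # median 2 SD away from zero
        delta = make_track(np.arange(1000) * 35, values)
        with pytest.warns(NullShiftWarning):
            null_stats(delta)

    def test_recovers_generator_sd(self):
        """On 10,000 N(0, 0.8) draws the sample SD lands within 5% of 0.8."""
        rng = np.random.default_rng(123)
        delta = make_track(np.arange(10_000) * 35, rng.normal(0.0, 0.8, 10_000))
        null = null_stats(delta)
        assert null.sd == pytest.approx(0.8, rel=0.05)
        assert abs(null.median) <= 0.25 * null.sd


class TestCallChangeIntervals:
    NULL = NullStats(median=0.0, mean=0.0, sd=1.0, n=10_000)

    def test_all_zero_delta_is_empty(self):
        delta = make_track(np.arange(10) * 35, np.zeros(10))
        inc, dec = call_change_intervals(delta, self.NULL)
        assert inc == [] and dec == []

    def test_three_probe_increase_run(self):
        delta = make_track([0, 35, 70], [2.5, 2.5, 2.5])
        inc, dec = call_change_intervals(delta, self.NULL)
        assert [(iv.start, iv.end, iv.sign) for iv in inc] == [(0, 105, 1)]
        assert dec == []

    def test_two_probe_run_is_rejected(self):
        delta = make_track([0, 35], [3.0, 3.0])
        inc, dec = call_change_intervals(delta, self.NULL)
        assert inc == [] and dec == []

    def test_signs_separate_and_never_overlap(self):
        values = np.array([3.0, 3.0, 3.0, -3.0, -3.0, -3.0, 0.0, 3.0, 3.0, 3.0])
        delta = make_track(np.arange(10) * 35, values)
        inc, dec = call_change_intervals(delta, self.NULL)
        assert [(iv.start, iv.end) for iv in inc] == [(0, 105), (245, 350)]
        assert [(iv.start, iv.end) for iv in dec] == [(105, 210)]
        for a in inc:
            for b in dec:
                assert not a.overlaps(b.chrom, b.start, b.end)

    def test_thresholds_use_median_not_zero(self):
        null = NullStats(median=1.0, mean=1.0, sd=1.0, n=100)
        delta = make_track(np.arange(3) * 35, [2.5, 2.5, 2.5])
        inc, dec = call_change_intervals(delta, null)
        assert inc == []  # 2.5 < 1.0 + 2*1.0

    def test_interval_score_is_mean_delta(self):
        delta = make_track([0, 35, 70], [2.0, 3.0, 4.0])
        inc, _ = call_change_intervals(delta, self.NULL)
        assert inc[0].score == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_window_scan_oracle(self, seed):
        """Exact equality with the brute-force scan, both signs, gappy grids."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(5, 1000))
        keep = rng.random(n) > 0.1
        starts = (np.arange(n) * 35)[keep]
        values = rng.normal(0, 1.4, size=starts.size)
        delta = make_track(starts, values)
        null = NullStats(median=0.0, mean=0.0, sd=1.0, n=starts.size)
        inc, dec = call_change_intervals(delta, null)
        exp_inc = window_scan_runs(starts, values >= 2.0, tile_width=35,
                                   max_gap=70, min_run=3, min_span=105)
        exp_dec = window_scan_runs(starts, values <= -2.0, tile_width=35,
                                   max_gap=70, min_run=3, min_span=105)
        assert [(iv.start, iv.end) for iv in inc] == exp_inc
        assert [(iv.start, iv.end) for iv in dec] == exp_dec

    @pytest.mark.parametrize("param,values", [
        ("k_sd", (1.5, 2.0, 2.5, 3.0)),
        ("min_run", (2, 3, 4, 6)),
    ])
    def test_stricter_params_never_add_intervals(self, param, values):
        rng = np.random.default_rng(9)
        delta = make_track(np.arange(2000) * 35, rng.normal(0, 1.2, 2000))
        counts = []
        for v in values:
            inc, dec = call_change_intervals(delta, self.NULL,
                                             ChangeCallParams(**{param: v}))
            counts.append(len(inc) + len(dec))
        assert counts == sorted(counts, reverse=True)


class TestIntegratedGeneDelta:
    REGION = Interval("chr2L", 0, 105)

    def test_two_probe_gene(self):
        control = make_track([0, 35], [1.0, 2.0])
        depleted = make_track([0, 35], [2.0, 4.0])
        m = integrated_gene_delta(control, depleted, self.REGION)
        assert m.status == "ok" and m.value == pytest.approx(3.0)

    def test_identical_tracks_give_zero(self):
        t = make_track([0, 35], [1.0, 2.0])
        m = integrated_gene_delta(t, t, self.REGION)
        assert m.value == 0.0 and m.status == "ok"

    def test_region_without_probes_flags_no_data(self):
        control = make_track([1000], [1.0])
        depleted = make_track([1000], [2.0])
        m = integrated_gene_delta(control, depleted, self.REGION)
        assert m.status == "no_data" and np.isnan(m.value)


class TestPauseIndex:
    def _gene_and_track(self, prom_scores, body_scores):
        # plus-strand gene with TSS at 1000; 400 bp promoter = [800, 1200)
        gene = GeneModel("g1", "chr2L", "+", 1000, 3000)
        prom_starts = 800 + np.arange(len(prom_scores)) * 35
        body_starts = 1200 + np.arange(len(body_scores)) * 35
        track = make_track(np.concatenate([prom_starts, body_starts]),
                           np.concatenate([prom_scores, body_scores]))
        return gene, track

    def test_simple_ratio(self):
        gene, track = self._gene_and_track([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        m = pause_index(track, gene)
        assert m.value == pytest.approx(2.0)

    def test_uniform_track_gives_one(self):
        gene = GeneModel("g1", "chr2L", "+", 1000, 3000)
        track = make_track(np.arange(0, 3000, 35), np.full(86, 1.7))
        assert pause_index(track, gene).value == pytest.approx(1.0)

    def test_hand_median_example(self):
        gene, track = self._gene_and_track([1.0, 3.0, 5.0], [1.0, 2.0, 2.0, 4.0])
        m = pause_index(track, gene)
        assert m.value == pytest.approx(1.5)  # 3 / 2

    def test_nonpositive_body_median_is_undefined(self):
        gene, track = self._gene_and_track([2.0, 2.0], [-1.0, 0.0, -2.0])
        assert pause_index(track, gene).status == "undefined"

    def test_missing_probes_flag_no_data(self):
        gene = GeneModel("g1", "chr2L", "+", 1000, 3000)
        track = make_track([5000], [1.0])
        assert pause_index(track, gene).status == "no_data"

    def test_minus_strand_promoter_sits_at_tx_end(self):
        # minus-strand TSS at 2999; promoter [2799, 3199)
        gene = GeneModel("g1", "chr2L", "-", 1000, 3000)
        starts = np.arange(1000, 3150, 35)
        scores = np.where(starts >= 2799, 4.0, 1.0)
        m = pause_index(make_track(starts, scores), gene)
        assert m.value == pytest.approx(4.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100))
    def test_invariant_under_positive_rescaling(self, scale):
        gene, track = self._gene_and_track([1.0, 3.0, 5.0], [1.0, 2.0, 2.0, 4.0])
        scaled = make_track(track.starts("chr2L"), track.scores("chr2L") * scale)
        assert pause_index(scaled, gene).value == pytest.approx(
            pause_index(track, gene).value)

    def test_density_variant(self):
        gene, track = self._gene_and_track([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        m = pause_index(track, gene, method="density")
        # promoter: 6.0 over 400 bp; body: 3.0 over 1800 bp
        assert m.value == pytest.approx((6.0 / 400) / (3.0 / 1800))


class TestElongationRatio:
    GENE = GeneModel("g1", "chr2L", "+", 0, 2000)

    def test_simple_ratio(self):
        starts = np.arange(300, 1900, 35)  # body = [200, 2000) for width 400
        ser2p = make_track(starts, np.full(starts.size, 4.0))
        rpb3 = make_track(starts, np.full(starts.size, 2.0))
        m = elongation_ratio(ser2p, rpb3, self.GENE)
        assert m.value == pytest.approx(2.0)

    def test_identical_tracks_give_one(self):
        starts = np.arange(300, 1900, 35)
        t = make_track(starts, np.linspace(1, 3, starts.size))
        assert elongation_ratio(t, t, self.GENE).value == pytest.approx(1.0)

    def test_zero_rpb3_median_is_undefined(self):
        starts = np.arange(300, 1900, 35)
        ser2p = make_track(starts, np.full(starts.size, 4.0))
        rpb3 = make_track(starts, np.zeros(starts.size))
        assert elongation_ratio(ser2p, rpb3, self.GENE).status == "undefined"


class TestClassifyGeneChanges:
    GENES = [GeneModel("g1", "chr2L", "+", 1000, 5000)]

    def test_body_increase_is_up(self):
        inc = [Interval("chr2L", 2000, 2200, sign=1, score=2.0)]
        frame = classify_gene_changes(inc, [], self.GENES)
        assert frame.loc["g1", "body_class"] == "UP"
        assert frame.loc["g1", "promoter_class"] == "NONE"

    def test_untouched_gene_is_none(self):
        frame = classify_gene_changes([], [], self.GENES)
        assert frame.loc["g1", "body_class"] == "NONE"
        assert frame.loc["g1", "promoter_class"] == "NONE"

    def test_promoter_window_is_200bp_around_tss(self):
        inc = [Interval("chr2L", 1050, 1090, sign=1, score=2.0)]
        frame = classify_gene_changes(inc, [], self.GENES)
        assert frame.loc["g1", "promoter_class"] == "UP"

    def test_ambiguous_resolved_by_weighted_area(self):
        """Increase of span 105 vs decrease of span 210 at equal |delta|: DOWN."""
        inc = [Interval("chr2L", 2000, 2105, sign=1, score=2.0)]
        dec = [Interval("chr2L", 3000, 3210, sign=-1, score=-2.0)]
        frame = classify_gene_changes(inc, dec, self.GENES)
        assert frame.loc["g1", "body_class"] == "AMBIGUOUS"
        assert frame.loc["g1", "body_resolved"] == "DOWN"

    def test_interval_outside_gene_ignored(self):
        inc = [Interval("chr2L", 8000, 9000, sign=1, score=3.0)]
        frame = classify_gene_changes(inc, [], self.GENES)
        assert frame.loc["g1", "body_class"] == "NONE"


class TestCategoryPercentages:
    def _classes(self, body):
        index = pd.Index([f"g{i}" for i in range(len(body))], name="gene_id")
        resolved = [c if c not in ("AMB_UP", "AMB_DOWN") else c[4:] for c in body]
        raw = ["AMBIGUOUS" if c.startswith("AMB_") else c for c in body]
        return pd.DataFrame({"body_class": raw, "body_resolved": resolved},
                            index=index)

    def test_simple_percentages(self):
        classes = self._classes(["DOWN", "DOWN", "NONE", "NONE"])
        groups = {"bound": pd.Series(True, index=classes.index)}
        table = category_percentages(classes, groups)
        assert table.loc["bound", "pct_down"] == pytest.approx(50.0)
        assert table.loc["bound", "pct_up"] == 0.0

    def test_ambiguous_counts_toward_resolution(self):
        """3 UP, 2 DOWN, 1 AMBIGUOUS->UP, 4 NONE -> 40% UP, 20% DOWN."""
        classes = self._classes(["UP", "UP", "UP", "DOWN", "DOWN", "AMB_UP",
                                 "NONE", "NONE", "NONE", "NONE"])
        table = category_percentages(
            classes, {"all": pd.Series(True, index=classes.index)})
        assert table.loc["all", "pct_up"] == pytest.approx(40.0)
        assert table.loc["all", "pct_down"] == pytest.approx(20.0)
        assert table.loc["all", "n_ambiguous"] == 1

    def test_empty_group_flagged_not_zero(self):
        classes = self._classes(["UP", "NONE"])
        table = category_percentages(
            classes, {"empty": pd.Series(False, index=classes.index)})
        assert not table.loc["empty", "defined"]
        assert np.isnan(table.loc["empty", "pct_up"])


class TestModelResults:
    def test_fit_summary_and_intervals(self):
        rng = np.random.default_rng(21)
        n = 3000
        starts = np.arange(n) * 35
        control = rng.normal(0, 0.8, n)
        depleted = control + rng.normal(0, 0.2, n)
        depleted[500:520] += 5.0  # one planted increase
        genes = [GeneModel("g1", "chr2L", "+", 500 * 35, 520 * 35)]
        model = DifferentialOccupancy(make_track(starts, control),
                                      make_track(starts, depleted), genes)
        res = model.fit()
        assert len(res.increases) >= 1
        assert res.gene_classes.loc["g1", "body_class"] in ("UP", "AMBIGUOUS")
        assert res.gene_deltas.loc["g1", "delta_total"] > 0
        text = res.summary()
        assert "null SD" in text and "increase intervals" in text

    def test_intervals_property_sorted(self):
        rng = np.random.default_rng(22)
        n = 2000
        starts = np.arange(n) * 35
        control = rng.normal(0, 0.8, n)
        depleted = control + rng.normal(0, 1.2, n)
        res = DifferentialOccupancy(make_track(starts, control),
                                    make_track(starts, depleted)).fit()
        ivs = res.intervals
        assert ivs == sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
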