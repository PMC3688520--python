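"""Cohesin-PcG chromatin-state classification."""

import numpy as np
import pandas as pd
import pytest

from polystate import (
    GeneModel,
    Interval,
    StateParams,
    classify_state,
    classify_states,
    cohesin_k27_overlap_span,
)
from polystate.states import STATES, active_gene_mask

GENE = GeneModel("g1", "chr2L", "+", 0, 2000)


class TestOverlapSpan:
    def test_partial_overlap(self):
        cohesin = [Interval("chr2L", 0, 1000)]
        k27 = [Interval("chr2L", 500, 2000)]
        assert cohesin_k27_overlap_span(cohesin, k27, GENE) == 500

    def test_disjoint_is_zero(self):
        cohesin = [Interval("chr2L", 0, 400)]
        k27 = [Interval("chr2L", 1000, 2000)]
        assert cohesin_k27_overlap_span(cohesin, k27, GENE) == 0

    def test_fragmented_overlaps_sum(self):
        """Three separate 400 bp overlaps total 1200 bp."""
        gene = GeneModel("g1", "chr2L", "+", 0, 10_000)
        cohesin = [Interval("chr2L", 0, 400), Interval("chr2L", 1000, 1400),
                   Interval("chr2L", 2000, 2400)]
        k27 = [Interval("chr2L", 0, 5000)]
        assert cohesin_k27_overlap_span(cohesin, k27, gene) == 1200

    def test_clipped_to_transcription_unit(self):
        cohesin = [Interval("chr2L", 0, 5000)]
        k27 = [Interval("chr2L", 0, 5000)]
        assert cohesin_k27_overlap_span(cohesin, k27, GENE) == 2000

    def test_overlapping_input_intervals_are_unioned(self):
        cohesin = [Interval("chr2L", 0, 600), Interval("chr2L", 400, 1000)]
        k27 = [Interval("chr2L", 0, 1000)]
        assert cohesin_k27_overlap_span(cohesin, k27, GENE) == 1000


def _bound(cohesin=0, pc=0, k27=0):
    return pd.Series({"cohesin": cohesin, "Pc": pc, "H3K27me3": k27})


class TestClassifyState:
    PARAMS = StateParams(pre_intervals=(Interval("chr2L", 200, 400),))

    def test_silenced_gene(self):
        """K27 + Pc bound, cohesin only inside the PRE, low expression."""
        intervals = {"cohesin": [Interval("chr2L", 250, 380)],
                     "H3K27me3": [Interval("chr2L", 0, 2000)]}
        call = classify_state(GENE, _bound(1, 1, 1), intervals,
                              expression=-2.0, cutoff=1.0, params=self.PARAMS)
        assert call["state"] == "SILENCED"
        assert call["cohesin_outside_pre"] == 0

    def test_active_gene(self):
        """Cohesin + Pc bound, no K27, high expression."""
        intervals = {"cohesin": [Interval("chr2L", 0, 300)], "H3K27me3": []}
        call = classify_state(GENE, _bound(1, 1, 0), intervals,
                              expression=4.0, cutoff=1.0, params=self.PARAMS)
        assert call["state"] == "ACTIVE"

    def test_restrained_gene(self):
        """Cohesin and K27 domains overlapping 2 kb or more."""
        gene = GeneModel("g1", "chr2L", "+", 0, 6000)
        intervals = {"cohesin": [Interval("chr2L", 0, 5000)],
                     "H3K27me3": [Interval("chr2L", 0, 6000)]}
        call = classify_state(gene, _bound(1, 1, 1), intervals,
                              expression=1.0, cutoff=1.0, params=self.PARAMS)
        assert call["state"] == "RESTRAINED"
        assert call["cohesin_k27_overlap_bp"] == 5000

    def test_unbound_gene_is_other(self):
        call = classify_state(GENE, _bound(0, 0, 0), {}, expression=0.0,
                              cutoff=1.0, params=self.PARAMS)
        assert call["state"] == "OTHER"

    def test_cohesin_outside_pre_blocks_silenced(self):
        intervals = {"cohesin": [Interval("chr2L", 250, 380),
                                 Interval("chr2L", 1000, 1400)],
                     "H3K27me3": [Interval("chr2L", 0, 2000)]}
        call = classify_state(GENE, _bound(1, 1, 1), intervals,
                              expression=-2.0, cutoff=1.0, params=self.PARAMS)
        assert call["state"] == "OTHER"
        assert call["cohesin_outside_pre"] == 1

    def test_without_pres_rule_degrades_to_bound_flag(self):
        params = StateParams()  # no PRE annotation
        intervals = {"H3K27me3": [Interval("chr2L", 0, 2000)]}
        call = classify_state(GENE, _bound(0, 1, 1), intervals,
                              expression=-2.0, cutoff=1.0, params=params)
        assert call["state"] == "SILENCED"
        assert call["pre_rule_degraded"] == 1

    def test_high_expression_blocks_silenced(self):
        intervals = {"cohesin": [], "H3K27me3": [Interval("chr2L", 0, 2000)]}
        call = classify_state(GENE, _bound(0, 1, 1), intervals,
                              expression=3.0, cutoff=1.0, params=self.PARAMS)
        assert call["state"] == "OTHER"

    def test_missing_factor_column_is_an_error(self):
        with pytest.raises(KeyError):
            classify_state(GENE, pd.Series({"cohesin": 1}), {}, 0.0, 1.0,
                           self.PARAMS)


class TestClassifyStates:
    def _small_cohort(self):
        genes = [GeneModel("act", "chr2L", "+", 0, 3000),
                 GeneModel("sil", "chr2L", "+", 10_000, 13_000),
                 GeneModel("res", "chr2L", "+", 20_000, 26_000),
                 GeneModel("oth", "chr2L", "+", 30_000, 33_000)]
        matrix = pd.DataFrame(
            {"cohesin": [1, 1, 1, 0], "Pc": [1, 1, 1, 0], "H3K27me3": [0, 1, 1, 0]},
            index=[g.gene_id for g in genes])
        intervals = {
            "cohesin": [Interval("chr2L", 0, 400),          # active promoter
                        Interval("chr2L", 10_200, 10_400),  # silenced PRE
                        Interval("chr2L", 20_000, 25_500)], # restrained domain
            "Pc": [],
            "H3K27me3": [Interval("chr2L", 10_000, 13_000),
                         Interval("chr2L", 20_000, 26_000)],
        }
        expression = pd.Series({"act": 4.0, "sil": -2.0, "res": 1.0, "oth": 0.0})
        params = StateParams(pre_intervals=(Interval("chr2L", 10_100, 10_500),))
        return genes, matrix, intervals, expression, params

    def test_each_gene_gets_its_state(self):
        genes, matrix, intervals, expression, params = self._small_cohort()
        frame = classify_states(genes, matrix, intervals, expression, params)
        assert frame["state"].to_dict() == {
            "act": "ACTIVE", "sil": "SILENCED", "res": "RESTRAINED", "oth": "OTHER"}

    def test_partition_every_gene_exactly_one_state(self):
        genes, matrix, intervals, expression, params = self._small_cohort()
        frame = classify_states(genes, matrix, intervals, expression, params)
        assert len(frame) == len(genes)
        assert frame["state"].isin(STATES).all()
        assert frame["state"].value_counts().sum() == len(genes)

    def test_raising_min_overlap_never_adds_restrained(self):
        genes, matrix, intervals, expression, params = self._small_cohort()
        counts = []
        for cutoff in (500, 2000, 5000, 6000):
            p = StateParams(restrained_min_overlap=cutoff,
                            pre_intervals=params.pre_intervals)
            frame = classify_states(genes, matrix, intervals, expression, p)
            counts.append(int((frame["state"] == "RESTRAINED").sum()))
        assert counts == sorted(counts, reverse=True)

    def test_default_cutoff_is_cohort_median(self):
        genes, matrix, intervals, expression, params = self._small_cohort()
        frame = classify_states(genes, matrix, intervals, expression, params)
        assert frame.attrs["expression_cutoff"] == pytest.approx(
            float(expression.median()))


class TestActiveGeneMask:
    def test_excludes_k27_and_low_expression(self):
        matrix = pd.DataFrame({"H3K27me3": [0, 1, 0]}, index=["a", "b", "c"])
        expr = pd.Series({"a": 3.0, "b": 3.0, "c": -3.0})
        mask = active_gene_mask(matrix, expr, StateParams(expression_cutoff=0.0))
        assert mask.to_dict() == {"a": True, "b": False, "c": False}

    def test_polii_binding_rescues_low_expression(self):
        matrix = pd.DataFrame({"H3K27me3": [0, 0], "Rpb3": [1, 0]},
                              index=["a", "b"])
        expr = pd.Series({"a": -3.0, "b": -3.0})
        mask = active_gene_mask(matrix, expr, StateParams(expression_cutoff=0.0),
                                polii_factor="Rpb3")
        assert mask.to_dict() == {"a": True, "b": False}


class TestSyntheticRecovery:
    def test_states_recovered_from_generated_tracks(self, small_dataset):
        """End-to-end: call intervals from noisy tracks, classify, compare truth."""
        from polystate import BindingCallParams, binding_matrix, call_bound_intervals

        ds = small_dataset
        params = BindingCallParams(tau=2.0)
        calls = {f: call_bound_intervals(ds.track(f), params)
                 for f in ("cohesin", "Pc", "H3K27me3")}
        matrix = binding_matrix(calls, ds.genes)
        sp = StateParams(pre_intervals=tuple(ds.truth.pre_intervals))
        frame = classify_states(ds.genes, matrix, calls, ds.expression, sp)
        truth = ds.truth.genes["state"].str.upper()
        agreement = (frame["state"] == truth).mean()
        assert agreement >= 0.98
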