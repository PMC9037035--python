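"""ISE training, index scoring, cross-validation, and enrichment analysis."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ppiscreen as pp
from ppiscreen.criteria import BEST, WORST
from ppiscreen.descriptors import DescriptorTable
from ppiscreen.ise import (Clause, DescriptorFilter, EnrichmentCurve, ISEModel,
                           ISEParams)


def small_table(n=40, d=6, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    X[: n // 2, :2] += shift
    ids = [f"m{i}" for i in range(n)]
    labels = pd.Series([BEST] * (n // 2) + [WORST] * (n - n // 2), index=ids)
    frame = pd.DataFrame(X, index=ids, columns=[f"d{j}" for j in range(d)])
    return DescriptorTable(values=frame, labels=labels)


class TestBinDescriptors:
    def test_quintile_edges_on_1_to_100(self):
        frame = pd.DataFrame({"v": np.arange(1.0, 101.0)})
        binning = pp.bin_descriptors(DescriptorTable(values=frame), n_bins=5)
        expected = np.quantile(np.arange(1.0, 101.0), [0.2, 0.4, 0.6, 0.8])
        assert np.allclose(binning.edges[0], expected)
        assert binning.n_bins == [5]

    def test_constant_column_single_bin_with_warning(self):
        frame = pd.DataFrame({"v": np.ones(10)})
        with pytest.warns(UserWarning, match="single bin"):
            binning = pp.bin_descriptors(DescriptorTable(values=frame), n_bins=5)
        assert binning.n_bins == [1]

    def test_bin_populations_near_equal(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame({"v": rng.normal(size=1000)})
        binning = pp.bin_descriptors(DescriptorTable(values=frame), n_bins=10)
        assigned = binning.assign(frame.to_numpy())
        counts = np.bincount(assigned[:, 0], minlength=10)
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 1000


class TestMcc:
    def test_perfect_classification(self):
        assert pp.mcc(68, 0, 69, 0) == 1.0

    def test_worked_example(self):
        assert pp.mcc(5, 1, 9, 5) == pytest.approx(0.4364, abs=1e-4)

    def test_no_association_is_zero(self):
        assert pp.mcc(7, 7, 7, 7) == 0.0

    def test_zero_denominator_factor_is_zero(self):
        assert pp.mcc(0, 0, 5, 5) == 0.0

    def test_all_zero_is_error(self):
        with pytest.raises(pp.ConfigurationError):
            pp.mcc(0, 0, 0, 0)

    @given(st.tuples(*[st.integers(0, 200)] * 4))
    @settings(max_examples=1000, derandomize=True)
    def test_label_swap_antisymmetry(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        assert pp.mcc(tp, fp, tn, fn) == pytest.approx(-pp.mcc(fn, tn, fp, tp), abs=1e-12)
        assert -1.0 <= pp.mcc(tp, fp, tn, fn) <= 1.0


class TestTrainIse:
    def test_planted_signal_yields_informative_top_filter(self, planted_table):
        table, informative = planted_table
        model = pp.train_ise(table, seed=1)
        assert model.filters, "expected at least one surviving filter"
        top = model.filters[0]
        assert top.train_mcc >= 0.7
        assert any(c.descriptor in informative for c in top.clauses)
        assert model.filters == sorted(model.filters,
                                       key=lambda f: -f.train_mcc)

    def test_pure_noise_yields_empty_or_tiny_model(self):
        table, _ = pp.make_learning_set(
            pp.LearningSetSpec(effect_size=0.0, seed=123))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = pp.train_ise(table, seed=9)
        assert len(model.filters) <= 2

    def test_deterministic_serialization(self, planted_table):
        table, _ = planted_table
        a = pp.train_ise(table, seed=3).to_json()
        b = pp.train_ise(table, seed=3).to_json()
        assert a == b
        assert pp.train_ise(table, seed=4).to_json() != a

    def test_json_round_trip(self, planted_table):
        table, _ = planted_table
        model = pp.train_ise(table, seed=3)
        again = ISEModel.from_json(model.to_json())
        assert again.filters == model.filters
        assert again.descriptor_hash == model.descriptor_hash

    def test_single_label_is_error(self):
        table = small_table()
        table.labels[:] = BEST
        with pytest.raises(pp.ModelingError):
            pp.train_ise(table, seed=0)

    def test_unlabeled_table_is_error(self):
        table, _ = pp.make_learning_set(pp.LearningSetSpec(seed=0))
        with pytest.raises(pp.ModelingError):
            pp.train_ise(DescriptorTable(values=table.values), seed=0)


def make_model(n_filters, split):
    """Model with `split` filters passing x <= 1 and the rest passing x > 1."""
    filters = [
        DescriptorFilter((Clause("x", -math.inf, 1.0),), 0.8)
        if i < split else
        DescriptorFilter((Clause("x", 1.0 + i * 1e-9, math.inf),), 0.75)
        for i in range(n_filters)
    ]
    return ISEModel(filters, ["x"], "h", ISEParams(), 0)


class TestScoreIndex:
    def test_pass_all_and_fail_all(self):
        model = make_model(10, 10)
        assert pp.score_index(model, {"x": 0.5}).index == 1.0
        assert pp.score_index(model, {"x": 5.0}).index == -1.0

    def test_partial_pass_arithmetic(self):
        model = make_model(919, 600)
        score = pp.score_index(model, {"x": 0.5})
        assert score.n_pass == 600
        assert score.n_fail == 319
        assert score.index == pytest.approx((600 - 319) / 919, abs=1e-12)
        assert score.index == pytest.approx(0.3058, abs=1e-4)

    def test_missing_descriptor_named_in_error(self):
        model = make_model(3, 3)
        with pytest.raises(pp.ModelingError, match="x"):
            pp.score_index(model, {"y": 1.0})

    def test_index_strictly_increasing_in_n_pass(self):
        indexes = [pp.score_index(make_model(10, k), {"x": 0.5}).index
                   for k in range(11)]
        assert all(b > a for a, b in zip(indexes, indexes[1:]))
        assert all(-1.0 <= v <= 1.0 for v in indexes)

    def test_score_table_matches_row_scoring(self, planted_table):
        table, _ = planted_table
        model = pp.train_ise(table, seed=1)
        frame = table.values.iloc[:20]
        vectorized = pp.score_table(model, frame)
        for mol_id, row in frame.iterrows():
            single = pp.score_index(model, row)
            assert vectorized.loc[mol_id, "index"] == pytest.approx(single.index)
            assert vectorized.loc[mol_id, "n_pass"] == single.n_pass


class TestCrossValidate:
    def test_stratified_fold_sizes(self, planted_table):
        table, _ = planted_table
        result = pp.cross_validate(table, 5, seed=2)
        per_fold = result.scores.groupby(["fold", "label"]).size().unstack()
        assert sorted(per_fold[BEST]) == [13, 13, 14, 14, 14]
        assert sorted(per_fold[WORST]) == [13, 14, 14, 14, 14]

    def test_every_molecule_scored_exactly_once(self, planted_table):
        table, _ = planted_table
        result = pp.cross_validate(table, 5, seed=2)
        assert sorted(result.scores.index) == sorted(table.values.index)
        assert len(result.scores) == 137

    def test_final_model_is_deduplicated_union(self, planted_table):
        table, _ = planted_table
        result = pp.cross_validate(table, 5, seed=2)
        keys = [tuple((c.descriptor, c.lower, c.upper) for c in f.clauses)
                for f in result.final_model.filters]
        assert len(keys) == len(set(keys))
        fold_keys = {tuple((c.descriptor, c.lower, c.upper) for c in f.clauses)
                     for m in result.fold_models for f in m.filters}
        assert set(keys) == fold_keys

    def test_class_too_small_for_folds_is_error(self):
        table = small_table(n=12)
        with pytest.raises(pp.ModelingError):
            pp.cross_validate(table, 10, seed=0)


class TestEnrichment:
    def test_baseline_ratio_at_lowest_threshold(self):
        rng = np.random.default_rng(0)
        idx = rng.uniform(-1, 1, 137)
        labels = np.array([BEST] * 68 + [WORST] * 69)
        curve = pp.enrichment_curve(idx, labels)
        assert curve.thresholds[0] == -1.0
        assert curve.tp[0] == 68
        assert curve.fp[0] == 69
        assert curve.ratio[0] == pytest.approx(68 / 69, abs=1e-12)
        assert round(curve.ratio[0]) == 1  # "one" at the printed precision

    def test_perfect_separation_gives_infinite_ratio(self):
        idx = np.array([0.8, 0.9, -0.8, -0.9])
        labels = np.array([True, True, False, False])
        curve = pp.enrichment_curve(idx, labels)
        assert np.isinf(curve.ratio[curve.thresholds > 0]).all()

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        idx = rng.choice(np.linspace(-1, 1, 21), 60)
        pos = rng.random(60) < 0.5
        if not pos.any():
            pos[0] = True
        curve = pp.enrichment_curve(idx, pos)
        for t, tp, fp in zip(curve.thresholds, curve.tp, curve.fp):
            assert tp == int(sum(1 for v, p in zip(idx, pos) if p and v >= t))
            assert fp == int(sum(1 for v, p in zip(idx, pos) if not p and v >= t))
        assert all(x >= y for x, y in zip(curve.tp, curve.tp[1:]))
        assert all(x >= y for x, y in zip(curve.fp, curve.fp[1:]))

    def test_no_positives_is_error(self):
        with pytest.raises(pp.ModelingError):
            pp.enrichment_curve(np.array([0.1, 0.2]), np.array([False, False]))


class TestSelectCutoff:
    def make_curve(self):
        return EnrichmentCurve(
            thresholds=np.array([-1.0, 0.0, 0.75]),
            tp=np.array([68, 40, 33]),
            fp=np.array([69, 10, 2]),
            ratio=np.array([68 / 69, 4.0, 16.5]),
        )

    def test_smallest_threshold_reaching_ratio(self):
        assert pp.select_cutoff(self.make_curve(), 10.0) == 0.75

    def test_zero_ratio_selects_lowest_threshold(self):
        assert pp.select_cutoff(self.make_curve(), 0.0) == -1.0

    def test_unattainable_ratio_reports_maximum(self):
        with pytest.raises(pp.ModelingError, match="16.5"):
            pp.select_cutoff(self.make_curve(), 100.0)
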