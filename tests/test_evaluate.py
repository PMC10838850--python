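"""MIE prediction rule, metrics, and report arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sinusmie import (ClassifierConfig, LabeledSinus, SamplingScheme,
                      SinusInstance, auprc, cross_fold_summary, ensemble_mean,
                      evaluate_fold, f1, make_folds, percentage_increase,
                      percentage_increase_report, relative_decrease,
                      sampling_strategy_comparison)
from sinusmie.dataset import labels_from_truths
from sinusmie.evaluate import EnsemblePrediction, ensemble_predict
from sinusmie.reference_results import ARCHITECTURE_AUPRC


def make_instance(pid="p0", side="left", idx=1, value=0.0):
    return SinusInstance(patient_id=pid, side=side, instance_index=idx,
                         centroid=(10.0, 10.0, 10.0), patch_size=9,
                         data=np.full((64, 64, 64), value, dtype=np.float32))


class StubModel:
    """Stand-in classifier returning a fixed or data-derived probability."""

    def __init__(self, proba_fn):
        self.proba_fn = proba_fn

    class _Net:
        def __init__(self, outer):
            self.outer = outer

        def forward(self, x, train=False):
            # x is the prepared (B,1,16,16,16) input; recover a scalar per item
            p = np.array([self.outer.proba_fn(xi) for xi in x])
            eps = 1e-9
            p = np.clip(p, eps, 1 - eps)
            return np.stack([np.log(1 - p), np.log(p)], axis=1)

    @property
    def net(self):
        return StubModel._Net(self)


def brute_force_auprc(labels, scores):
    """Exhaustive-threshold average precision: sweep every distinct score as
    threshold in descending order and accumulate (R_k - R_{k-1}) * P_k."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestEnsembleRule:
    def test_mean_of_explicit_probabilities(self):
        np.testing.assert_allclose(
            ensemble_mean([(0.2, 0.8), (0.6, 0.4)]), (0.4, 0.6))

    def test_single_instance_reduces_to_itself(self):
        np.testing.assert_allclose(ensemble_mean([(0.3, 0.7)]), (0.3, 0.7))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=20),
           st.integers(2, 4))
    def test_duplication_linearity(self, p_anoms, reps):
        """Ensembling a duplicated instance list equals the original
        ensemble exactly (Eq. linearity)."""
        pairs = [(1 - p, p) for p in p_anoms]
        np.testing.assert_allclose(ensemble_mean(pairs * reps),
                                   ensemble_mean(pairs), atol=1e-12)

    def test_identical_instances_give_common_pair(self):
        np.testing.assert_allclose(
            ensemble_mean([(0.25, 0.75)] * 7), (0.25, 0.75))

    def test_ensemble_predict_mixed_sinuses_rejected(self):
        model = StubModel(lambda x: 0.5)
        insts = [make_instance("p0", "left"), make_instance("p1", "left")]
        with pytest.raises(ValueError, match="multiple sinuses"):
            ensemble_predict(model, insts)

    def test_ensemble_predict_averages_model_outputs(self):
        model = StubModel(lambda x: float(np.clip(x.mean() * 4, 0.01, 0.99)))
        insts = [make_instance(value=v, idx=i + 1)
                 for i, v in enumerate((0.1, 0.2, 0.3))]
        pred = ensemble_predict(model, insts)
        from sinusmie.classifier import predict_proba_batch
        expect = predict_proba_batch(model, insts).mean(axis=0)
        np.testing.assert_allclose(pred.y_hat, expect, atol=1e-12)
        assert pred.n_instances == 3

    def test_invalid_probability_pair_rejected(self):
        with pytest.raises(ValueError):
            EnsemblePrediction("p", "left", np.array([0.7, 0.7]), 1,
                               np.array([[0.7, 0.7]]))


class TestAUPRC:
    def test_perfect_separation(self):
        assert auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    @pytest.mark.parametrize("labels", [[1, 0, 0, 1, 0], [1, 1, 0]])
    def test_constant_scores_equal_prevalence(self, labels):
        pi = np.mean(labels)
        assert auprc(labels, [0.5] * len(labels)) == pytest.approx(pi)

    def test_hand_case_matches_enumeration(self):
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]
        assert auprc(labels, scores) == pytest.approx(
            brute_force_auprc(labels, scores))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=2, max_size=12))
    def test_agrees_with_exhaustive_threshold_oracle(self, items):
        labels = [l for l, _ in items]
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        scores = [s for _, s in items]
        assert auprc(labels, scores) == pytest.approx(
            brute_force_auprc(labels, scores), abs=1e-9)

    def test_permutation_invariance(self, rng):
        labels = [0, 1, 0, 1, 1, 0]
        scores = [0.2, 0.9, 0.4, 0.6, 0.55, 0.3]
        base = auprc(labels, scores)
        for _ in range(5):
            perm = rng.permutation(6)
            assert auprc(np.array(labels)[perm],
                         np.array(scores)[perm]) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auprc([1, 1, 1], [0.5, 0.6, 0.7])


class TestF1:
    def test_perfect(self):
        assert f1([0, 1, 1], [0, 1, 1]) == 1.0

    def test_hand_contingency(self):
        # TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1) = 2/3
        assert f1([1, 1, 1, 0, 0], [1, 1, 0, 1, 0]) == pytest.approx(2 / 3)

    def test_all_negative_predictions_zero(self):
        assert f1([1, 0, 0], [0, 0, 0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            f1([1, 0], [1])

    def test_permutation_invariance(self, rng):
        y = [1, 0, 1, 1, 0, 0]
        p = [1, 0, 0, 1, 1, 0]
        base = f1(y, p)
        perm = rng.permutation(6)
        assert f1(np.array(y)[perm], np.array(p)[perm]) == pytest.approx(base)


class TestCrossFoldSummary:
    def test_constant_folds(self):
        m, s = cross_fold_summary([0.8, 0.8, 0.8])
        assert m == pytest.approx(0.8)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_two_folds_hand_arithmetic(self):
        m, s = cross_fold_summary([0.7, 0.9])
        assert m == pytest.approx(0.8)
        assert s == pytest.approx(np.sqrt(((0.7 - 0.8) ** 2 +
                                           (0.9 - 0.8) ** 2) / 1))

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            cross_fold_summary([0.8])
        with pytest.raises(ValueError):
            cross_fold_summary([])


class TestReports:
    def test_identical_columns_zero(self):
        t = pd.DataFrame({"family": ["a", "a"], "baseline": [0.5, 0.7],
                          "sampled": [0.5, 0.7], "sampled_mie": [0.5, 0.7]})
        rep = percentage_increase_report(t)
        assert (rep["mean_increase_pct"] == 0).all()
        assert (rep["sd_increase_pct"] == 0).all()

    def test_population_sd_hand_case(self):
        t = pd.DataFrame({"family": ["f", "f"], "baseline": [1.0, 1.0],
                          "sampled": [1.1, 1.2], "sampled_mie": [1.1, 1.2]})
        rep = percentage_increase_report(t)
        row = rep[rep.variant == "sampled"].iloc[0]
        assert row.mean_increase_pct == pytest.approx(15.0)
        assert row.sd_increase_pct == pytest.approx(5.0)   # population sd

    def test_zero_baseline_rejected(self):
        t = pd.DataFrame({"family": ["f"], "baseline": [0.0],
                          "sampled": [0.5], "sampled_mie": [0.5]})
        with pytest.raises(ValueError):
            percentage_increase_report(t)

    def test_published_table_statistics(self):
        """The percent-increase summary of the published per-architecture
        AUPRC values reproduces the reported family-level statistics."""
        rep = percentage_increase_report(ARCHITECTURE_AUPRC).set_index(
            ["family", "variant"])
        res = rep.loc[("resnet3d", "sampled")]
        assert res.mean_increase_pct == pytest.approx(21.86, abs=0.05)
        assert res.sd_increase_pct == pytest.approx(11.92, abs=0.05)
        den = rep.loc[("densenet3d", "sampled")]
        assert den.mean_increase_pct == pytest.approx(4.27, abs=0.05)
        assert den.sd_increase_pct == pytest.approx(5.04, abs=0.05)
        den_mie = rep.loc[("densenet3d", "sampled_mie")]
        assert den_mie.mean_increase_pct == pytest.approx(9.85, abs=0.05)
        assert den_mie.sd_increase_pct == pytest.approx(4.02, abs=0.05)

    def test_relative_decrease(self):
        assert relative_decrease(0.89, 0.88) == pytest.approx(1.12, abs=0.01)
        assert relative_decrease(0.7, 0.7) == 0.0
        with pytest.raises(ValueError):
            relative_decrease(0.0, 0.5)

    def test_percentage_increase_errors(self):
        with pytest.raises(ValueError):
            percentage_increase(0.0, 1.0)
        assert percentage_increase(0.8, 0.88) == pytest.approx(10.0)


class TestEvaluateFold:
    def _sinus_map(self, labels, n=3):
        out = {}
        for l in labels:
            out[(l.patient_id, l.side)] = [
                make_instance(l.patient_id, l.side, i + 1,
                              value=float(l.label))
                for i in range(n)]
        return out

    def _labels(self):
        return [LabeledSinus(f"p{i}", s, y) for i, s, y in
                [(0, "left", 1), (0, "right", 0), (1, "left", 0),
                 (1, "right", 1), (2, "left", 0), (2, "right", 0)]]

    @staticmethod
    def _graded_instance(pid, side, idx, frac):
        """Binary cube whose mean (preserved by pooling) encodes ``frac``."""
        data = np.zeros((64, 64, 64), dtype=np.float32)
        data[:round(64 * frac)] = 1.0
        return SinusInstance(patient_id=pid, side=side, instance_index=idx,
                             centroid=(10.0, 10.0, 10.0), patch_size=9,
                             data=data)

    @pytest.mark.parametrize("use_mie", [True, False])
    def test_truth_returning_stub_is_perfect(self, use_mie):
        """A stub whose probability equals the true label yields perfect
        AUPRC and F1 in either evaluation mode."""
        labels = self._labels()
        sinus_map = {
            (l.patient_id, l.side): [
                self._graded_instance(l.patient_id, l.side, 1,
                                      0.9 if l.label else 0.1)]
            for l in labels}
        model = StubModel(lambda x: float(np.clip(x.mean(), 0.01, 0.99)))
        res = evaluate_fold(model, sinus_map, labels, use_mie=use_mie)
        assert res["auprc"] == 1.0
        assert res["f1"] == 1.0

    def test_constant_half_stub_ties_classified_positive(self):
        labels = self._labels()
        sinus_map = self._sinus_map(labels, n=2)
        model = StubModel(lambda x: 0.5)
        res = evaluate_fold(model, sinus_map, labels, use_mie=True)
        # every sinus predicted positive at the tie-break
        n_pos = sum(l.label for l in labels)
        expect_f1 = 2 * n_pos / (2 * n_pos + (len(labels) - n_pos))
        assert res["f1"] == pytest.approx(expect_f1)
        assert res["auprc"] == pytest.approx(n_pos / len(labels))

    def test_mie_vs_single_unit_sizes(self):
        labels = self._labels()
        sinus_map = self._sinus_map(labels, n=4)
        model = StubModel(lambda x: 0.5)
        res = evaluate_fold(model, sinus_map, labels, use_mie=True)
        assert res["n_sinuses"] == len(labels)
        assert res["evaluation_unit"] == "per_sinus_MIE"
        res1 = evaluate_fold(model, sinus_map, labels, use_mie=False)
        assert res1["evaluation_unit"] == "per_instance"


class TestStrategyComparison:
    @pytest.mark.parametrize("n_strategies", [2])
    def test_report_shape_and_determinism(self, small_cohort, small_labels,
                                          n_strategies):
        spec, volumes, truths = small_cohort
        strategies = [SamplingScheme(mode="equidistant", n=2, seed=3),
                      SamplingScheme(mode="gaussian", n=2, seed=3)][:n_strategies]
        config = ClassifierConfig(family="tiny3d", epochs=2,
                                  learning_rate=1e-3, seed=4)
        folds = make_folds(small_labels, k=2, seed=5, tolerance=0.25)
        kwargs = dict(volumes=volumes, labels=small_labels,
                      strategies=strategies, model=spec.centroid_model,
                      patch_size=9, config=config, folds=folds)
        a = sampling_strategy_comparison(**kwargs)
        assert len(a) == n_strategies
        assert {"strategy", "auprc_mean", "auprc_sd", "f1_mean",
                "f1_sd"} <= set(a.columns)
        b = sampling_strategy_comparison(**kwargs)
        pd.testing.assert_frame_equal(a, b)
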