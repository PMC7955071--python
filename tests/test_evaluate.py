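"""Confusion matrix, recall/precision/F1 and Cohen's kappa."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from somnoband.classify import ClassifierSpec, CVPlan, cross_validate
from somnoband.evaluate import (
    ConfusionMatrix,
    EvaluationReport,
    confusion,
    kappa,
    metric_set,
    prf,
)
from somnoband.synthetic import generate_feature_table

from .oracles import kappa_reference


def cm(counts, classes=("OSA", "CSA", "NB")):
    counts = np.asarray(counts, dtype=float)
    return ConfusionMatrix(counts=counts, classes=tuple(classes[: len(counts)]))


class TestConfusion:
    def test_perfect_agreement_is_diagonal(self):
        y = ["OSA", "CSA", "NB", "NB", "OSA"]
        m = confusion(y, y)
        assert np.trace(m.counts) == 5
        assert m.counts.sum() == 5
        assert m.classes == ("OSA", "CSA", "NB")

    def test_single_predicted_class_single_column(self):
        m = confusion(["OSA", "CSA", "NB"], ["NB", "NB", "NB"])
        nb_col = list(m.classes).index("NB")
        assert m.counts[:, nb_col].sum() == 3
        assert m.counts.sum(axis=0)[np.arange(3) != nb_col].sum() == 0

    def test_two_swaps_off_diagonal(self):
        y_true = ["OSA", "OSA", "CSA", "CSA", "NB", "NB"]
        y_pred = ["OSA", "CSA", "OSA", "CSA", "NB", "NB"]
        m = confusion(y_true, y_pred)
        assert m.counts.sum() - np.trace(m.counts) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            confusion(["OSA"], ["OSA", "NB"])

    def test_non_alphabet_labels_sorted(self):
        m = confusion(["x", "y"], ["y", "x"])
        assert m.classes == ("x", "y")


class TestPRF:
    def test_perfect_diagonal_all_ones(self):
        m = cm([[5, 0, 0], [0, 7, 0], [0, 0, 9]])
        for i in range(3):
            assert prf(m, i) == (1.0, 1.0, 1.0)

    def test_hand_computed_example(self):
        # class 0: TP=8, FN=2, FP=4
        m = cm([[8, 2], [4, 20]], classes=("OSA", "NB"))
        recall, precision, f1 = prf(m, 0)
        assert recall == pytest.approx(0.8)
        assert precision == pytest.approx(2 / 3)
        assert f1 == pytest.approx(2 * (2 / 3 * 0.8) / (2 / 3 + 0.8))
        assert f1 == pytest.approx(0.727272727272, abs=1e-9)

    def test_degenerate_class_reports_zero_with_warning(self):
        m = cm([[4, 0, 0], [0, 6, 0], [0, 0, 0]])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            recall, precision, f1 = prf(m, 2)
        assert (recall, precision, f1) == (0.0, 0.0, 0.0)


class TestKappa:
    def test_perfect_diagonal_is_one(self):
        assert kappa(cm([[50, 0, 0], [0, 3, 0], [0, 0, 17]])) == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        assert kappa(cm([[25, 25], [25, 25]], ("A", "B"))) == pytest.approx(0.0)

    def test_matches_independent_arithmetic(self):
        counts = np.array([[50, 10, 5], [8, 40, 7], [2, 3, 60]], dtype=float)
        ours = kappa(cm(counts))
        assert ours == pytest.approx(kappa_reference(counts), abs=1e-12)

    def test_matches_sklearn_on_label_vectors(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(["OSA", "CSA", "NB"], size=200)
        y_pred = np.where(rng.random(200) < 0.6, y_true,
                          rng.choice(["OSA", "CSA", "NB"], size=200))
        ours = kappa(confusion(y_true, y_pred))
        assert ours == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            kappa(cm([[10, 0], [0, 0]], ("A", "B")))

    @pytest.mark.parametrize("seed", range(5))
    def test_kappa_at_most_accuracy_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(3, 3)).astype(float)
        counts += np.eye(3)  # avoid degenerate marginals
        m = cm(counts)
        p_o = np.trace(counts) / counts.sum()
        assert kappa(m) <= p_o + 1e-12
        perm = rng.permutation(3)
        m_perm = cm(counts[np.ix_(perm, perm)])
        assert kappa(m_perm) == pytest.approx(kappa(m), abs=1e-12)
        a, b = metric_set(m), metric_set(m_perm)
        assert a.macro_f1 == pytest.approx(b.macro_f1, abs=1e-12)
        assert a.macro_recall == pytest.approx(b.macro_recall, abs=1e-12)

    def test_kappa_one_only_for_diagonal(self):
        off = cm([[10, 1, 0], [0, 9, 0], [0, 0, 12]])
        assert kappa(off) < 1.0


class TestMetricSet:
    def test_micro_recall_equals_accuracy(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 40, size=(3, 3)).astype(float)
        m = cm(counts)
        tp = np.diag(counts)
        micro_recall = tp.sum() / counts.sum()
        assert metric_set(m).accuracy == pytest.approx(micro_recall)

    def test_f1_is_harmonic_mean(self):
        m = cm([[30, 5, 2], [4, 25, 6], [1, 3, 40]])
        ms = metric_set(m)
        for c in m.classes:
            p, r = ms.precision[c], ms.recall[c]
            assert ms.f1[c] == pytest.approx(2 * p * r / (p + r))


class TestReportRoundTrip:
    def test_json_round_trip_reproduces_metrics(self, tmp_path):
        fm = generate_feature_table(n=120, effect_size=2.0, seed=2)
        rep = cross_validate(
            ClassifierSpec(kind="knn"), fm.values, fm.labels, CVPlan(n_folds=5)
        )
        rep.to_json(tmp_path / "rep.json")
        back = EvaluationReport.from_json(tmp_path / "rep.json")
        assert back.mean_accuracy == rep.mean_accuracy
        assert back.metrics.kappa == rep.metrics.kappa
        assert back.metrics.recall == rep.metrics.recall
        np.testing.assert_array_equal(back.total_counts, rep.total_counts)
        np.testing.assert_array_equal(back.averaged_matrix, rep.averaged_matrix)
        for a, b in zip(back.fold_matrices, rep.fold_matrices):
            np.testing.assert_array_equal(a, b)
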