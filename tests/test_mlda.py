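import numpy as np
import pytest

from fcdiscrim.mlda import (
    FoldPrediction,
    MaxUncertaintyLDA,
    loocv,
    performance_metrics,
)
from fcdiscrim.permselect import CovariateTable, FeatureTable


def _spherical_classes(mu1, mu2, a=1.0):
    """Two classes whose pooled within-class covariance is exactly a
    multiple of the identity (so max-uncertainty regularisation is a no-op)."""
    mu1, mu2 = np.asarray(mu1, float), np.asarray(mu2, float)
    f = mu1.size
    offsets = np.vstack([a * np.eye(f), -a * np.eye(f)])
    x1 = mu1 + offsets
    x2 = mu2 + offsets
    x = np.vstack([x1, x2])
    y = np.array(["A"] * len(x1) + ["B"] * len(x2))
    return x, y


class TestMldaFit:
    def test_equal_eigenvalues_reduce_to_classical_lda(self):
        mu1, mu2 = np.array([1.0, 2.0, 0.5]), np.array([-1.0, 0.0, 1.5])
        x, y = _spherical_classes(mu1, mu2)
        res = MaxUncertaintyLDA(x, y, class_order=("A", "B")).fit()
        # pooled covariance is c*I so w must be parallel to mu1 - mu2
        w = res.discriminant
        direction = (mu1 - mu2) / np.linalg.norm(mu1 - mu2)
        w_unit = w / np.linalg.norm(w)
        assert np.abs(w_unit - direction).max() < 1e-10

    def test_matches_sklearn_when_regularization_inactive(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        mu1, mu2 = np.array([1.0, 0.0, 0.0, 2.0]), np.array([0.0, 1.0, 1.0, 0.0])
        x, y = _spherical_classes(mu1, mu2, a=0.8)
        res = MaxUncertaintyLDA(x, y, class_order=("A", "B")).fit()
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(x, y)
        test = np.random.default_rng(0).standard_normal((40, 4)) + (mu1 + mu2) / 2
        ours, _ = res.predict(test)
        theirs = sk.predict(test)
        assert (ours == theirs).mean() == 1.0

    def test_more_features_than_samples_fits(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 20))
        y = np.array(["A"] * 4 + ["B"] * 4)
        res = MaxUncertaintyLDA(x, y).fit()
        assert np.isfinite(res.discriminant).all()

    def test_regularized_eigenvalue_floor(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 15))  # rank-deficient pooled covariance
        y = np.array(["A"] * 5 + ["B"] * 5)
        model = MaxUncertaintyLDA(x, y)
        res = model.fit()
        x1, x2 = x[y == "A"], x[y == "B"]
        s1 = (x1 - x1.mean(0)).T @ (x1 - x1.mean(0))
        s2 = (x2 - x2.mean(0)).T @ (x2 - x2.mean(0))
        sp = (s1 + s2) / (len(x) - 2)
        raw = np.linalg.eigvalsh(sp)
        reg = np.linalg.eigvalsh(res.pooled_cov_regularized)
        lam_bar = raw.mean()
        assert reg.min() >= lam_bar - 1e-10
        # eigenvalues above the mean are untouched
        np.testing.assert_allclose(
            reg[reg > lam_bar + 1e-8], raw[raw > lam_bar + 1e-8], atol=1e-10
        )

    def test_widely_separated_classes_perfect_training_accuracy(self):
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal((20, 5))
        x2 = rng.standard_normal((20, 5)) + 10.0
        x = np.vstack([x1, x2])
        y = np.array(["P"] * 20 + ["C"] * 20)
        res = MaxUncertaintyLDA(x, y).fit()
        labels, _ = res.predict(x)
        assert (labels == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            MaxUncertaintyLDA(np.zeros((4, 2)), np.array(["A"] * 4))

    def test_summary_mentions_classes(self):
        x, y = _spherical_classes([1.0, 0.0], [0.0, 1.0])
        text = MaxUncertaintyLDA(x, y).fit().summary()
        assert "A vs B" in text


class TestPredict:
    def _fitted(self):
        x, y = _spherical_classes([2.0, 0.0], [-2.0, 0.0])
        return MaxUncertaintyLDA(x, y, class_order=("A", "B"), tie_label="A").fit()

    def test_class_mean_classified_to_own_class(self):
        res = self._fitted()
        labels, _ = res.predict(res.class_means[0][None, :])
        assert labels[0] == "A"

    def test_midpoint_tie_goes_to_patient_class(self):
        res = self._fitted()
        mid = (res.class_means[0] + res.class_means[1]) / 2
        labels, scores = res.predict(mid[None, :])
        assert scores[0] == pytest.approx(0.0, abs=1e-12)
        assert labels[0] == "A"

    def test_translation_invariance(self):
        x, y = _spherical_classes([1.0, 1.0, 0.0], [0.0, -1.0, 2.0])
        shift = np.array([5.0, -3.0, 11.0])
        rng = np.random.default_rng(4)
        test = rng.standard_normal((10, 3))
        res1 = MaxUncertaintyLDA(x, y, class_order=("A", "B")).fit()
        res2 = MaxUncertaintyLDA(x + shift, y, class_order=("A", "B")).fit()
        l1, _ = res1.predict(test)
        l2, _ = res2.predict(test + shift)
        assert (l1 == l2).all()

    def test_dimension_mismatch_rejected(self):
        res = self._fitted()
        with pytest.raises(ValueError):
            res.predict(np.zeros((1, 5)))


def _toy_cohort(rng, n_pos=8, n_neg=8, n_feat=6, shift=3.0):
    x = rng.standard_normal((n_pos + n_neg, n_feat))
    x[:n_pos, :2] += shift
    y = np.array(["PD"] * n_pos + ["NC"] * n_neg)
    ids = [f"sub-{i:03d}" for i in range(n_pos + n_neg)]
    table = FeatureTable(x, [(i, "e_nodal") for i in range(n_feat)], ids)
    cov = CovariateTable(
        rng.uniform(40, 80, n_pos + n_neg), rng.integers(0, 2, n_pos + n_neg).astype(float)
    )
    return table, y, cov


class TestLoocv:
    def test_one_prediction_per_subject(self):
        rng = np.random.default_rng(5)
        table, y, cov = _toy_cohort(rng)
        preds = loocv(table, y, cov, positive_class="PD", n_permutations=100, seed=0)
        assert len(preds) == 16
        assert sorted(p.subject_id for p in preds) == sorted(table.subject_ids)

    def test_strong_effect_classified_well(self):
        rng = np.random.default_rng(6)
        table, y, cov = _toy_cohort(rng, shift=6.0)
        preds = loocv(table, y, cov, positive_class="PD", n_permutations=200, seed=1)
        perf = performance_metrics(preds, "PD")
        assert perf.accuracy >= 0.9

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(7)
        table, y, cov = _toy_cohort(rng)
        perm = rng.permutation(len(y))
        shuffled = FeatureTable(
            table.values[perm],
            table.feature_ids,
            [table.subject_ids[i] for i in perm],
        )
        a = loocv(table, y, cov, positive_class="PD", n_permutations=100, seed=2)
        b = loocv(shuffled, y[perm], cov.subset(perm), positive_class="PD",
                  n_permutations=100, seed=2)
        by_id_a = {p.subject_id: (p.predicted_label, p.score) for p in a}
        by_id_b = {p.subject_id: (p.predicted_label, p.score) for p in b}
        assert by_id_a == by_id_b

    def test_modes_give_one_prediction_each(self):
        rng = np.random.default_rng(8)
        table, y, cov = _toy_cohort(rng)
        for mode in ("nested", "paper_faithful"):
            preds = loocv(table, y, cov, positive_class="PD", mode=mode,
                          n_permutations=100, seed=3)
            assert len(preds) == len(y)

    def test_class_loss_in_fold_rejected(self):
        rng = np.random.default_rng(9)
        table, y, cov = _toy_cohort(rng, n_pos=2, n_neg=10)
        with pytest.raises(ValueError, match="class"):
            loocv(table, y, cov, positive_class="PD", n_permutations=50, seed=4)

    def test_unknown_mode_rejected(self):
        rng = np.random.default_rng(10)
        table, y, cov = _toy_cohort(rng)
        with pytest.raises(ValueError):
            loocv(table, y, cov, positive_class="PD", mode="oracle")


class TestPerformanceMetrics:
    def _preds(self, spec):
        out = []
        for k, (true, pred) in enumerate(spec):
            out.append(FoldPrediction(f"s{k}", true, pred, 0.0))
        return out

    def test_all_correct(self):
        preds = self._preds([("PD", "PD")] * 3 + [("NC", "NC")] * 4)
        perf = performance_metrics(preds, "PD")
        assert perf.sensitivity == 1.0
        assert perf.specificity == 1.0
        assert perf.accuracy == 1.0

    def test_degenerate_all_positive(self):
        preds = self._preds([("PD", "PD")] * 3 + [("NC", "PD")] * 4)
        perf = performance_metrics(preds, "PD")
        assert perf.sensitivity == 1.0
        assert perf.specificity == 0.0

    def test_hand_counted_confusion(self):
        preds = self._preds(
            [("PD", "PD")] * 3 + [("PD", "NC")] * 1
            + [("NC", "NC")] * 4 + [("NC", "PD")] * 2
        )
        perf = performance_metrics(preds, "PD")
        assert (perf.tp, perf.fn, perf.tn, perf.fp) == (3, 1, 4, 2)
        assert perf.sensitivity == pytest.approx(0.75)
        assert perf.specificity == pytest.approx(2 / 3)
        assert perf.accuracy == pytest.approx(0.7)

    def test_missing_positive_class_rejected(self):
        preds = self._preds([("NC", "NC")] * 4)
        with pytest.raises(ValueError):
            performance_metrics(preds, "PD")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            performance_metrics([], "PD")
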