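"""Maximum-uncertainty linear discriminant analysis (MLDA) with LOOCV.

Classical LDA needs the inverse of the pooled within-class covariance,
which is singular whenever features outnumber samples.  The
maximum-uncertainty regulariser replaces every eigenvalue of the pooled
covariance that falls below the mean eigenvalue with that mean, leaving the
larger eigenvalues untouched; the regularised matrix is positive-definite
by construction, so the discriminant direction w = (S*)^{-1} (mu1 - mu2)
always exists.  With equal priors the decision threshold is the projected
midpoint of the class means; tie scores go to the patient class.

The module follows the Model/Results convention: ``MaxUncertaintyLDA(X, y)``
holds the data, ``fit()`` returns an :class:`MLDAResults` carrying the
estimates, with ``predict`` and ``summary``.  ``loocv`` wraps the classifier
in leave-one-out cross-validation with per-fold (nested) or one-shot
(paper_faithful) covariate residualisation and permutation feature
selection; ``performance_metrics`` reduces the fold predictions to
sensitivity / specificity / accuracy with the patient group as positive.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .permselect import (
    CovariateTable,
    FeatureTable,
    fit_residualizer,
    permutation_test,
    residualize,
    select_features,
)

__all__ = [
    "MaxUncertaintyLDA",
    "MLDAResults",
    "FoldPrediction",
    "PerformanceSummary",
    "loocv",
    "performance_metrics",
]


@dataclass
class MLDAResults:
    """Fitted MLDA discriminant.

    ``class_labels`` is ordered (first, second); the score of a sample x is
    w.x - threshold, positive scores map to the first label, negative to the
    second, exact zeros to ``tie_label``.
    """

    class_labels: tuple[str, str]
    class_means: tuple[np.ndarray, np.ndarray]
    pooled_cov_regularized: np.ndarray
    discriminant: np.ndarray
    threshold: float
    tie_label: str
    n_obs: int = 0

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.discriminant.shape[0]:
            raise ValueError(
                f"expected {self.discriminant.shape[0]} features, got {x.shape[1]}"
            )
        return x @ self.discriminant - self.threshold

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and decision scores for new samples."""
        scores = self.decision_scores(x)
        first, second = self.class_labels
        labels = np.where(scores > 0, first, second).astype(object)
        labels[scores == 0] = self.tie_label
        return labels.astype(str), scores

    def summary(self) -> str:
        first, second = self.class_labels
        sep = float(
            self.discriminant @ (self.class_means[0] - self.class_means[1])
        )
        lines = [
            "Maximum-uncertainty LDA results",
            "=" * 38,
            f"classes:            {first} vs {second}",
            f"n features:         {self.discriminant.shape[0]}",
            f"n training samples: {self.n_obs}",
            f"threshold:          {self.threshold:.6g}",
            f"projected class separation: {sep:.6g}",
            f"tie label:          {self.tie_label}",
        ]
        return "\n".join(lines)


class MaxUncertaintyLDA:
    """Two-class linear discriminant with maximum-uncertainty covariance
    regularisation.

    Parameters
    ----------
    x : (S, F) array
        Feature matrix.
    y : sequence of str
        Class label per sample; exactly two distinct labels, each with at
        least two samples.
    class_order : optional pair
        Ordering of the labels; the discriminant points from the second
        towards the first.  Defaults to order of first appearance.
    tie_label : optional str
        Label assigned to exact zero scores; defaults to the first class
        (callers put the patient group first so ties favour sensitivity).
    """

    def __init__(self, x, y, class_order=None, tie_label=None):
        self.x = np.atleast_2d(np.asarray(x, dtype=float))
        self.y = np.asarray(y)
        labels = list(dict.fromkeys(self.y.tolist()))
        if class_order is not None:
            if set(class_order) != set(labels):
                raise ValueError("class_order must name the observed labels")
            labels = list(class_order)
        if len(labels) != 2:
            raise ValueError(f"exactly two classes required, got {labels}")
        if self.x.shape[1] == 0:
            raise ValueError("at least one feature required")
        for lab in labels:
            if (self.y == lab).sum() < 2:
                raise ValueError(f"class {lab!r} needs at least 2 samples")
        self.class_labels = (labels[0], labels[1])
        self.tie_label = tie_label if tie_label is not None else labels[0]

    def fit(self) -> MLDAResults:
        x, y = self.x, self.y
        first, second = self.class_labels
        x1, x2 = x[y == first], x[y == second]
        mu1, mu2 = x1.mean(0), x2.mean(0)
        sp = _pooled_covariance(x1, x2, mu1, mu2)
        sp_star = _max_uncertainty(sp)
        w = np.linalg.solve(sp_star, mu1 - mu2)
        threshold = float(w @ (mu1 + mu2) / 2.0)
        return MLDAResults(
            class_labels=self.class_labels,
            class_means=(mu1, mu2),
            pooled_cov_regularized=sp_star,
            discriminant=w,
            threshold=threshold,
            tie_label=self.tie_label,
            n_obs=x.shape[0],
        )


def _pooled_covariance(x1, x2, mu1, mu2) -> np.ndarray:
    n1, n2 = x1.shape[0], x2.shape[0]
    s1 = (x1 - mu1).T @ (x1 - mu1)
    s2 = (x2 - mu2).T @ (x2 - mu2)
    return (s1 + s2) / (n1 + n2 - 2)


def _max_uncertainty(sp: np.ndarray) -> np.ndarray:
    """Raise every below-mean eigenvalue of the pooled covariance to the
    mean eigenvalue; leaves larger eigenvalues untouched."""
    eigval, eigvec = np.linalg.eigh(sp)
    lam_bar = eigval.mean()
    eigval = np.maximum(eigval, lam_bar)
    out = (eigvec * eigval) @ eigvec.T
    return (out + out.T) / 2.0


@dataclass
class FoldPrediction:
    subject_id: str
    true_label: str
    predicted_label: str
    score: float


@dataclass
class PerformanceSummary:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    contrast: str = ""


def _fold_seed(base_seed: int, subject_id: str) -> int:
    """Stable per-fold seed tied to the held-out subject, so LOOCV results
    do not depend on subject ordering."""
    return zlib.crc32(f"{base_seed}:{subject_id}".encode()) % 2**31


def _selected_columns(result, alpha: float) -> np.ndarray:
    sel = select_features(result, alpha).selected
    if not sel.any():
        # degenerate fold: fall back to the single most discriminative feature
        sel = np.zeros_like(sel)
        sel[int(np.argmin(result.p_values))] = True
    return np.flatnonzero(sel)


def loocv(
    features: FeatureTable,
    labels,
    cov: CovariateTable,
    positive_class: str,
    mode: str = "nested",
    selection_alpha: float = 0.05,
    n_permutations: int = 1_000,
    seed: int = 0,
) -> list[FoldPrediction]:
    """Leave-one-out cross-validation of feature selection + MLDA.

    mode="nested" re-runs residualisation and permutation feature selection
    on each training fold and applies the fitted transforms to the held-out
    subject; mode="paper_faithful" performs both once on the full sample
    before the loop, reproducing a selection-before-validation protocol
    (optimistically biased; retained for comparability).
    """
    if mode not in ("nested", "paper_faithful"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(labels)
    s = y.shape[0]
    if s < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    if features.values.shape[0] != s or cov.age.shape[0] != s:
        raise ValueError("features, labels and covariates must align")
    neg = [l for l in dict.fromkeys(y.tolist()) if l != positive_class]
    if positive_class not in y or len(neg) != 1:
        raise ValueError("labels must contain the positive class and one other")
    negative_class = neg[0]

    # canonical subject order makes results invariant to input ordering
    order = np.argsort(np.asarray(features.subject_ids))
    vals = features.values[order]
    y = y[order]
    ids = [features.subject_ids[i] for i in order]
    cov = cov.subset(order)

    if mode == "paper_faithful":
        table = FeatureTable(vals, features.feature_ids, ids)
        resid = residualize(table, cov).values
        pos, negm = resid[y == positive_class], resid[y == negative_class]
        sel_seed = _fold_seed(seed, "__global__")
        result = permutation_test(pos, negm, n_permutations, seed=sel_seed)
        cols = _selected_columns(result, selection_alpha)

    preds: list[FoldPrediction] = []
    for i in range(s):
        train = np.ones(s, dtype=bool)
        train[i] = False
        y_tr = y[train]
        if len(set(y_tr.tolist())) < 2 or min(
            (y_tr == positive_class).sum(), (y_tr == negative_class).sum()
        ) < 2:
            raise ValueError("a training fold lost a class")
        if mode == "nested":
            table = FeatureTable(
                vals[train], features.feature_ids, [ids[j] for j in np.flatnonzero(train)]
            )
            cov_tr = cov.subset(train)
            apply_resid = fit_residualizer(table, cov_tr)
            x_tr = apply_resid(vals[train], cov_tr)
            x_te = apply_resid(vals[i : i + 1], cov.subset([i]))
            result = permutation_test(
                x_tr[y_tr == positive_class],
                x_tr[y_tr == negative_class],
                n_permutations,
                seed=_fold_seed(seed, ids[i]),
            )
            cols = _selected_columns(result, selection_alpha)
        else:
            x_tr, x_te = resid[train], resid[i : i + 1]
        model = MaxUncertaintyLDA(
            x_tr[:, cols],
            y_tr,
            class_order=(positive_class, negative_class),
            tie_label=positive_class,
        ).fit()
        pred, score = model.predict(x_te[:, cols])
        preds.append(FoldPrediction(ids[i], str(y[i]), str(pred[0]), float(score[0])))
    return preds


def performance_metrics(
    preds: list[FoldPrediction], positive_class: str, contrast: str = ""
) -> PerformanceSummary:
    """Confusion counts and rates with the patient group as positive class."""
    if not preds:
        raise ValueError("no predictions to summarise")
    labels = {p.true_label for p in preds} | {p.predicted_label for p in preds}
    if positive_class not in {p.true_label for p in preds}:
        raise ValueError(f"positive class {positive_class!r} absent from truths")
    if len(labels) > 2:
        raise ValueError(f"more than two labels present: {sorted(labels)}")
    tp = sum(p.true_label == positive_class == p.predicted_label for p in preds)
    fn = sum(
        p.true_label == positive_class != p.predicted_label for p in preds
    )
    tn = sum(
        p.true_label != positive_class and p.predicted_label != positive_class
        for p in preds
    )
    fp = sum(
        p.true_label != positive_class and p.predicted_label == positive_class
        for p in preds
    )
    total = tp + tn + fp + fn

    def _rate(num, den):
        return num / den if den else float("nan")

    return PerformanceSummary(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        accuracy=_rate(tp + tn, total),
        contrast=contrast,
    )
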