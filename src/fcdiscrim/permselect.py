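"""Feature selection: covariate residualisation and permutation t-tests.

Per-node network metrics enter a two-sample comparison only after the
linear effects of age and gender have been regressed out on the combined
sample.  For each feature the pooled-variance two-sample t statistic is
compared against a Monte-Carlo null built by randomly reassigning subjects
to two groups of the original sizes; the two-tailed p-value uses the
add-one convention p = (1 + #{|t*| >= |t_obs|}) / (1 + P), so p is never
exactly zero and its minimum is 1/(P+1).  Features with p below the
(uncorrected) significance level are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FeatureTable",
    "CovariateTable",
    "SelectionResult",
    "residualize",
    "permutation_test",
    "select_features",
]


@dataclass
class FeatureTable:
    """Subjects x features matrix with aligned identifiers."""

    values: np.ndarray
    feature_ids: list[tuple]  # (node index, metric name)
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("feature table contains non-finite values")
        s, f = self.values.shape
        if len(self.subject_ids) != s or len(self.feature_ids) != f:
            raise ValueError("identifier lengths must match the value matrix")


@dataclass
class CovariateTable:
    """Per-subject nuisance covariates for residualisation."""

    age: np.ndarray
    gender: np.ndarray  # coded 0/1

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=float)
        if self.age.shape != self.gender.shape:
            raise ValueError("age and gender must have equal length")

    def subset(self, idx) -> "CovariateTable":
        return CovariateTable(self.age[idx], self.gender[idx])


@dataclass
class SelectionResult:
    """Permutation p-values, observed t statistics and the selected mask."""

    p_values: np.ndarray
    t_observed: np.ndarray
    selected: np.ndarray
    alpha: float
    n_permutations: int
    seed: int


def _design(cov: CovariateTable) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones_like(cov.age)], ["intercept"]
    for name, v in (("age", cov.age), ("gender", cov.gender)):
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=3)
            continue
        cols.append(v)
        names.append(name)
    return np.column_stack(cols), names


def residualize(features: FeatureTable, cov: CovariateTable) -> FeatureTable:
    """Replace each feature by its residual from least squares on
    [intercept, age, gender] fitted over the whole sample."""
    s = features.values.shape[0]
    if cov.age.shape[0] != s:
        raise ValueError("covariate length must match the feature table")
    if s < 4:
        raise ValueError("residualisation needs at least 4 subjects")
    x, _ = _design(cov)
    beta, *_ = np.linalg.lstsq(x, features.values, rcond=None)
    return FeatureTable(
        features.values - x @ beta, features.feature_ids, features.subject_ids
    )


def fit_residualizer(features: FeatureTable, cov: CovariateTable):
    """Fit the covariate model on one sample and return a function that
    residualises new (subject x feature) rows with the same coefficients —
    used to apply a training-fold fit to a held-out subject."""
    s = features.values.shape[0]
    if s < 4:
        raise ValueError("residualisation needs at least 4 subjects")
    x, names = _design(cov)
    beta, *_ = np.linalg.lstsq(x, features.values, rcond=None)

    def apply(values: np.ndarray, new_cov: CovariateTable) -> np.ndarray:
        cols = [np.ones_like(new_cov.age)]
        if "age" in names:
            cols.append(new_cov.age)
        if "gender" in names:
            cols.append(new_cov.gender)
        return np.atleast_2d(values) - np.column_stack(cols) @ beta

    return apply


def _pooled_t(
    sum_a, sumsq_a, n_a, sum_all, sumsq_all, n_all
) -> np.ndarray:
    """Two-sample pooled-variance t from group-A and total sufficient stats."""
    n_b = n_all - n_a
    sum_b = sum_all - sum_a
    sumsq_b = sumsq_all - sumsq_a
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    ss_a = sumsq_a - n_a * mean_a**2
    ss_b = sumsq_b - n_b * mean_b**2
    sp2 = (ss_a + ss_b) / (n_all - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return np.where(np.isfinite(t), t, 0.0)


def permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
    chunk: int = 512,
) -> SelectionResult:
    """Per-feature two-sample permutation t-test.

    The null reassigns subjects at random to two groups of the original
    sizes (Monte-Carlo, with replacement from the assignment space) and
    recomputes the pooled-variance t each time.  Two-tailed add-one
    p-values; bitwise-deterministic under ``seed``.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 subjects")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the feature dimension")
    x = np.vstack([a, b])
    n_all = n_a + n_b
    sum_all, sumsq_all = x.sum(0), (x**2).sum(0)
    t_obs = _pooled_t(a.sum(0), (a**2).sum(0), n_a, sum_all, sumsq_all, n_all)

    # canonical row order + drawing subsets of the smaller group's size make
    # the Monte-Carlo null invariant to subject ordering and label exchange
    # (|t| of a split does not depend on which side is called "group A")
    x_canon = x[np.lexsort(x.T)]
    n_small = min(n_a, n_b)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[1], dtype=np.int64)
    x_sq = x_canon**2
    done = 0
    while done < n_permutations:
        c = min(chunk, n_permutations - done)
        order = np.argsort(rng.random((c, n_all)), axis=1)
        membership = np.zeros((c, n_all))
        np.put_along_axis(membership, order[:, :n_small], 1.0, axis=1)
        sum_a = membership @ x_canon
        sumsq_a = membership @ x_sq
        t_null = _pooled_t(sum_a, sumsq_a, n_small, sum_all, sumsq_all, n_all)
        exceed += (np.abs(t_null) >= np.abs(t_obs)[None, :]).sum(0)
        done += c
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return SelectionResult(
        p_values=p,
        t_observed=t_obs,
        selected=np.zeros(x.shape[1], dtype=bool),
        alpha=np.nan,
        n_permutations=n_permutations,
        seed=seed,
    )


def select_features(result: SelectionResult, alpha: float = 0.05) -> SelectionResult:
    """Mark features with uncorrected permutation p below ``alpha``."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    # alpha = 1 selects everything even though add-one p-values can equal 1
    selected = result.p_values < alpha if alpha < 1.0 else np.ones_like(result.p_values, bool)
    return replace(result, selected=selected, alpha=alpha)
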