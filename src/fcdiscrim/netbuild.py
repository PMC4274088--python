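"""Weighted functional-network construction from preprocessed ROI signals.

Edges are pairwise Pearson correlations between ROI time series, kept only
when significant after Bonferroni correction over the N(N-1)/2 unordered
pairs and (by default) positive; surviving correlations are carried as
Fisher r-to-z weights.  Isolated nodes are retained so the node set is
identical across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tsprep import TimeSeriesMatrix

__all__ = [
    "CorrelationResult",
    "FCNetwork",
    "pearson_matrix",
    "fisher_r_to_z",
    "bonferroni_threshold",
]


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-test p-values."""

    r: np.ndarray
    p: np.ndarray
    n_samples: int


@dataclass
class FCNetwork:
    """Symmetric nonnegative weighted adjacency; weight 0 means no edge."""

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    cerebellum_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        n = w.shape[0]
        if not self.node_labels:
            self.node_labels = [f"ROI_{i + 1:04d}" for i in range(n)]
        if len(self.node_labels) != n:
            raise ValueError("one label per node required")
        if self.cerebellum_mask is None:
            self.cerebellum_mask = np.zeros(n, dtype=bool)
        else:
            self.cerebellum_mask = np.asarray(self.cerebellum_mask, dtype=bool)
            if self.cerebellum_mask.shape != (n,):
                raise ValueError("cerebellum mask length must equal node count")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def subnetwork(self, keep: np.ndarray) -> "FCNetwork":
        """Induced subnetwork on the boolean node mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        return FCNetwork(
            self.weights[np.ix_(keep, keep)],
            [l for l, k in zip(self.node_labels, keep) if k],
            self.cerebellum_mask[keep],
        )


def pearson_matrix(ts: TimeSeriesMatrix) -> CorrelationResult:
    """All-pairs Pearson correlation with exact t-distribution p-values
    (df = T - 2, two-sided).  Diagonal p is 0 by convention."""
    x = ts.values
    t, n = x.shape
    spread = np.ptp(x, axis=0)
    if (spread == 0).any():
        bad = [f"ROI {i}" for i in np.flatnonzero(spread == 0)]
        raise ValueError(f"zero-variance columns: {', '.join(bad)}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    df = t - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p[np.isnan(p)] = 0.0  # |r| == 1
    np.fill_diagonal(p, 0.0)
    return CorrelationResult(r, p, t)


def fisher_r_to_z(r):
    """Fisher's variance-stabilising transform z = arctanh(r) = (1/2) ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def bonferroni_threshold(
    corr: CorrelationResult,
    alpha: float = 0.05,
    positive_only: bool = True,
    node_labels: list[str] | None = None,
    cerebellum_mask: np.ndarray | None = None,
) -> FCNetwork:
    """Keep edge (i, j) iff p < alpha / m with m = N(N-1)/2 unordered pairs
    (and r > 0 when ``positive_only``); surviving edges weighted by
    Fisher z of their correlation."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    n = corr.r.shape[0]
    m = n * (n - 1) // 2
    keep = corr.p < alpha / m
    if positive_only:
        keep &= corr.r > 0
    np.fill_diagonal(keep, False)
    keep &= keep.T  # p and r are symmetric; guard against asymmetry anyway
    weights = np.zeros_like(corr.r)
    weights[keep] = np.arctanh(np.clip(corr.r[keep], -1 + 1e-15, 1 - 1e-15))
    if positive_only is False:
        weights = np.abs(weights)  # network weights must be nonnegative
    return FCNetwork(weights, node_labels or [], cerebellum_mask)
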