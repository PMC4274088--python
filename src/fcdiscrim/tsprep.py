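"""Temporal preprocessing of ROI time series.

The chain applied before network construction is: drop initial volumes
(scanner stabilisation), linear detrend, ideal band-pass filter (default
0.01-0.1 Hz), and nuisance regression against the 24-parameter motion
expansion plus mean WM and CSF signals.  The global signal is deliberately
not regressed.  Every operation acts column-wise and independently, so
ROI ordering never matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "NuisanceMatrix",
    "drop_initial_volumes",
    "detrend_linear",
    "bandpass_filter",
    "expand_motion_24",
    "regress_nuisance",
    "preprocess",
]


@dataclass
class TimeSeriesMatrix:
    """T x N matrix of ROI signals sampled every ``tr`` seconds."""

    values: np.ndarray
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 3:
            raise ValueError("time series must have at least 3 time points")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


#: column roles emitted by :func:`expand_motion_24`
MOTION24_ROLES = (
    ["motion"] * 6 + ["motion_lag"] * 6 + ["motion_sq"] * 6 + ["motion_lag_sq"] * 6
)


@dataclass
class NuisanceMatrix:
    """T x P confound matrix with a role tag per column."""

    values: np.ndarray
    column_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.column_roles:
            self.column_roles = ["confound"] * self.values.shape[1]
        if len(self.column_roles) != self.values.shape[1]:
            raise ValueError("one role per nuisance column required")


def drop_initial_volumes(ts: TimeSeriesMatrix, k: int) -> TimeSeriesMatrix:
    """Discard the first ``k`` volumes (e.g. 5 of 180 for scanner settling)."""
    if not 0 <= k < ts.n_volumes:
        raise ValueError(f"cannot drop {k} of {ts.n_volumes} volumes")
    return TimeSeriesMatrix(ts.values[k:].copy(), ts.tr)


def detrend_linear(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Remove the least-squares line (intercept + slope) from every column."""
    t = np.arange(ts.n_volumes, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return TimeSeriesMatrix(ts.values - design @ beta, ts.tr)


def bandpass_filter(
    ts: TimeSeriesMatrix, low_hz: float = 0.01, high_hz: float = 0.1
) -> TimeSeriesMatrix:
    """Ideal discrete-Fourier band-pass: retain coefficients with frequency
    in [``low_hz``, ``high_hz``], zero all others (including DC when
    ``low_hz`` > 0)."""
    nyquist = 0.5 / ts.tr
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyquist}")
    freqs = np.fft.rfftfreq(ts.n_volumes, d=ts.tr)
    spectrum = np.fft.rfft(ts.values, axis=0)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum[~keep] = 0.0
    return TimeSeriesMatrix(
        np.fft.irfft(spectrum, n=ts.n_volumes, axis=0), ts.tr
    )


def expand_motion_24(motion6: np.ndarray) -> NuisanceMatrix:
    """Friston 24-parameter expansion of six rigid-body motion series:
    the parameters, their one-volume lags (first row zero), and the squares
    of both sets."""
    motion6 = np.atleast_2d(np.asarray(motion6, dtype=float))
    if motion6.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got {motion6.shape[1]}")
    lag = np.vstack([np.zeros((1, 6)), motion6[:-1]])
    out = np.hstack([motion6, lag, motion6**2, lag**2])
    return NuisanceMatrix(out, list(MOTION24_ROLES))


def regress_nuisance(ts: TimeSeriesMatrix, nuis: NuisanceMatrix) -> TimeSeriesMatrix:
    """Project each ROI column onto the orthogonal complement of the nuisance
    design (intercept always included); returns the residuals."""
    x = nuis.values
    if x.shape[0] != ts.n_volumes:
        raise ValueError("nuisance row count must match the time series")
    design = np.column_stack([np.ones(ts.n_volumes), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        dep = _dependent_columns(design, nuis.column_roles)
        raise ValueError(f"rank-deficient nuisance design; dependent columns: {dep}")
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return TimeSeriesMatrix(ts.values - design @ beta, ts.tr)


def _dependent_columns(design: np.ndarray, roles: list[str]) -> list[str]:
    """Name nuisance columns implicated in a rank deficiency (QR pivot test)."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = [int(p) for p, d in zip(piv, diag) if d < tol]
    names = ["intercept"] + [f"{role}[{i}]" for i, role in enumerate(roles)]
    return [names[b] for b in sorted(bad)]


def preprocess(
    ts: TimeSeriesMatrix,
    motion6: np.ndarray | None = None,
    wm_csf: np.ndarray | None = None,
    drop: int = 5,
    band: tuple[float, float] = (0.01, 0.1),
) -> TimeSeriesMatrix:
    """Full temporal chain: drop -> detrend -> band-pass -> nuisance regression.

    ``motion6`` and ``wm_csf`` are given at the original (pre-drop) length;
    the same initial rows are discarded before building the design.  The
    assembled nuisance regressors are detrended and band-pass filtered
    exactly like the data before the regression: regressing band-limited
    signals on broadband confounds leaves residual in-band contamination
    (the frequency-mismatch problem), so the design must live in the same
    frequency band as the signal it cleans.
    """
    out = drop_initial_volumes(ts, drop)
    out = detrend_linear(out)
    out = bandpass_filter(out, *band)
    columns, roles = [], []
    if motion6 is not None:
        m = expand_motion_24(np.asarray(motion6)[drop:])
        columns.append(m.values)
        roles.extend(m.column_roles)
    if wm_csf is not None:
        w = np.atleast_2d(np.asarray(wm_csf, dtype=float))[drop:]
        columns.append(w)
        roles.extend(["wm", "csf"][: w.shape[1]])
    if columns:
        design = TimeSeriesMatrix(np.hstack(columns), ts.tr)
        design = bandpass_filter(detrend_linear(design), *band)
        out = regress_nuisance(out, NuisanceMatrix(design.values, roles))
    return out
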