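"""Synthetic cohorts with the statistical structure the network analysis assumes.

The study design being emulated is a three-group resting-state fMRI cohort:
normal controls (NC), tremor-dominant patients (TPD) and non-tremor-dominant
patients (NTPD), each subject contributing a T x N matrix of ROI time series.
Group structure is injected at the level of the generative correlation matrix:
ROIs are organised into modules with correlation ``r_within`` inside a module
and ``r_between`` across modules, and in the patient groups the within-module
correlations incident to a known set of "affected" nodes are reduced by
``effect_delta``.  Because the affected set is known, downstream feature
selection and classification are falsifiable: a pipeline that works must
recover those nodes and separate the groups.

Confound structure mimics what temporal preprocessing is meant to remove:
six AR(1) head-motion series plus white-matter and CSF signals, a mixture of
which is added to every ROI with gain ``nuisance_loading``.

The module also builds synthetic random parcellations (contiguous random
ROIs grown inside a label volume), standing in for randomly subdivided
anatomical atlases with and without the cerebellum.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

GROUPS = ("NC", "TPD", "NTPD")
PATIENT_GROUPS = ("TPD", "NTPD")

__all__ = [
    "GROUPS",
    "PATIENT_GROUPS",
    "CohortConfigError",
    "SubjectRecord",
    "CohortConfig",
    "SimulatedSubject",
    "ParcelVolume",
    "make_cohort",
    "module_assignment",
    "build_group_correlation",
    "simulate_subject",
    "simulate_cohort",
    "generate_parcellation",
    "two_hemisphere_mask",
]


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class SubjectRecord:
    """Metadata for one simulated subject."""

    subject_id: str
    group: str
    age: float
    gender: str  # "M" or "F"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortConfigError(f"unknown group {self.group!r}")
        if not self.age > 0:
            raise CohortConfigError("age must be positive")
        if self.gender not in ("M", "F"):
            raise CohortConfigError(f"unknown gender {self.gender!r}")


@dataclass
class CohortConfig:
    """Generative parameters for a synthetic cohort.

    Defaults mirror the emulated study design: 20 NC / 15 TPD / 10 NTPD
    subjects, 180 volumes at TR = 2 s, and a desk-scale parcellation of
    128 ROIs (set ``n_rois=1024`` to mirror the full-resolution template).
    The group effect is a 0.25 correlation decrement on ten known nodes.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NC": 20, "TPD": 15, "NTPD": 10}
    )
    n_rois: int = 128
    n_modules: int = 8
    n_volumes: int = 180
    tr: float = 2.0
    r_within: float = 0.6
    r_between: float = 0.1
    affected_nodes: tuple[int, ...] = tuple(range(10))
    effect_delta: float | Mapping[str, float] = 0.25
    cerebellum_nodes: tuple[int, ...] = tuple(range(96, 128))
    nuisance_loading: float = 0.5
    age_range: tuple[float, float] = (40.0, 80.0)
    male_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        self.affected_nodes = tuple(int(i) for i in self.affected_nodes)
        self.cerebellum_nodes = tuple(int(i) for i in self.cerebellum_nodes)
        self.validate()

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise CohortConfigError(f"unknown group {g!r} in n_per_group")
            if n < 0:
                raise CohortConfigError(f"negative count for group {g!r}")
        if self.n_rois < 1 or self.n_modules < 1 or self.n_modules > self.n_rois:
            raise CohortConfigError("need 1 <= n_modules <= n_rois")
        if not (0.0 < self.r_within < 1.0):
            raise CohortConfigError("r_within must lie in (0, 1)")
        if not (0.0 <= self.r_between < self.r_within):
            raise CohortConfigError("need 0 <= r_between < r_within")
        for d in self._deltas().values():
            if not (0.0 <= d < self.r_within):
                raise CohortConfigError("effect_delta must lie in [0, r_within)")
        for name in ("affected_nodes", "cerebellum_nodes"):
            idx = getattr(self, name)
            if any(i < 0 or i >= self.n_rois for i in idx):
                raise CohortConfigError(f"{name} outside 0..n_rois-1")
        if self.nuisance_loading < 0:
            raise CohortConfigError("nuisance_loading must be nonnegative")
        if self.n_volumes < 3:
            raise CohortConfigError("n_volumes must be at least 3")

    def _deltas(self) -> dict[str, float]:
        """Correlation decrement per patient group."""
        if isinstance(self.effect_delta, Mapping):
            return {g: float(self.effect_delta.get(g, 0.0)) for g in PATIENT_GROUPS}
        return {g: float(self.effect_delta) for g in PATIENT_GROUPS}

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulatedSubject:
    """One subject's simulated ROI time series plus confounds and metadata."""

    record: SubjectRecord
    timeseries: np.ndarray  # T x N
    nuisance: np.ndarray  # T x 8: six motion series, WM, CSF
    true_affected: tuple[int, ...]


@dataclass
class ParcelVolume:
    """Integer label volume whose labels 1..K partition a mask into parcels."""

    labels: np.ndarray
    n_parcels: int


def make_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw subject metadata: group sizes from the config, ages uniform on
    ``age_range``, genders Bernoulli(``male_fraction``).  Deterministic under
    ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    records: list[SubjectRecord] = []
    k = 0
    for group in GROUPS:
        for _ in range(int(config.n_per_group.get(group, 0))):
            k += 1
            age = float(rng.uniform(*config.age_range))
            gender = "M" if rng.random() < config.male_fraction else "F"
            records.append(SubjectRecord(f"sub-{k:03d}", group, age, gender))
    return records


def module_assignment(config: CohortConfig) -> np.ndarray:
    """Module index of each ROI (contiguous, near-equal blocks)."""
    return (np.arange(config.n_rois) * config.n_modules // config.n_rois).astype(int)


def build_group_correlation(
    config: CohortConfig, group: str, ensure_pd: bool = True
) -> np.ndarray:
    """Generative ROI correlation matrix for one group.

    Block structure: ``r_within`` inside modules, ``r_between`` across.  For
    patient groups, within-module entries incident to an affected node are
    reduced by that group's effect delta.  With ``ensure_pd`` the matrix is
    projected to the nearest positive-definite matrix by eigenvalue clipping
    (floor 1e-6) and rescaled back to unit diagonal.
    """
    if group not in GROUPS:
        raise CohortConfigError(f"unknown group {group!r}")
    n = config.n_rois
    mod = module_assignment(config)
    same_module = mod[:, None] == mod[None, :]
    r = np.where(same_module, config.r_within, config.r_between).astype(float)
    if group in PATIENT_GROUPS:
        delta = config._deltas()[group]
        if delta:
            affected = np.zeros(n, bool)
            affected[list(config.affected_nodes)] = True
            hit = same_module & (affected[:, None] | affected[None, :])
            r[hit] -= delta
    np.fill_diagonal(r, 1.0)
    if not ensure_pd:
        return r
    w, v = np.linalg.eigh(r)
    w = np.maximum(w, 1e-6)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    if np.linalg.eigvalsh(r).min() <= 0:
        raise CohortConfigError("group correlation not positive-definite after clipping")
    return r


def _ar1(rng: np.random.Generator, t: int, phi: float = 0.9) -> np.ndarray:
    x = np.empty(t)
    x[0] = rng.standard_normal() / np.sqrt(1 - phi**2)
    for i in range(1, t):
        x[i] = phi * x[i - 1] + rng.standard_normal()
    return x


def simulate_subject(
    record: SubjectRecord, config: CohortConfig, seed: int
) -> SimulatedSubject:
    """Simulate one subject's T x N BOLD-like time-series matrix.

    Rows are i.i.d. multivariate normal with the group's correlation matrix
    (drawn through its Cholesky factor); six AR(1) motion series plus AR(1)
    WM and CSF signals form the nuisance matrix, and ``nuisance_loading``
    times a shared standardized confound mixture is added to every ROI.
    """
    config.validate()
    t, n = config.n_volumes, config.n_rois
    if t < 3:
        raise CohortConfigError("need at least 3 volumes")
    rng = np.random.default_rng(seed)
    corr = build_group_correlation(config, record.group)
    chol = np.linalg.cholesky(corr)
    ts = rng.standard_normal((t, n)) @ chol.T
    nuis = np.column_stack([_ar1(rng, t) for _ in range(8)])  # 6 motion + WM + CSF
    if config.nuisance_loading > 0:
        z = (nuis - nuis.mean(0)) / nuis.std(0)
        mixture = z.sum(1) / np.sqrt(z.shape[1])
        ts = ts + config.nuisance_loading * mixture[:, None]
    return SimulatedSubject(record, ts, nuis, tuple(config.affected_nodes))


def simulate_cohort(config: CohortConfig) -> list[SimulatedSubject]:
    """Simulate every subject in the cohort; bitwise-reproducible under
    ``config.seed`` (per-subject streams are spawned from one seed sequence)."""
    records = make_cohort(config)
    seeds = np.random.SeedSequence([config.seed, 1]).generate_state(max(len(records), 1))
    return [
        simulate_subject(rec, config, int(s) % 2**31)
        for rec, s in zip(records, seeds)
    ]


_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def generate_parcellation(
    label_volume: np.ndarray, k: int, seed: int
) -> ParcelVolume:
    """Split a label volume into ``k`` contiguous random parcels.

    Each input region (distinct positive label) receives a share of parcels
    proportional to its voxel count and is partitioned by balanced
    multi-source region growing under 6-connectivity: random seed voxels,
    then the currently smallest parcel claims a random frontier voxel until
    the region is exhausted.  Deterministic under ``seed``.
    """
    labels = np.asarray(label_volume)
    if labels.ndim != 3:
        raise CohortConfigError("label volume must be 3-D")
    region_ids = [int(r) for r in np.unique(labels) if r > 0]
    n_voxels = int((labels > 0).sum())
    if k < 1 or k > n_voxels:
        raise CohortConfigError("k must lie in 1..number of nonzero voxels")
    if k < len(region_ids):
        raise CohortConfigError("k smaller than the number of input regions")
    rng = np.random.default_rng(seed)

    sizes = np.array([(labels == r).sum() for r in region_ids], float)
    quota = np.maximum(1, np.floor(k * sizes / sizes.sum()).astype(int))
    quota = np.minimum(quota, sizes.astype(int))
    # largest-remainder top-up / trim to hit exactly k parcels
    while quota.sum() < k:
        frac = k * sizes / sizes.sum() - quota
        frac[quota >= sizes] = -np.inf
        quota[int(np.argmax(frac))] += 1
    while quota.sum() > k:
        frac = k * sizes / sizes.sum() - quota
        frac[quota <= 1] = np.inf
        quota[int(np.argmin(frac))] -= 1

    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for region, k_r in zip(region_ids, quota):
        coords = np.argwhere(labels == region)
        index = {tuple(c): i for i, c in enumerate(coords)}
        assigned = np.zeros(len(coords), dtype=np.int64)
        seed_rows = rng.choice(len(coords), size=int(k_r), replace=False)
        frontiers: list[list[int]] = [[int(r)] for r in seed_rows]
        counts = np.zeros(int(k_r), int)
        active = set(range(int(k_r)))
        while active:
            p = min(active, key=lambda j: (counts[j], j))
            frontier = frontiers[p]
            claimed = False
            while frontier:
                j = frontier.pop(rng.integers(len(frontier)))
                if assigned[j]:
                    continue
                assigned[j] = p + 1
                counts[p] += 1
                claimed = True
                for off in _NEIGHBOR_OFFSETS:
                    nb = index.get(tuple(coords[j] + off))
                    if nb is not None and not assigned[nb]:
                        frontier.append(nb)
                break
            if not claimed and not frontier:
                active.discard(p)
        if (assigned == 0).any():
            raise CohortConfigError(
                f"region {region} is not 6-connected: region growing left "
                f"{int((assigned == 0).sum())} voxels unreachable"
            )
        for i, c in enumerate(coords):
            out[tuple(c)] = next_label + assigned[i] - 1
        next_label += int(k_r)
    return ParcelVolume(out, k)


def two_hemisphere_mask(shape: tuple[int, int, int] = (32, 38, 32)) -> np.ndarray:
    """Synthetic brain-like mask: two ellipsoids ("hemispheres") labelled 1
    and 2, separated by a one-voxel sagittal gap.  A stand-in for an
    anatomical template when none is supplied."""
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    out = np.zeros(shape, dtype=np.int16)
    half = nx // 2
    for label, cx in ((1, half // 2), (2, half + half // 2 + 1)):
        e = (
            ((x - cx) / (half * 0.42)) ** 2
            + ((y - ny / 2) / (ny * 0.42)) ** 2
            + ((z - nz / 2) / (nz * 0.42)) ** 2
        )
        out[(e <= 1.0) & (out == 0)] = label
    out[half, :, :] = 0  # enforce the inter-hemispheric gap
    return out
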