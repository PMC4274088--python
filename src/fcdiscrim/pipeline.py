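"""End-to-end experiment orchestration.

One configuration drives the whole chain: simulate a three-group cohort,
temporally preprocess every subject, build Bonferroni-thresholded weighted
networks under one or two template arms (with the designated cerebellar
node subset included or excluded), compute per-node and small-world
metrics, select discriminative nodes by permutation testing, and classify
every pairwise group contrast with MLDA under leave-one-out
cross-validation.  All stage seeds derive from a single master seed, so a
rerun with the same configuration reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .cohortsim import CohortConfig, SimulatedSubject, simulate_cohort
from .graphmetrics import compute_nodal_metrics, small_world_metrics
from .mlda import FoldPrediction, PerformanceSummary, loocv, performance_metrics
from .netbuild import bonferroni_threshold, pearson_matrix
from .permselect import CovariateTable, FeatureTable
from .tsprep import TimeSeriesMatrix, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "PrepConfig",
    "NetConfig",
    "MetricsConfig",
    "SelectionConfig",
    "ClassifyConfig",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "summarize_smallworld",
    "CONTRASTS",
]

#: contrast name -> (positive groups, positive label, negative groups)
CONTRASTS = {
    "mixed-vs-nc": (("TPD", "NTPD"), "PD", ("NC",)),
    "tpd-vs-nc": (("TPD",), "TPD", ("NC",)),
    "ntpd-vs-nc": (("NTPD",), "NTPD", ("NC",)),
    "tpd-vs-ntpd": (("TPD",), "TPD", ("NTPD",)),
}

TEMPLATES = ("with_cerebellum", "without_cerebellum")

METRIC_NAMES = ("e_local", "e_nodal", "c_node", "l_node")


@dataclass
class PrepConfig:
    drop: int = 5
    band_low: float = 0.01
    band_high: float = 0.1


@dataclass
class NetConfig:
    alpha: float = 0.05
    positive_only: bool = True


@dataclass
class MetricsConfig:
    n_nulls: int = 100
    compute_smallworld: bool = True


@dataclass
class SelectionConfig:
    n_perm: int = 1_000
    alpha: float = 0.05
    metrics: tuple[str, ...] = ("e_local", "e_nodal")


@dataclass
class ClassifyConfig:
    contrasts: tuple[str, ...] = tuple(CONTRASTS)
    mode: str = "nested"


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    net: NetConfig = field(default_factory=NetConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    templates: tuple[str, ...] = TEMPLATES
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.templates or any(t not in TEMPLATES for t in self.templates):
            raise ValueError(f"templates must be a nonempty subset of {TEMPLATES}")
        if not self.classify.contrasts or any(
            c not in CONTRASTS for c in self.classify.contrasts
        ):
            raise ValueError(f"contrasts must be a nonempty subset of {tuple(CONTRASTS)}")
        if any(m not in METRIC_NAMES for m in self.selection.metrics):
            raise ValueError(f"selection metrics must come from {METRIC_NAMES}")

    def to_yaml(self, path=None) -> str:
        doc = dataclasses.asdict(self)
        doc["cohort"]["n_per_group"] = dict(doc["cohort"]["n_per_group"])
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        doc = yaml.safe_load(text) or {}
        kw = {}
        for name, sub in (
            ("cohort", CohortConfig),
            ("prep", PrepConfig),
            ("net", NetConfig),
            ("metrics", MetricsConfig),
            ("selection", SelectionConfig),
            ("classify", ClassifyConfig),
        ):
            if name in doc:
                d = dict(doc[name])
                for k, v in d.items():
                    if isinstance(v, list):
                        d[k] = tuple(v)
                kw[name] = sub(**d)
        if "templates" in doc:
            kw["templates"] = tuple(doc["templates"])
        if "seed" in doc:
            kw["seed"] = int(doc["seed"])
        return cls(**kw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Structured output of one experiment run."""

    performance: dict  # (template, contrast, metric) key -> PerformanceSummary
    predictions: dict  # same key -> list[FoldPrediction]
    selected_nodes: dict  # same key -> list of node labels selected on full sample
    smallworld: pd.DataFrame | None
    features: dict  # template -> {metric -> FeatureTable}
    records: list
    provenance: dict

    def performance_frame(self) -> pd.DataFrame:
        rows = []
        for key, perf in self.performance.items():
            template, contrast, metric = key.split("|")
            rows.append(
                {
                    "template": template,
                    "contrast": contrast,
                    "metric": metric,
                    "sensitivity": perf.sensitivity,
                    "specificity": perf.specificity,
                    "accuracy": perf.accuracy,
                    "tp": perf.tp,
                    "tn": perf.tn,
                    "fp": perf.fp,
                    "fn": perf.fn,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        doc = {
            "provenance": self.provenance,
            "performance": {
                k: dataclasses.asdict(v) for k, v in self.performance.items()
            },
            "selected_nodes": self.selected_nodes,
            "predictions": {
                k: [dataclasses.asdict(p) for p in v]
                for k, v in self.predictions.items()
            },
        }
        if self.smallworld is not None:
            doc["smallworld"] = self.smallworld.round(12).to_dict(orient="list")
        return json.dumps(doc, indent=1, sort_keys=True)


def _stage_seeds(master: int) -> dict[str, int]:
    state = np.random.SeedSequence([int(master), 2026]).generate_state(4)
    names = ("cohort", "metrics", "selection", "classify")
    return {n: int(s) % 2**31 for n, s in zip(names, state)}


def _preprocess_subject(sub: SimulatedSubject, tr: float, prep: PrepConfig) -> TimeSeriesMatrix:
    ts = TimeSeriesMatrix(sub.timeseries, tr)
    return preprocess(
        ts,
        motion6=sub.nuisance[:, :6],
        wm_csf=sub.nuisance[:, 6:8],
        drop=prep.drop,
        band=(prep.band_low, prep.band_high),
    )


def _metric_vector(nm, name: str) -> np.ndarray:
    return {
        "e_local": nm.e_local,
        "e_nodal": nm.e_nodal,
        "c_node": nm.c_node,
        "l_node": nm.l_node,
    }[name]


def cohort_features(
    config: CohortConfig,
    metrics: tuple[str, ...] = ("e_local", "e_nodal"),
    template: str = "with_cerebellum",
    prep: PrepConfig | None = None,
    net: NetConfig | None = None,
):
    """Simulate one cohort and compute its per-node network feature table.

    Returns ``(table, groups, cov)``: a :class:`FeatureTable` whose columns
    concatenate the requested per-node metrics, the group label per subject,
    and the age/gender covariates.  This is the standard entry point for
    desk-scale selection/classification studies that do not need the full
    report machinery of :func:`run_experiment`.
    """
    prep = prep or PrepConfig()
    net = net or NetConfig()
    subjects = simulate_cohort(config)
    cere = np.zeros(config.n_rois, dtype=bool)
    cere[list(config.cerebellum_nodes)] = True
    keep = ~cere if template == "without_cerebellum" else np.ones_like(cere)
    labels = [l for l, k in zip(fio.roi_labels(config.n_rois), keep) if k]
    rows = []
    for sub in subjects:
        ts = _preprocess_subject(sub, config.tr, prep)
        corr = pearson_matrix(TimeSeriesMatrix(ts.values[:, keep], ts.tr))
        fc = bonferroni_threshold(
            corr, alpha=net.alpha, positive_only=net.positive_only,
            node_labels=labels, cerebellum_mask=cere[keep],
        )
        nm = compute_nodal_metrics(fc)
        rows.append(np.concatenate([_metric_vector(nm, m) for m in metrics]))
    records = [s.record for s in subjects]
    n_keep = int(keep.sum())
    table = FeatureTable(
        np.vstack(rows),
        [(i, m) for m in metrics for i in range(n_keep)],
        [r.subject_id for r in records],
    )
    groups = np.array([r.group for r in records])
    cov = CovariateTable(
        np.array([r.age for r in records]),
        np.array([1.0 if r.gender == "M" else 0.0 for r in records]),
    )
    return table, groups, cov


def run_experiment(config: ExperimentConfig, outdir=None) -> ExperimentReport:
    """Execute every stage of the experiment; see the module docstring.

    When ``outdir`` is given, all intermediates (metadata, per-subject time
    series, networks, metric tables) plus the JSON report and a
    Table-2-style performance CSV are written beneath it.
    """
    seeds = _stage_seeds(config.seed)
    cohort_cfg = config.cohort.replace(seed=seeds["cohort"])
    logger.info("stage simulate: %d subjects, %d ROIs",
                sum(cohort_cfg.n_per_group.values()), cohort_cfg.n_rois)
    subjects = simulate_cohort(cohort_cfg)
    records = [s.record for s in subjects]

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        fio.write_metadata(records, out / "metadata.csv")
        (out / "config.yaml").write_text(config.to_yaml())

    logger.info("stage prep: drop=%d band=[%g, %g] Hz",
                config.prep.drop, config.prep.band_low, config.prep.band_high)
    clean = [_preprocess_subject(s, cohort_cfg.tr, config.prep) for s in subjects]
    if out is not None:
        tsdir = out / "timeseries"
        tsdir.mkdir(exist_ok=True)
        for sub, ts in zip(subjects, clean):
            fio.write_timeseries(ts.values, tsdir / f"{sub.record.subject_id}.tsv",
                                 tr=cohort_cfg.tr)

    cere = np.zeros(cohort_cfg.n_rois, dtype=bool)
    cere[list(cohort_cfg.cerebellum_nodes)] = True
    all_labels = fio.roi_labels(cohort_cfg.n_rois)

    features: dict[str, dict[str, FeatureTable]] = {}
    sw_rows = []
    metric_seed_pool = np.random.SeedSequence([seeds["metrics"]]).generate_state(
        len(subjects) * len(config.templates)
    )
    for t_idx, template in enumerate(config.templates):
        keep = ~cere if template == "without_cerebellum" else np.ones_like(cere)
        labels = [l for l, k in zip(all_labels, keep) if k]
        logger.info("stage net+metrics: template=%s, %d nodes", template, keep.sum())
        per_metric = {name: [] for name in METRIC_NAMES}
        netdir = None
        if out is not None:
            netdir = out / "networks" / template
            netdir.mkdir(parents=True, exist_ok=True)
        for s_idx, (sub, ts) in enumerate(zip(subjects, clean)):
            ts_arm = TimeSeriesMatrix(ts.values[:, keep], ts.tr)
            corr = pearson_matrix(ts_arm)
            net = bonferroni_threshold(
                corr,
                alpha=config.net.alpha,
                positive_only=config.net.positive_only,
                node_labels=labels,
                cerebellum_mask=cere[keep],
            )
            if netdir is not None:
                fio.write_network(net, netdir / f"{sub.record.subject_id}.tsv")
            nm = compute_nodal_metrics(net)
            for name in METRIC_NAMES:
                per_metric[name].append(_metric_vector(nm, name))
            if config.metrics.compute_smallworld:
                gm = small_world_metrics(
                    net,
                    n_nulls=config.metrics.n_nulls,
                    seed=int(metric_seed_pool[t_idx * len(subjects) + s_idx]) % 2**31,
                )
                sw_rows.append(
                    {
                        "subject_id": sub.record.subject_id,
                        "group": sub.record.group,
                        "template": template,
                        "e_glob": gm.e_glob,
                        "e_loc": gm.e_loc,
                        "cp": gm.cp,
                        "lp": gm.lp,
                        "gamma": gm.gamma,
                        "lambda": gm.lambda_,
                        "sigma": gm.sigma,
                    }
                )
        subject_ids = [r.subject_id for r in records]
        features[template] = {
            name: FeatureTable(
                np.vstack(per_metric[name]),
                [(i, name) for i in range(keep.sum())],
                subject_ids,
            )
            for name in METRIC_NAMES
        }

    smallworld = pd.DataFrame(sw_rows) if sw_rows else None
    if out is not None and smallworld is not None:
        smallworld.to_csv(out / "smallworld.csv", index=False, float_format="%.10g")

    gender_code = np.array([1.0 if r.gender == "M" else 0.0 for r in records])
    ages = np.array([r.age for r in records])
    groups = np.array([r.group for r in records])

    performance: dict[str, PerformanceSummary] = {}
    predictions: dict[str, list[FoldPrediction]] = {}
    selected_nodes: dict[str, list[str]] = {}
    classify_seed = seeds["classify"]
    for template in config.templates:
        keep = ~cere if template == "without_cerebellum" else np.ones_like(cere)
        labels = [l for l, k in zip(all_labels, keep) if k]
        for contrast in config.classify.contrasts:
            pos_groups, pos_label, neg_groups = CONTRASTS[contrast]
            in_contrast = np.isin(groups, pos_groups + neg_groups)
            y = np.where(np.isin(groups, pos_groups), pos_label, groups)[in_contrast]
            idx = np.flatnonzero(in_contrast)
            cov = CovariateTable(ages[idx], gender_code[idx])
            for metric in config.selection.metrics:
                table = features[template][metric]
                sub_table = FeatureTable(
                    table.values[idx],
                    table.feature_ids,
                    [table.subject_ids[i] for i in idx],
                )
                logger.info("stage classify: %s | %s | %s", template, contrast, metric)
                preds = loocv(
                    sub_table,
                    y,
                    cov,
                    positive_class=pos_label,
                    mode=config.classify.mode,
                    selection_alpha=config.selection.alpha,
                    n_permutations=config.selection.n_perm,
                    seed=classify_seed,
                )
                key = f"{template}|{contrast}|{metric}"
                predictions[key] = preds
                performance[key] = performance_metrics(preds, pos_label, contrast=key)
                selected_nodes[key] = _full_sample_selection(
                    sub_table, y, cov, pos_label, config, labels, seeds["selection"]
                )

    report = ExperimentReport(
        performance=performance,
        predictions=predictions,
        selected_nodes=selected_nodes,
        smallworld=smallworld,
        features=features,
        records=records,
        provenance={
            "config_hash": config.config_hash(),
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "version": _package_version(),
        },
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
        report.performance_frame().to_csv(
            out / "performance.csv", index=False, float_format="%.6g"
        )
        manifest = sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        )
        (out / "MANIFEST.txt").write_text("\n".join(manifest) + "\n")
    return report


def _full_sample_selection(table, y, cov, pos_label, config, labels, seed):
    """Descriptive full-sample selection (which nodes differ between groups),
    reported alongside the cross-validated performance."""
    from .permselect import permutation_test, residualize, select_features

    resid = residualize(table, cov).values
    y = np.asarray(y)
    result = permutation_test(
        resid[y == pos_label],
        resid[y != pos_label],
        config.selection.n_perm,
        seed=seed,
    )
    sel = select_features(result, config.selection.alpha).selected
    return [labels[i] for i in np.flatnonzero(sel)]


def _package_version() -> str:
    from . import __version__

    return __version__


def summarize_smallworld(report: ExperimentReport) -> pd.DataFrame:
    """Mean and SD of gamma, lambda and sigma per group and template, with a
    flag for small-world organisation (sigma > 1)."""
    if report.smallworld is None or report.smallworld.empty:
        raise ValueError("report has no small-world metrics")
    df = report.smallworld
    agg = (
        df.groupby(["group", "template"])[["gamma", "lambda", "sigma"]]
        .agg(["mean", "std"])
    )
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    agg["small_world"] = agg["sigma_mean"] > 1.0
    return agg.reset_index()
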