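"""End-to-end simulation study: generate, fit the six models, aggregate tables.

A study config names a simulation scenario, the model variants to fit, and
either fixed (s0, s1) per model or grids to search by cross-validated
deviance.  Each replicate dataset gets its own deterministic seed derived
from the master seed, so results are reproducible regardless of worker count.
Aggregated output mirrors the usual layout of simulation benchmark tables:
one table of prediction-error metrics and one of classification metrics, one
row per model, averaged over replicate datasets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from .em_solver import DesignData, FitControl
from .evaluation import (
    ALL_METRICS,
    LOWER_IS_BETTER,
    CVReport,
    grid_select,
    kfold_cv,
    path_select,
    stratified_folds,
)
from .simdata import SimScenario, generate_dataset, replicate_seeds
from .spatial_graph import lattice_adjacency
from .ssen_prior import MODEL_NAMES, PriorSpec

logger = logging.getLogger(__name__)

#: (s0, s1) selections reported for the two standard simulation conditions,
#: keyed by non-zero signal value; used to skip grid search when requested.
REPORTED_HYPERPARAMS = {
    0.10: {
        "lasso": (0.022, 0.022),
        "ssl": (0.08, 1.0),
        "ssl-iar": (0.10, 1.0),
        "en": (0.037, 0.037),
        "ssen": (0.07, 1.0),
        "ssen-iar": (0.10, 2.0),
    },
    0.05: {
        "lasso": (0.035, 0.035),
        "ssl": (0.06, 1.0),
        "ssl-iar": (0.09, 1.0),
        "en": (0.061, 0.061),
        "ssen": (0.05, 1.0),
        "ssen-iar": (0.10, 2.0),
    },
}

#: Default simulation search grids: spike scales 0.01..0.10, slab scales {1, 2}.
DEFAULT_S0_GRID = tuple(np.round(np.arange(0.01, 0.11, 0.01), 2))
DEFAULT_S1_GRID = (1.0, 2.0)


@dataclass(frozen=True)
class StudyConfig:
    scenario: SimScenario = field(default_factory=SimScenario)
    n_datasets: int = 50
    models: tuple = MODEL_NAMES
    s0_grid: tuple = DEFAULT_S0_GRID
    s1_grid: tuple = DEFAULT_S1_GRID
    k: int = 5
    repeats: int = 1
    fixed_hyperparams: dict | None = None
    master_seed: int = 0
    n_workers: int = 1
    graph_scheme: str = "rook"

    def __post_init__(self):
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown model names: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scen = raw.pop("scenario", {})
        if "signal_center" in scen and scen["signal_center"] is not None:
            scen["signal_center"] = tuple(scen["signal_center"])
        fixed = raw.pop("fixed_hyperparams", None)
        if fixed is not None:
            fixed = {m: tuple(v) for m, v in fixed.items()}
        return cls(
            scenario=SimScenario(**scen),
            fixed_hyperparams=fixed,
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.items()
            },
        )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.to_dict(),
            "n_datasets": self.n_datasets,
            "models": list(self.models),
            "s0_grid": [float(s) for s in self.s0_grid],
            "s1_grid": [float(s) for s in self.s1_grid],
            "k": self.k,
            "repeats": self.repeats,
            "fixed_hyperparams": (
                None
                if self.fixed_hyperparams is None
                else {m: list(v) for m, v in self.fixed_hyperparams.items()}
            ),
            "master_seed": self.master_seed,
            "n_workers": self.n_workers,
            "graph_scheme": self.graph_scheme,
        }


@dataclass
class StudyResult:
    per_dataset: pd.DataFrame  # one row per (dataset, model)
    aggregate: pd.DataFrame  # one row per model: mean metrics over datasets
    missing_counts: pd.DataFrame  # per model: count of undefined metric values
    n_failed: int
    failed_seeds: list


def traditional_scale(lam: float, n_train: int) -> float:
    """Map a per-observation (glmnet-convention) penalty level to this
    package's prior scale.

    Benchmark tables report the traditional lasso/EN penalty as the
    per-observation lambda of an averaged-likelihood objective; this package
    penalizes the total log-likelihood with multiplier 1/s, so the equivalent
    scale is s = 1 / (lambda * n_train).
    """
    if lam <= 0 or n_train < 1:
        raise ValueError("lambda must be positive and n_train >= 1")
    return 1.0 / (lam * n_train)


def _fit_one_model(data, model, config, graph, folds, cv_seed, control):
    """CV metrics for one model on one dataset; returns a metrics row."""
    spatial_graph = graph if model.endswith("iar") else None
    fixed = (config.fixed_hyperparams or {}).get(model)
    if fixed is not None:
        s0, s1 = fixed
        if model in ("lasso", "en"):
            # fixed values for traditional models are per-observation lambdas
            n_train = int(round(data.n_subjects * (config.k - 1) / config.k))
            s = traditional_scale(s0, n_train)
            prior = PriorSpec.from_model_name(model, s)
        else:
            prior = PriorSpec.from_model_name(model, s0, s1)
        res = kfold_cv(
            data,
            prior,
            spatial_graph,
            k=config.k,
            control=control,
            folds_per_repeat=folds,
        )
        metrics = res.metrics
    else:
        prior = PriorSpec.from_model_name(model, 0.05, 1.0)
        if prior.spike_slab:
            report: CVReport = grid_select(
                data,
                prior,
                spatial_graph,
                s0_grid=config.s0_grid,
                s1_grid=config.s1_grid,
                k=config.k,
                repeats=config.repeats,
                seed=cv_seed,
                control=control,
            )
        else:
            report = path_select(
                data,
                prior.xi,
                k=config.k,
                repeats=config.repeats,
                seed=cv_seed,
                control=control,
            )
        s0, s1 = report.chosen
        metrics = {m: report.chosen_row[m] for m in ALL_METRICS}
    return {"model": model, "s0": s0, "s1": s1, **metrics}


def _run_replicate(config: StudyConfig, index: int, seed: int, control: FitControl):
    scenario = replace(config.scenario, seed=int(seed))
    ds = generate_dataset(scenario)
    data = DesignData.from_arrays(ds.X, ds.y)
    graph = lattice_adjacency(
        scenario.n_rows, scenario.n_cols, scheme=config.graph_scheme
    )
    cv_seed = int(seed % (2**31 - 1))
    # one fold assignment per repeat, shared by all models for comparability
    folds = [
        stratified_folds(data.y.astype(int), config.k, cv_seed + r)
        for r in range(config.repeats)
    ]
    rows = []
    for model in config.models:
        row = _fit_one_model(data, model, config, graph, folds, cv_seed, control)
        row.update({"dataset": index, "seed": int(seed)})
        logger.info(
            "replicate %d seed %d model %s (s0=%g, s1=%g): deviance=%.2f auc=%.3f",
            index, seed, model, row["s0"], row["s1"], row["deviance"], row["auc"],
        )
        rows.append(row)
    return rows


def run_study(config: StudyConfig, control: FitControl | None = None) -> StudyResult:
    """Run the full simulation study described by ``config``."""
    control = control or FitControl()
    seeds = replicate_seeds(config.master_seed, config.n_datasets)

    def job(i):
        try:
            return _run_replicate(config, i, seeds[i], control)
        except Exception:  # noqa: BLE001 - replicate failures are reported, not fatal
            logger.exception("replicate %d (seed %d) failed", i, seeds[i])
            return {"failed_seed": int(seeds[i])}

    results = Parallel(n_jobs=config.n_workers)(
        delayed(job)(i) for i in range(config.n_datasets)
    )
    rows, failed = [], []
    for out in results:
        if isinstance(out, dict):
            failed.append(out["failed_seed"])
        else:
            rows.extend(out)
    if failed:
        logger.warning("%d replicate(s) failed: seeds %s", len(failed), failed)
    per_dataset = pd.DataFrame(rows)
    front = ["dataset", "seed", "model", "s0", "s1"]
    per_dataset = per_dataset[front + [c for c in ALL_METRICS]]
    grouped = per_dataset.groupby("model", sort=False)
    aggregate = grouped[["s0", "s1", *ALL_METRICS]].mean()
    aggregate = aggregate.reindex([m for m in config.models])
    missing = grouped[list(ALL_METRICS)].agg(lambda s: int(s.isna().sum()))
    missing = missing.reindex([m for m in config.models])
    return StudyResult(
        per_dataset=per_dataset,
        aggregate=aggregate,
        missing_counts=missing,
        n_failed=len(failed),
        failed_seeds=failed,
    )


def compare_models(result: StudyResult, metric: str) -> list[str]:
    """Models ordered best-first on ``metric`` (direction-aware; ties by name)."""
    if metric not in result.aggregate.columns:
        raise ValueError(f"unknown metric {metric!r}")
    col = result.aggregate[metric]
    ascending = metric in LOWER_IS_BETTER
    frame = col.reset_index().rename(columns={"index": "model"})
    frame = frame.sort_values([metric, "model"], ascending=[ascending, True],
                              kind="mergesort")
    return frame["model"].tolist()


def load_feature_table(path, label_column: str, label_map: dict | None = None) -> DesignData:
    """Read a delimited feature table with a binary label column.

    ``label_map`` maps class strings to {0, 1} (e.g. ``{"CN": 0,
    "Dementia": 1}``).  Missing values and unmapped labels are hard errors.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"{path}: file contains no data rows")
    if label_column not in df.columns:
        raise ValueError(f"{path}: no column named {label_column!r}")
    if df.isna().any().any():
        cells = [
            f"(row {i}, column {c})"
            for c in df.columns
            for i in df.index[df[c].isna()]
        ]
        raise ValueError(f"{path}: missing values at " + ", ".join(cells[:20]))
    labels = df[label_column]
    if label_map:
        unmapped = sorted(set(labels.astype(str)) - set(map(str, label_map)))
        if unmapped:
            raise ValueError(f"{path}: unmapped label value(s) {unmapped}")
        labels = labels.astype(str).map({str(k): v for k, v in label_map.items()})
    y = labels.to_numpy()
    if not np.all(np.isin(np.unique(y), [0, 1])):
        raise ValueError(
            f"{path}: label column {label_column!r} is not binary 0/1 "
            f"(values {sorted(pd.unique(labels))}); provide a label_map"
        )
    X = df.drop(columns=[label_column]).to_numpy(dtype=float)
    data = DesignData.from_arrays(X, y.astype(int))
    logger.info(
        "loaded %s: N=%d, J=%d, event rate %.2f%%",
        path, data.n_subjects, data.n_predictors, 100 * data.y.mean(),
    )
    return data


def write_tables(result: StudyResult, config: StudyConfig, outdir):
    """Emit the tidy study outputs (two aggregate tables, per-dataset rows)."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pred = result.aggregate[["s0", "s1", "deviance", "auc", "mse", "mae", "mc"]]
    cls = result.aggregate[["s0", "s1", "ac", "sn", "sp", "ppv", "npv", "mcc", "f1"]]
    pred.to_csv(outdir / "table3_like.tsv", sep="\t")
    cls.to_csv(outdir / "table4_like.tsv", sep="\t")
    result.per_dataset.to_csv(outdir / "per_dataset.tsv", sep="\t", index=False)
    manifest = {
        "config": config.to_dict(),
        "n_failed": result.n_failed,
        "failed_seeds": result.failed_seeds,
    }
    with open(outdir / "study_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def plot_classification(result: StudyResult, path=None):
    """Basic grouped bar chart of classification metrics by model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["ac", "sn", "sp", "ppv", "npv", "mcc", "f1"]
    ax = result.aggregate[metrics].plot.bar(figsize=(9, 4), rot=0)
    ax.set_ylabel("cross-validated average")
    ax.set_ylim(0, 1)
    fig = ax.get_figure()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
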