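"""Cross-validated evaluation, metrics, baselines and orchestration.

Stratified k-fold plans, the standard binary-classification report
(accuracy, rank-based AUC, sensitivity, specificity, F1), the three
reference pipelines (no graph / random graph / fully-connected graph), the
sensitivity sweep over the filter cutoff k, and ``run_experiment`` which
glues the whole pipeline together from a config mapping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import sklearn
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .blocks import BlockClassifier, block_accuracy_curve, filter_features
from .cohort import Cohort, SimulationParams, generate_cohort, load_cohort, vectorize_rsfc
from .ensemble import select_low_frequency_graphs, train_ensemble
from .graphs import build_population_graph, enumerate_graph_configs
from .spectral import combinatorial_laplacian, eigendecompose

logger = logging.getLogger("popgse")

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "stratified_kfold",
    "compute_metrics",
    "run_baseline",
    "sweep_k",
    "run_experiment",
]


@dataclasses.dataclass
class FoldPlan:
    """Disjoint, exhaustive, label-stratified fold assignment."""

    n_folds: int
    assignments: np.ndarray
    seed: int

    def validate(self, labels: np.ndarray) -> None:
        labels = np.asarray(labels)
        if sorted(np.unique(self.assignments)) != list(range(self.n_folds)):
            raise ValueError("assignments must cover folds 0..n_folds-1")
        for cls in np.unique(labels):
            counts = np.bincount(self.assignments[labels == cls], minlength=self.n_folds)
            if counts.max() - counts.min() > 1:
                raise ValueError(f"class {cls} not stratified within one subject per fold")


def stratified_kfold(labels: np.ndarray, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded stratified partition preserving the class ratio per fold."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if np.min(np.bincount(labels)) < n_folds:
        raise ValueError("every class needs at least n_folds members")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    plan = FoldPlan(n_folds=n_folds, assignments=assignments, seed=seed)
    plan.validate(labels)
    return plan


def _rank_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with average-rank tie correction."""
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = scipy.stats.rankdata(probabilities)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclasses.dataclass
class MetricsReport:
    """Binary-classification metrics with optional per-fold mean +/- sd."""

    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    f_score: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc_defined: bool = True
    per_fold: dict | None = None
    runtime_seconds: float | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["per_fold"] is not None:
            d["per_fold"] = {k: list(v) for k, v in d["per_fold"].items()}
        return d


def compute_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    fold_assignments: np.ndarray | None = None,
) -> MetricsReport:
    """Confusion-matrix metrics at the given threshold plus rank AUC.

    The positive class (label 1, the patient class) defines sensitivity and
    the F1 score.  With a fold assignment, per-fold means and standard
    deviations are reported alongside the pooled values.  Single-class
    label vectors leave the AUC undefined (NaN, flagged) but the remaining
    metrics are still computed.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    pred = (probabilities >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = len(labels)
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    if precision + (0.0 if np.isnan(sensitivity) else sensitivity) > 0:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f_score = 0.0
    auc = _rank_auc(probabilities, labels)
    per_fold = None
    if fold_assignments is not None:
        fold_assignments = np.asarray(fold_assignments)
        accs, aucs = [], []
        for fold in np.unique(fold_assignments):
            mask = fold_assignments == fold
            accs.append(float(np.mean(pred[mask] == labels[mask])))
            aucs.append(_rank_auc(probabilities[mask], labels[mask]))
        per_fold = {
            "accuracy": (float(np.mean(accs)), float(np.std(accs))),
            "auc": (float(np.nanmean(aucs)), float(np.nanstd(aucs))),
        }
    return MetricsReport(
        accuracy=accuracy,
        auc=auc,
        sensitivity=sensitivity,
        specificity=specificity,
        f_score=f_score,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auc_defined=not np.isnan(auc),
        per_fold=per_fold,
    )


def single_block_oof(
    X: np.ndarray,
    y: np.ndarray,
    fold_assignments: np.ndarray,
    random_state: int = 0,
    **block_params,
) -> np.ndarray:
    """Out-of-fold positive-class probabilities of one learning block."""
    y = np.asarray(y)
    oof = np.full(len(y), np.nan)
    for fi, fold in enumerate(np.unique(fold_assignments)):
        test = fold_assignments == fold
        clf = BlockClassifier(random_state=random_state + fi, **block_params)
        clf.fit(X[~test], y[~test])
        pos_col = int(np.where(clf.classes_ == 1)[0][0])
        oof[test] = clf.predict_proba(X[test])[:, pos_col]
    return oof


def run_baseline(
    kind: str,
    cohort: Cohort,
    fold_assignments: np.ndarray,
    k: int = 200,
    random_density: float = 0.1,
    seed: int = 0,
    **block_params,
) -> MetricsReport:
    """Reference pipelines probing the value of the graph construction.

    ``no_graph`` trains the block on unfiltered features (equivalently any
    graph with k = n); ``random_graph`` and ``fc_graph`` run the filtering
    pipeline on the corresponding baseline graph.
    """
    X = vectorize_rsfc(cohort).values
    y = cohort.labels
    if kind == "no_graph":
        Xf = X
    elif kind in ("random_graph", "fc_graph"):
        from .graphs import build_baseline_graph

        graph = build_baseline_graph(
            kind.split("_")[0], cohort.n, density=random_density, seed=seed,
            subject_ids=cohort.subject_ids,
        )
        basis = eigendecompose(combinatorial_laplacian(graph), source_config=graph.config)
        Xf = filter_features(basis, X, k)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    oof = single_block_oof(X=Xf, y=y, fold_assignments=fold_assignments,
                           random_state=seed, **block_params)
    return compute_metrics(oof, y, fold_assignments=fold_assignments)


def sweep_k(
    bases: list,
    X: np.ndarray,
    y: np.ndarray,
    k_values: list[int],
    fold_assignments: np.ndarray,
    random_state: int = 0,
    **ensemble_params,
) -> pd.DataFrame:
    """Ensemble metrics as a function of the shared filter cutoff k.

    One cross-validated ensemble run per k, with folds and seeds shared
    across cutoffs so the rows are directly comparable.
    """
    n = len(y)
    rows = []
    for k in k_values:
        if not 1 <= k <= n:
            raise ValueError(f"k={k} out of range [1, {n}]")
        inputs = [filter_features(b, X, int(k)) for b in bases]
        result = train_ensemble(inputs, y, fold_assignments,
                                random_state=random_state, **ensemble_params)
        report = compute_metrics(result.oof_probabilities, y,
                                 fold_assignments=fold_assignments)
        rows.append(
            {
                "k": int(k),
                "accuracy_mean": report.per_fold["accuracy"][0],
                "accuracy_sd": report.per_fold["accuracy"][1],
                "auc_mean": report.per_fold["auc"][0],
                "auc_sd": report.per_fold["auc"][1],
            }
        )
    return pd.DataFrame(rows)


# -- experiment orchestration ------------------------------------------------

DEFAULT_CONFIG: dict = {
    "cohort": {"path": None, "simulate": {}},
    "graphs": {"sigma": None, "age_bin_width": 5.0, "random_density": 0.1,
               "include_baselines": True},
    "spectral": {"k": 200, "low_k_fraction": 0.2, "margin": 0.01},
    "blocks": {"hidden_sizes": [512, 64], "learning_rate": 0.01, "epochs": 200,
               "dropout": 0.3},
    "curves": {"k_fractions": [0.1, 0.2, 1.0], "epochs": 30, "n_folds": 3},
    "ensemble": {"mode": "weighted_sum", "training": "end_to_end", "top_m": 8,
                 "epochs": 200},
    "evaluation": {"n_folds": 10, "seed": 0, "threshold": 0.5, "repeats": 1},
}


class ConfigError(ValueError):
    pass


def _merge_config(user: dict, defaults: dict, path: str = "") -> dict:
    merged = {}
    for key, default in defaults.items():
        here = f"{path}.{key}".lstrip(".")
        value = user.get(key, default)
        if isinstance(default, dict) and key != "simulate" and isinstance(value, dict):
            value = _merge_config(value, default, here)
        merged[key] = value
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(f'{path}.{k}'.lstrip('.') for k in unknown)}")
    return merged


def load_config(source: dict | str | Path | None) -> dict:
    """Merge a YAML file or mapping over the documented defaults."""
    import yaml

    if source is None:
        user = {}
    elif isinstance(source, (str, Path)):
        user = yaml.safe_load(Path(source).read_text()) or {}
    else:
        user = dict(source)
    sim_keys = {f.name for f in dataclasses.fields(SimulationParams)}
    sim = user.get("cohort", {}).get("simulate", {}) or {}
    unknown = set(sim) - sim_keys
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted('cohort.simulate.' + k for k in unknown)}")
    return _merge_config(user, DEFAULT_CONFIG)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run_experiment(
    config: dict | str | Path | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Full pipeline: cohort -> graphs -> spectra -> curves -> selection ->
    cross-validated ensemble -> metrics.

    Returns a report dict; when ``out_dir`` is given, writes predictions
    and gate weights as CSV, metrics as JSON, and a provenance manifest
    (config hash, seed, package versions).
    """
    t0 = time.time()
    cfg = load_config(config)
    if seed is not None:
        cfg["evaluation"]["seed"] = int(seed)
    eval_seed = int(cfg["evaluation"]["seed"])

    # cohort
    if cfg["cohort"]["path"]:
        cohort = load_cohort(cfg["cohort"]["path"])
        logger.info("loaded cohort of %d subjects from %s", cohort.n, cfg["cohort"]["path"])
    else:
        sim = dict(cfg["cohort"]["simulate"] or {})
        sim.setdefault("seed", eval_seed)
        if "age_range" in sim:
            sim["age_range"] = tuple(sim["age_range"])
        params = SimulationParams(**sim)
        cohort = generate_cohort(params)
        logger.info("simulated cohort of %d subjects (r=%d)", cohort.n, cohort.r)
    features = vectorize_rsfc(cohort)
    X, y, n = features.values, cohort.labels, cohort.n

    # graphs and spectra
    configs = enumerate_graph_configs(
        include_baselines=bool(cfg["graphs"]["include_baselines"]),
        random_density=float(cfg["graphs"]["random_density"]),
        seed=eval_seed,
    )
    graphs = {c: build_population_graph(features, cohort, c, sigma=cfg["graphs"]["sigma"])
              for c in configs}
    bases = {c: eigendecompose(combinatorial_laplacian(g), source_config=c)
             for c, g in graphs.items()}
    logger.info("built %d population graphs", len(graphs))

    # accuracy-vs-k curves and low-frequency selection
    curve_cfg = cfg["curves"]
    k_grid = sorted({max(1, int(np.ceil(f * n))) for f in curve_cfg["k_fractions"]} | {n})
    curve_folds = stratified_kfold(y, n_folds=int(curve_cfg["n_folds"]), seed=eval_seed)
    block_cfg = cfg["blocks"]
    curves = {}
    for c in configs:
        curves[c] = (
            np.asarray(k_grid),
            block_accuracy_curve(
                bases[c], X, y, np.asarray(k_grid), curve_folds.assignments,
                random_state=eval_seed,
                hidden_sizes=tuple(block_cfg["hidden_sizes"]),
                dropout=float(block_cfg["dropout"]),
                learning_rate=float(block_cfg["learning_rate"]),
                epochs=int(curve_cfg["epochs"]),
            ),
        )
        logger.info("curve %-24s %s", c.name, np.round(curves[c][1], 3))
    selection = select_low_frequency_graphs(
        curves, n,
        low_k_fraction=float(cfg["spectral"]["low_k_fraction"]),
        margin=float(cfg["spectral"]["margin"]),
        top_m=cfg["ensemble"]["top_m"],
    )
    logger.info("selected %d low-frequency graphs: %s",
                selection.m, [c.name for c in selection.selected])

    # cross-validated ensemble
    k = min(int(cfg["spectral"]["k"]), n)
    inputs = [filter_features(bases[c], X, k) for c in selection.selected]
    plan = stratified_kfold(y, n_folds=int(cfg["evaluation"]["n_folds"]), seed=eval_seed)
    result = train_ensemble(
        inputs, y, plan.assignments,
        random_state=eval_seed,
        mode=cfg["ensemble"]["mode"],
        training=cfg["ensemble"]["training"],
        hidden_sizes=tuple(block_cfg["hidden_sizes"]),
        dropout=float(block_cfg["dropout"]),
        learning_rate=float(block_cfg["learning_rate"]),
        epochs=int(cfg["ensemble"]["epochs"]),
    )
    report = compute_metrics(
        result.oof_probabilities, y,
        threshold=float(cfg["evaluation"]["threshold"]),
        fold_assignments=plan.assignments,
    )
    report.runtime_seconds = time.time() - t0

    bundle = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": eval_seed,
        "n_subjects": int(n),
        "k_effective": int(k),
        "selected_graphs": [c.name for c in selection.selected],
        "regimes": {c.name: selection.regimes[c] for c in curves},
        "metrics": report.to_dict(),
        "fold_alphas": result.fold_alphas.tolist(),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "subject_id": cohort.subject_ids,
                "fold": plan.assignments,
                "probability": result.oof_probabilities,
                "predicted_label": result.oof_predictions,
                "true_label": y,
            }
        ).to_csv(out_dir / "predictions.csv", index=False)
        gates = []
        for fold, alpha in enumerate(result.fold_alphas):
            for c, a in zip(selection.selected, alpha):
                gates.append({"fold": fold, "config_name": c.name, "alpha": float(a)})
        pd.DataFrame(gates).to_csv(out_dir / "gates.csv", index=False)
        (out_dir / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
        manifest = {
            "config": cfg,
            "config_hash": bundle["config_hash"],
            "seed": eval_seed,
            "versions": {
                "popgse": __version__,
                "numpy": np.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return bundle
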