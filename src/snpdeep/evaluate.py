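"""Stratified five-fold cross-validated evaluation of the full pipeline.

The unit under validation is the *whole* pipeline, not just the
classifier: in the default fold-safe mode each fold refits the mean
encoding and the feature selection on its training samples only, so no
held-out label can reach the features or the selected SNP set.  The
``global`` encoding mode (encoding and selection fitted once on all
samples) is available for comparison; on label-independent data it
measurably inflates accuracy, which is exactly the data-leakage failure
mode the fold-safe default guards against.

Metrics use Case as the positive class: accuracy, sensitivity (Case
recall), specificity (Control recall) and F1.  A metric whose denominator
is zero is reported as 0 and flagged as degenerate rather than raised —
a fold whose test split happens to be single-class is a legitimate,
reportable outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EncodedMatrix, GenotypeMatrix
from .errors import ValidationError
from .models import ModelSpec, predict, train_classifier
from .preprocess import apply_mean_encoding, fit_mean_encoding
from .select import select_features

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1")


def stratified_kfold(y: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified partition into k test-index sets.

    Fold sizes differ by at most one, as do the per-class counts across
    folds.  Raises when any class has fewer than k members.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    if k < 2:
        raise ValidationError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} member(s) < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(y)), y)]


@dataclass
class ConfusionCounts:
    """Binary confusion counts with Case = positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity and F1 from confusion counts.

    Any 0/0 ratio is reported as 0.0 and listed in the returned
    ``degenerate`` entry, mirroring how all-one-class test folds show up as
    0% cells in practice.
    """
    if c.total == 0:
        raise ValidationError("empty confusion counts")
    degenerate = []

    def safe(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    out = {
        "accuracy": (c.tp + c.tn) / c.total,
        "sensitivity": safe(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": safe(c.tn, c.tn + c.fp, "specificity"),
        "f1": safe(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1"),
        "degenerate": degenerate,
    }
    return out


@dataclass
class PipelineConfig:
    """Everything that defines one (FS method, model, encoding mode) pipeline."""

    fs_method: str = "amgm_cosine"
    n_select: int = 100
    n_intermediate: int = 1000
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    encoding_mode: str = "fold_safe"  # or "global"
    k: int = 5
    seed: int = 0
    fs_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.encoding_mode not in ("fold_safe", "global"):
            raise ValidationError("encoding_mode must be 'fold_safe' or 'global'")


@dataclass
class CVReport:
    """Per-fold confusion counts and metrics, plus fold-averaged metrics."""

    fold_counts: list[ConfusionCounts]
    fold_metrics: list[dict]
    mean_metrics: dict
    provenance: dict

    @property
    def k(self) -> int:
        return len(self.fold_counts)


def cross_validate(dataset: GenotypeMatrix, config: PipelineConfig) -> CVReport:
    """Run the full encode -> select -> train -> predict pipeline under CV.

    ``dataset`` must already be cleaned (NC-free, labeled).  In fold-safe
    mode every label-dependent fit (encoding, feature selection, model) sees
    only the training samples of its fold; in global mode the encoding and
    the selection are fitted once on all samples and only the model is
    refitted per fold.
    """
    if dataset.labels is None:
        raise ValidationError("cross_validate requires a labeled dataset")
    y = dataset.y()
    folds = stratified_kfold(y, k=config.k, seed=config.seed)
    samples = np.array(dataset.sample_ids)

    global_encoded = None
    global_selection = None
    if config.encoding_mode == "global":
        mapping = fit_mean_encoding(dataset)
        global_encoded = apply_mean_encoding(mapping, dataset)
        global_selection = select_features(
            dataset, global_encoded, config.fs_method,
            n_select=config.n_select, n_intermediate=config.n_intermediate,
            seed=config.seed, **config.fs_params,
        )

    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[dict] = []
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        train_ids = samples[train_idx].tolist()
        test_ids = samples[test_idx].tolist()
        try:
            if config.encoding_mode == "global":
                X_train = global_encoded.subset_samples(train_ids).subset_snps(global_selection.snp_ids)
                X_test = global_encoded.subset_samples(test_ids).subset_snps(global_selection.snp_ids)
            else:
                G_train = dataset.subset_samples(train_ids)
                mapping = fit_mean_encoding(G_train)
                X_train_full = apply_mean_encoding(mapping, G_train)
                selection = select_features(
                    G_train, X_train_full, config.fs_method,
                    n_select=config.n_select, n_intermediate=config.n_intermediate,
                    seed=config.seed, **config.fs_params,
                )
                X_train = X_train_full.subset_snps(selection.snp_ids)
                G_test = dataset.subset_samples(test_ids)
                X_test = apply_mean_encoding(mapping, G_test).subset_snps(selection.snp_ids)

            model = train_classifier(X_train, spec=config.model_spec)
            _, y_pred = predict(model, X_test)
        except Exception as exc:  # annotate with the fold, then re-raise
            raise type(exc)(f"fold {fold_i}: {exc}") from exc
        counts = confusion_counts(y[test_idx], y_pred)
        fold_counts.append(counts)
        fold_metrics.append(classification_metrics(counts))

    mean_metrics = {
        name: float(np.mean([fm[name] for fm in fold_metrics])) for name in METRIC_NAMES
    }
    provenance = {
        "fs_method": config.fs_method,
        "n_select": config.n_select,
        "architecture": config.model_spec.architecture,
        "model_spec": config.model_spec,
        "encoding_mode": config.encoding_mode,
        "k": config.k,
        "seed": config.seed,
    }
    return CVReport(fold_counts, fold_metrics, mean_metrics, provenance)


def summarize_heatmap(
    reports: dict[tuple, CVReport] | list[CVReport],
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Condense CV reports into a long-format results table (and heatmaps).

    ``reports`` is either a list (keys derived from each report's
    provenance) or a mapping from ``(dataset, fs_method, n_features, model)``
    tuples to reports.  The table has one row per (cell, metric); with
    ``plot_path`` one heatmap figure per metric is written (model rows by
    dataset/FS columns, mean metric in each cell).
    """
    if not reports:
        raise ValidationError("no reports to summarize")
    if isinstance(reports, list):
        reports = {
            (
                r.provenance.get("dataset", "dataset"),
                r.provenance["fs_method"],
                r.provenance["n_select"],
                r.provenance["architecture"],
            ): r
            for r in reports
        }
    rows = []
    for (dataset, fs_method, n_features, model), report in reports.items():
        for metric in METRIC_NAMES:
            rows.append(
                {
                    "dataset": dataset,
                    "fs_method": fs_method,
                    "n_features": n_features,
                    "model": model,
                    "metric": metric,
                    "mean_value": report.mean_metrics[metric],
                }
            )
    table = pd.DataFrame(rows)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        for metric in METRIC_NAMES:
            sub = table[table.metric == metric]
            pivot = sub.pivot_table(
                index="model", columns=["dataset", "fs_method", "n_features"], values="mean_value"
            )
            fig, ax = plt.subplots(figsize=(2 + pivot.shape[1], 1 + 0.5 * pivot.shape[0]))
            sns.heatmap(pivot, annot=True, fmt=".2f", vmin=0, vmax=1, cmap="viridis", ax=ax)
            ax.set_title(metric)
            fig.tight_layout()
            fig.savefig(f"{plot_path.removesuffix('.png')}_{metric}.png", dpi=120)
            plt.close(fig)
    return table
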