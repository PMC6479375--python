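"""Repeated-split classifier benchmark over band-wise feature tables.

Four feature conditions are benchmarked: ``raw`` (band-filtered samples as
features), ``lda`` (raw + per-fold Fisher reduction), ``de`` (differential
entropy), and ``de_lda`` (DE + per-fold Fisher reduction). Five classifiers
ship with fixed hyperparameters: k-NN (k=20), L2 logistic regression (C=1),
RBF-kernel SVM (C=1), random forest (120 trees, depth 10, min split 8) and
an Adam-trained MLP (hidden 64/32, ReLU, batch 32, lr 1e-4).

Splitting defaults to repeated stratified 70/30 hold-out; stratified k-fold
is available as an alternative mode. Any Fisher reduction is fitted inside
each training fold and applied to its validation fold only. Metrics are
accuracy, macro precision/recall/F1 and Cohen's kappa, plus per-split
classifier fit+predict wall time and a confusion matrix summed over splits.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .data import FeatureTable
from .lda import fit_lda, transform

CONDITIONS = ("raw", "lda", "de", "de_lda")


@dataclass
class ClassifierSpec:
    """A named classifier plus hyperparameter overrides."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _BUILDERS:
            raise ValueError(
                f"unknown classifier {self.name!r}; expected one of {sorted(_BUILDERS)}"
            )

    def build(self, seed: int):
        return _BUILDERS[self.name](self.params, seed)


def _build_knn(params: dict, seed: int):
    return KNeighborsClassifier(n_neighbors=params.get("n_neighbors", 20))


def _build_lr(params: dict, seed: int):
    return LogisticRegression(
        penalty=params.get("penalty", "l2"),
        C=params.get("C", 1.0),
        max_iter=params.get("max_iter", 1000),
    )


def _build_svm(params: dict, seed: int):
    return SVC(
        kernel=params.get("kernel", "rbf"),
        C=params.get("C", 1.0),
        random_state=seed,
    )


def _build_rf(params: dict, seed: int):
    return RandomForestClassifier(
        n_estimators=params.get("n_estimators", 120),
        max_depth=params.get("max_depth", 10),
        min_samples_split=params.get("min_samples_split", 8),
        random_state=seed,
    )


def _build_mlp(params: dict, seed: int):
    return MLPClassifier(
        hidden_layer_sizes=tuple(params.get("hidden_layer_sizes", (64, 32))),
        activation=params.get("activation", "relu"),
        solver=params.get("solver", "adam"),
        batch_size=params.get("batch_size", 32),
        learning_rate_init=params.get("learning_rate_init", 1e-4),
        max_iter=params.get("max_iter", 200),
        random_state=seed,
    )


_BUILDERS = {
    "knn": _build_knn,
    "lr": _build_lr,
    "svm": _build_svm,
    "rf": _build_rf,
    "mlp": _build_mlp,
}


def default_classifiers(names: list[str] | None = None) -> list[ClassifierSpec]:
    return [ClassifierSpec(n) for n in (names or list(_BUILDERS))]


@dataclass
class SplitProtocol:
    """Resampling protocol: repeated stratified hold-out or k-fold CV."""

    mode: str = "repeated_holdout"
    train_fraction: float = 0.7
    repeats: int = 200
    folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("repeated_holdout", "kfold"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @property
    def n_splits(self) -> int:
        return self.repeats if self.mode == "repeated_holdout" else self.repeats * self.folds


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def split(
    labels: np.ndarray, protocol: SplitProtocol, repeat_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (train, valid) index arrays for one repeat.

    In hold-out mode ``repeat_index`` enumerates repeats; in k-fold mode it
    enumerates round * folds + fold. Identical (seed, repeat_index) always
    yields the identical split.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise ValueError(f"class(es) {small.tolist()} have fewer than 2 samples")
    if labels.size < classes.size:
        raise ValueError("fewer samples than classes")
    if protocol.mode == "repeated_holdout":
        rs = _derived_seed(protocol.seed, repeat_index)
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=protocol.train_fraction, random_state=rs
        )
        train, valid = next(splitter.split(np.zeros_like(labels), labels))
        return train, valid
    round_idx, fold_idx = divmod(repeat_index, protocol.folds)
    rs = _derived_seed(protocol.seed, round_idx)
    kf = StratifiedKFold(n_splits=protocol.folds, shuffle=True, random_state=rs)
    for i, (train, valid) in enumerate(kf.split(np.zeros_like(labels), labels)):
        if i == fold_idx:
            return train, valid
    raise IndexError(f"fold index {fold_idx} out of range for {protocol.folds} folds")


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> dict:
    """Accuracy, macro precision/recall/F1 and Cohen's kappa."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    labels = np.arange(n_classes)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "macro_precision": float(prec),
        "macro_recall": float(rec),
        "macro_f1": float(f1),
        "kappa": float(cohen_kappa_score(y_true, y_pred, labels=labels)),
    }


@dataclass
class EvalReport:
    """Per-split records plus summed confusion matrices for one condition."""

    condition: str
    n_classes: int
    records: pd.DataFrame
    confusions: dict[tuple[str, str], np.ndarray]

    def aggregate(self, include_timing: bool = True) -> pd.DataFrame:
        """Mean and std of every metric per (band, classifier) cell."""
        if self.records.empty:
            raise ValueError("empty report")
        metrics = ["accuracy", "macro_precision", "macro_recall", "macro_f1", "kappa"]
        if include_timing:
            metrics = metrics + ["seconds"]
        g = self.records.groupby(["band", "classifier"], sort=True)[metrics]
        agg = g.agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        # a single split has no spread; report 0 rather than NaN
        agg = agg.fillna(0.0)
        return agg.reset_index()


def run_condition(
    tables: dict[str, FeatureTable],
    condition: str,
    classifiers: list[ClassifierSpec],
    protocol: SplitProtocol,
    *,
    lda_dim: int | None = None,
    lda_shrinkage: float = 1e-6,
) -> EvalReport:
    """Full factorial benchmark: bands x classifiers x splits.

    ``tables`` maps band name (possibly including 'combined') to the feature
    table appropriate for the condition: raw tables for raw/lda, DE tables
    for de/de_lda. For the two *_lda conditions a Fisher projection is
    fitted on each training fold and applied to its validation fold.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if not tables:
        raise ValueError("no feature tables given")
    if not classifiers:
        raise ValueError("no classifiers given")
    use_lda = condition in ("lda", "de_lda")

    first = next(iter(tables.values()))
    n_classes = int(np.unique(first.labels).size)
    rows = []
    confusions: dict[tuple[str, str], np.ndarray] = {}
    for band, table in tables.items():
        y = table.labels
        splits = [split(y, protocol, r) for r in range(protocol.n_splits)]
        for spec in classifiers:
            conf_sum = np.zeros((n_classes, n_classes), dtype=np.int64)
            for r, (train, valid) in enumerate(splits):
                X_train, X_valid = table.values[train], table.values[valid]
                y_train, y_valid = y[train], y[valid]
                if use_lda:
                    sub = FeatureTable(
                        values=X_train,
                        labels=y_train,
                        feature_meta=table.feature_meta,
                        provenance=table.provenance,
                    )
                    model = fit_lda(sub, d=lda_dim, shrinkage=lda_shrinkage)
                    X_train = (X_train - model.global_mean) @ model.projection
                    X_valid = (X_valid - model.global_mean) @ model.projection
                clf = spec.build(_derived_seed(protocol.seed, r, 7))
                t0 = time.perf_counter()
                clf.fit(X_train, y_train)
                y_pred = clf.predict(X_valid)
                seconds = time.perf_counter() - t0
                m = compute_metrics(y_valid, y_pred, n_classes)
                conf_sum += confusion_matrix(y_valid, y_pred, labels=np.arange(n_classes))
                rows.append(
                    {
                        "condition": condition,
                        "band": band,
                        "classifier": spec.name,
                        "repeat": r,
                        "n_train": int(train.size),
                        "n_valid": int(valid.size),
                        "seconds": seconds,
                        **m,
                    }
                )
            confusions[(band, spec.name)] = conf_sum
    records = pd.DataFrame(rows)
    return EvalReport(
        condition=condition, n_classes=n_classes, records=records, confusions=confusions
    )


def export_report(report: EvalReport, out_dir, *, plots: bool = False) -> list:
    """Write aggregate metrics, per-split long table, confusion matrices and
    (optionally) box-plot / confusion-matrix images; returns written paths."""
    from pathlib import Path

    if report.records.empty:
        raise ValueError("cannot export an empty report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    # timing is written separately: wall-clock is hardware noise, and keeping
    # it out of the metric tables lets identical re-runs be byte-identical
    agg = report.aggregate(include_timing=False)
    p = out_dir / f"metrics_{report.condition}.tsv"
    agg.to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)

    # full precision so aggregates re-derived from this file match exactly
    long = report.records.sort_values(["band", "classifier", "repeat"], kind="stable")
    p = out_dir / f"per_split_{report.condition}.tsv"
    long.drop(columns=["seconds"]).to_csv(p, sep="\t", index=False, float_format="%.17g")
    written.append(p)

    timing = long[["condition", "band", "classifier", "repeat", "seconds"]]
    p = out_dir / f"timing_{report.condition}.tsv"
    timing.to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)

    for (band, clf) in sorted(report.confusions):
        conf = report.confusions[(band, clf)]
        p = out_dir / f"confusion_{report.condition}_{band}_{clf}.tsv"
        pd.DataFrame(conf).to_csv(p, sep="\t", index=False, header=False)
        written.append(p)

    if plots:
        written.extend(_render_plots(report, out_dir))
    return written


def _render_plots(report: EvalReport, out_dir) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for band, sub in report.records.groupby("band"):
        fig, ax = plt.subplots(figsize=(6, 4))
        names = sorted(sub["classifier"].unique())
        ax.boxplot(
            [sub.loc[sub["classifier"] == n, "accuracy"] for n in names],
            tick_labels=names,
        )
        ax.set_ylabel("validation accuracy")
        ax.set_title(f"{report.condition} / {band}")
        p = out_dir / f"accuracy_boxplot_{report.condition}_{band}.png"
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    for (band, clf), conf in sorted(report.confusions.items()):
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(conf, cmap="Blues")
        for i in range(conf.shape[0]):
            for j in range(conf.shape[1]):
                ax.text(j, i, str(conf[i, j]), ha="center", va="center", fontsize=8)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"{report.condition} / {band} / {clf}")
        fig.colorbar(im, shrink=0.8)
        p = out_dir / f"confusion_{report.condition}_{band}_{clf}.png"
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
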