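"""Multi-class Fisher linear discriminant analysis via scatter matrices.

With class means mu_j, global mean mu and class sizes N_j, the within- and
between-class scatter matrices are

    Sw = sum_j sum_{x in X_j} (x - mu_j)(x - mu_j)^T
    Sb = sum_j N_j (mu_j - mu)(mu_j - mu)^T

and the total scatter about the global mean satisfies St = Sw + Sb. The
Fisher objective J(W) = prod_i (w_i^T Sb w_i) / (w_i^T Sw w_i) is maximized
by the top eigenvectors of the generalized eigenproblem Sb w = lambda Sw w;
at most K - 1 directions carry between-class information (rank(Sb) <= K-1).

Since Sw can be ill-conditioned when features outnumber training samples,
a scaled ridge gamma * (trace(Sw)/n) * I is added to Sw before solving
(default gamma = 1e-6).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .data import FeatureColumn, FeatureTable


@dataclass
class LDAModel:
    """Fitted Fisher discriminant projection.

    ``projection`` is n x d with unit-norm columns ordered by decreasing
    Fisher quotient; ``eigenvalues`` holds the achieved per-direction
    Rayleigh quotients w^T Sb w / w^T Sw w.
    """

    class_means: np.ndarray          # K x n
    global_mean: np.ndarray          # n
    class_counts: np.ndarray         # K
    class_labels: np.ndarray         # K (original label codes, ascending)
    within_scatter: np.ndarray       # n x n
    between_scatter: np.ndarray      # n x n
    projection: np.ndarray           # n x d
    eigenvalues: np.ndarray          # d, descending
    shrinkage: float

    @property
    def n_features(self) -> int:
        return self.projection.shape[0]

    @property
    def n_components(self) -> int:
        return self.projection.shape[1]

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "class_means": self.class_means.tolist(),
            "global_mean": self.global_mean.tolist(),
            "class_counts": self.class_counts.tolist(),
            "class_labels": self.class_labels.tolist(),
            "projection": self.projection.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "shrinkage": self.shrinkage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "LDAModel":
        with open(path) as fh:
            p = json.load(fh)
        means = np.asarray(p["class_means"], dtype=np.float64)
        X = np.asarray(p["projection"], dtype=np.float64)
        counts = np.asarray(p["class_counts"], dtype=np.int64)
        # scatter matrices are derivable from the training data, not stored
        n = X.shape[0]
        return cls(
            class_means=means,
            global_mean=np.asarray(p["global_mean"], dtype=np.float64),
            class_counts=counts,
            class_labels=np.asarray(p["class_labels"], dtype=np.int64),
            within_scatter=np.full((n, n), np.nan),
            between_scatter=np.full((n, n), np.nan),
            projection=X,
            eigenvalues=np.asarray(p["eigenvalues"], dtype=np.float64),
            shrinkage=float(p["shrinkage"]),
        )


def _class_stats(X: np.ndarray, y: np.ndarray):
    labels = np.unique(y)
    if labels.size < 2:
        raise ValueError(f"need at least 2 classes, got {labels.size}")
    means = np.vstack([X[y == c].mean(axis=0) for c in labels])
    counts = np.array([int(np.sum(y == c)) for c in labels])
    return labels, means, counts


def scatter_matrices(table: FeatureTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Sw, Sb, St) of a feature table; St = Sw + Sb holds to ~1e-8 relative."""
    X = np.asarray(table.values, dtype=np.float64)
    y = table.labels
    if X.shape[0] == 0:
        raise ValueError("empty feature table")
    labels, means, counts = _class_stats(X, y)
    n = X.shape[1]
    Sw = np.zeros((n, n))
    for c, mu_j in zip(labels, means):
        Xc = X[y == c] - mu_j
        Sw += Xc.T @ Xc
    mu = X.mean(axis=0)
    D = means - mu
    Sb = (D.T * counts) @ D
    Xt = X - mu
    St = Xt.T @ Xt
    return Sw, Sb, St


def fit_lda(
    table: FeatureTable,
    d: int | None = None,
    shrinkage: float = 1e-6,
) -> LDAModel:
    """Fit the Fisher projection maximizing between/within scatter.

    d defaults to K - 1 (the maximal informative rank); d > K - 1 is an
    error. Eigenvectors are unit-normalized with the sign fixed so each
    column's largest-magnitude entry is positive, and equal eigenvalues are
    ordered by that entry's index, for bit-reproducibility.
    """
    X = np.asarray(table.values, dtype=np.float64)
    y = table.labels
    labels, means, counts = _class_stats(X, y)
    K = labels.size
    if d is None:
        d = K - 1
    if not 1 <= d <= K - 1:
        raise ValueError(
            f"d={d} is invalid: at most K - 1 = {K - 1} discriminant "
            f"directions carry between-class information for K={K} classes"
        )
    Sw, Sb, _ = scatter_matrices(table)
    n = X.shape[1]
    if shrinkage < 0:
        raise ValueError("shrinkage must be non-negative")
    scale = np.trace(Sw) / n if np.trace(Sw) > 0 else 1.0
    Sw_reg = Sw + shrinkage * scale * np.eye(n)
    if shrinkage == 0:
        try:
            linalg.cholesky(Sw_reg)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "within-class scatter is singular; refit with shrinkage > 0"
            ) from exc
    # generalized symmetric eigenproblem Sb w = lambda (Sw + ridge) w
    eigvals, eigvecs = linalg.eigh(Sb, Sw_reg)
    order = np.argsort(eigvals)[::-1][:d]
    W = eigvecs[:, order]
    # unit columns, deterministic sign, stable order among ties
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    peak = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[peak, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    W = W * signs
    lam = eigvals[order]
    tie_groups: list[np.ndarray] = []
    i = 0
    while i < d:
        j = i
        while j + 1 < d and abs(lam[j + 1] - lam[i]) <= 1e-12 * max(1.0, abs(lam[i])):
            j += 1
        tie_groups.append(np.arange(i, j + 1))
        i = j + 1
    for g in tie_groups:
        if g.size > 1:
            sub = W[:, g]
            reorder = np.argsort(np.argmax(np.abs(sub), axis=0), kind="stable")
            W[:, g] = sub[:, reorder]

    # achieved Rayleigh quotients on the *unregularized* scatter
    quots = []
    for k in range(d):
        w = W[:, k]
        denom = float(w @ Sw @ w)
        if denom <= 0:
            denom = float(w @ Sw_reg @ w)
        quots.append(float(w @ Sb @ w) / denom)
    return LDAModel(
        class_means=means,
        global_mean=X.mean(axis=0),
        class_counts=counts,
        class_labels=labels,
        within_scatter=Sw,
        between_scatter=Sb,
        projection=W,
        eigenvalues=np.asarray(quots),
        shrinkage=shrinkage,
    )


def fisher_objective(W: np.ndarray, Sw: np.ndarray, Sb: np.ndarray) -> float:
    """J(W) = prod_i (w_i^T Sb w_i)/(w_i^T Sw w_i) over the columns of W."""
    J = 1.0
    for k in range(W.shape[1]):
        w = W[:, k]
        J *= float(w @ Sb @ w) / float(w @ Sw @ w)
    return J


def transform(model: LDAModel, table: FeatureTable) -> FeatureTable:
    """Project a table onto the fitted directions (no re-estimation).

    Rows are centered by the *training* global mean and multiplied by the
    projection, so applying a model to held-out data leaks nothing.
    """
    X = np.asarray(table.values, dtype=np.float64)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"table has {X.shape[1]} features but the model expects {model.n_features}"
        )
    Z = (X - model.global_mean) @ model.projection
    meta = [
        FeatureColumn(channel_name=f"comp{k + 1}", band_name="lda", feature_kind="lda_component")
        for k in range(model.n_components)
    ]
    return FeatureTable(
        values=Z,
        labels=table.labels,
        feature_meta=meta,
        provenance=f"lda(d={model.n_components},gamma={model.shrinkage})<-{table.provenance}",
    )
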