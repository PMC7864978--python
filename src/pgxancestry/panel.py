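"""Genetic-ancestry prediction panel.

Markers (AIM dosages, AIG gene intensities) are selected greedily under a
flexible discriminant analysis (FDA) classifier inside stratified k-fold
cross-validation: on each training split, features are added one at a time
by maximal training-accuracy increment — ties broken by the smallest
within-class / between-class sum-of-squares ratio of the candidate's raw
values — until training accuracy reaches 1.0 or the increment falls below a
minimum; the fold whose model classifies its held-out subset best supplies
the final panel.

The FDA here uses the optimal-scoring formulation with a linear basis, so
its decision rule coincides with classical linear discriminant analysis:
class indicators are ridge-regressed on the features, the between-class
structure of the fits is eigen-decomposed into discriminant directions, and
samples are assigned to the nearest class centroid under the pooled
within-class metric with log-prior correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PanelConfig",
    "FDAModel",
    "CVReport",
    "PanelModel",
    "stratified_folds",
    "fda_fit",
    "fda_predict",
    "forward_select",
    "build_panel",
]


@dataclass(frozen=True)
class PanelConfig:
    k_folds: int = 10
    seed: int = 0
    target_accuracy: float = 1.0
    min_increment: float = 0.001
    max_panel_size: int = 60
    ridge: float = 1e-8

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.min_increment <= 0:
            raise ValueError("min_increment must be > 0")


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Per-class round-robin fold assignment after a seeded shuffle.

    Fold sizes within each class differ by at most one; classes smaller than
    k simply appear in fewer folds.  Deterministic under (labels, k, seed).
    """
    y = np.asarray(labels)
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.intp)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


@dataclass
class FDAModel:
    classes: np.ndarray
    feature_mean: np.ndarray
    directions: np.ndarray      # (p, K) discriminant directions
    centroids: np.ndarray       # (J, K) class means in discriminant space
    within_inv: np.ndarray      # (K, K) inverse pooled within-class covariance
    log_priors: np.ndarray


def _fda_core(G, h, Xc, y_idx, n_classes, counts, ridge):
    """Fit FDA from precomputed Gram pieces.

    G = Xc'Xc (p,p); h = Xc'Y (p,J); Xc centered features (n,p); y_idx class
    indices; counts per-class sizes.  Returns (directions, centroids,
    within_inv, log_priors).
    """
    p = G.shape[0]
    n = Xc.shape[0]
    A = G + ridge * np.eye(p) * max(1.0, np.trace(G) / max(p, 1))
    B = np.linalg.solve(A, h)                       # (p, J)
    S = h.T @ B                                     # Y'Xc B, symmetric PSD (J, J)
    d = np.sqrt(counts.astype(float))
    Sym = S / d[:, None] / d[None, :]               # D^-1/2 S D^-1/2
    evals, evecs = np.linalg.eigh(Sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    K = min(n_classes - 1, p)
    keep = np.flatnonzero(evals > max(evals[0], 0) * 1e-10 + 1e-300)[:K]
    if keep.size == 0:
        keep = np.array([0])
    theta = evecs[:, keep] / d[:, None]             # optimal scores
    V = B @ theta                                   # (p, K) directions
    Z = Xc @ V                                      # discriminant coordinates
    centroids = np.stack([Z[y_idx == j].mean(axis=0) for j in range(n_classes)])
    resid = Z - centroids[y_idx]
    dof = max(n - n_classes, 1)
    W = resid.T @ resid / dof
    W += np.eye(W.shape[0]) * (np.trace(W) / max(W.shape[0], 1) + 1.0) * 1e-10
    within_inv = np.linalg.inv(W)
    log_priors = np.log(counts / counts.sum())
    return V, centroids, within_inv, log_priors


def fda_fit(X, labels, ridge: float = 1e-8) -> FDAModel:
    """Fit flexible discriminant analysis with a linear basis (= LDA rule)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes in training data")
    counts = np.bincount(y_idx, minlength=classes.size)
    mean = X.mean(axis=0)
    Xc = X - mean
    Y = np.eye(classes.size)[y_idx]
    G = Xc.T @ Xc
    h = Xc.T @ Y
    V, centroids, within_inv, log_priors = _fda_core(
        G, h, Xc, y_idx, classes.size, counts, ridge
    )
    return FDAModel(
        classes=classes,
        feature_mean=mean,
        directions=V,
        centroids=centroids,
        within_inv=within_inv,
        log_priors=log_priors,
    )


def fda_predict(model: FDAModel, X) -> np.ndarray:
    """Nearest-centroid classification in the whitened discriminant space."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Z = (X - model.feature_mean) @ model.directions
    diff = Z[:, None, :] - model.centroids[None, :, :]    # (n, J, K)
    maha = np.einsum("njk,kl,njl->nj", diff, model.within_inv, diff)
    score = maha - 2.0 * model.log_priors[None, :]
    return model.classes[np.argmin(score, axis=1)]


def _ss_ratio(X, y_idx, n_classes) -> np.ndarray:
    """Within-class / between-class sum of squares per feature (tie-break)."""
    n = X.shape[0]
    grand = X.mean(axis=0)
    ssw = np.zeros(X.shape[1])
    ssb = np.zeros(X.shape[1])
    for j in range(n_classes):
        sub = X[y_idx == j]
        if len(sub) == 0:
            continue
        m = sub.mean(axis=0)
        ssw += ((sub - m) ** 2).sum(axis=0)
        ssb += len(sub) * (m - grand) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ssw / ssb
    return np.where(ssb > 0, ratio, np.inf)


def forward_select(
    X,
    labels,
    config: PanelConfig = PanelConfig(),
    feature_ids: list | None = None,
) -> tuple[list[int], list[float]]:
    """Greedy forward selection of features under the FDA classifier.

    At every step each remaining candidate is evaluated by refitting the
    model on current set + candidate and scoring training accuracy; the
    maximal-accuracy candidate wins, with exact ties resolved by minimum
    within/between sum-of-squares ratio of the candidate's raw values, then
    by feature index.  Stops at training accuracy >= target, increment <
    min_increment, or max_panel_size.  Returns (selected indices, accuracy
    trace); deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    J = classes.size
    counts = np.bincount(y_idx, minlength=J)
    n, p = X.shape
    if p == 0:
        raise ValueError("no candidate features")
    mean = X.mean(axis=0)
    Xc = X - mean
    Y = np.eye(J)[y_idx]
    G_full = Xc.T @ Xc
    h_full = Xc.T @ Y
    ratio = _ss_ratio(X, y_idx, J)

    def acc_of(subset: list[int]) -> float:
        S = np.asarray(subset, dtype=np.intp)
        V, centroids, within_inv, log_priors = _fda_core(
            G_full[np.ix_(S, S)], h_full[S], Xc[:, S], y_idx, J, counts, config.ridge
        )
        Z = Xc[:, S] @ V
        diff = Z[:, None, :] - centroids[None, :, :]
        maha = np.einsum("njk,kl,njl->nj", diff, within_inv, diff)
        pred = np.argmin(maha - 2.0 * log_priors[None, :], axis=1)
        return float(np.mean(pred == y_idx))

    selected: list[int] = []
    trace: list[float] = []
    current = 0.0
    remaining = list(range(p))
    while remaining and len(selected) < config.max_panel_size:
        best_acc = -1.0
        best_j = None
        for j in remaining:
            a = acc_of(selected + [j])
            better = a > best_acc + 1e-12
            tie = abs(a - best_acc) <= 1e-12
            if better or (
                tie
                and (
                    ratio[j] < ratio[best_j] - 1e-12
                    or (abs(ratio[j] - ratio[best_j]) <= 1e-12 and j < best_j)
                )
            ):
                best_acc, best_j = a, j
        increment = best_acc - current
        if selected and increment < config.min_increment:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        trace.append(best_acc)
        current = best_acc
        if current >= config.target_accuracy:
            break
    return selected, trace


@dataclass
class PanelModel:
    feature_indices: list[int]
    feature_ids: list
    model: FDAModel
    fold: int
    training_accuracy: float
    testing_accuracy: float


@dataclass
class CVReport:
    fold_selections: list[list[int]]
    fold_traces: list[list[float]]
    fold_testing_accuracy: list[float]
    chosen_fold: int
    marker_impact: pd.DataFrame      # feature, rank, accuracy increment (chosen fold)
    selection_counts: pd.DataFrame   # feature, folds selected in

    @property
    def consistently_selected(self) -> list:
        k = len(self.fold_selections)
        df = self.selection_counts
        return df.loc[df["n_folds"] == k, "feature"].tolist()


def build_panel(
    X,
    labels,
    config: PanelConfig = PanelConfig(),
    feature_ids: list | None = None,
) -> tuple[PanelModel, CVReport]:
    """Forward-select a panel on each CV training split; keep the best.

    Each of the k stratified folds serves once as the testing subset; the
    candidate model trained on the other k-1 folds is scored on it, and the
    model with the highest testing accuracy (ties: lowest fold index) is the
    final panel.  Marker impact = per-feature training-accuracy increment in
    the chosen fold's selection trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    n, p = X.shape
    ids = list(feature_ids) if feature_ids is not None else list(range(p))
    folds = stratified_folds(y, config.k_folds, config.seed)

    selections, traces, test_accs = [], [], []
    for f in range(config.k_folds):
        train = folds != f
        test = ~train
        sel, trace = forward_select(X[train], y[train], config)
        model = fda_fit(X[train][:, sel], y[train], ridge=config.ridge)
        pred = fda_predict(model, X[test][:, sel])
        test_accs.append(float(np.mean(pred == y[test])))
        selections.append(sel)
        traces.append(trace)
    chosen = int(np.argmax(test_accs))  # argmax takes first maximum
    sel = selections[chosen]
    train = folds != chosen
    model = fda_fit(X[train][:, sel], y[train], ridge=config.ridge)

    increments = np.diff([0.0] + traces[chosen])
    impact = pd.DataFrame(
        {
            "feature": [ids[j] for j in sel],
            "rank": np.arange(1, len(sel) + 1),
            "impact": increments,
        }
    )
    count: dict = {}
    for s in selections:
        for j in s:
            count[ids[j]] = count.get(ids[j], 0) + 1
    sel_counts = pd.DataFrame(
        sorted(count.items(), key=lambda kv: (-kv[1], str(kv[0]))),
        columns=["feature", "n_folds"],
    )
    pm = PanelModel(
        feature_indices=sel,
        feature_ids=[ids[j] for j in sel],
        model=model,
        fold=chosen,
        training_accuracy=traces[chosen][-1] if traces[chosen] else float("nan"),
        testing_accuracy=test_accs[chosen],
    )
    report = CVReport(
        fold_selections=selections,
        fold_traces=traces,
        fold_testing_accuracy=test_accs,
        chosen_fold=chosen,
        marker_impact=impact,
        selection_counts=sel_counts,
    )
    return pm, report
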