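"""Group classification from FC features with embedded NCA feature
selection inside nested leave-one-out cross-validation.

The outer leave-one-out loop measures generalization: for each held-out
subject, everything learnable — feature standardization statistics, NCA
feature weights, the regularization strength, and the margin classifier —
is fit strictly on the remaining subjects.  The inner step is
neighborhood component analysis with a diagonal (per-feature) metric:
weights w are learned by maximizing the expected leave-one-out soft
classification accuracy under stochastic nearest-neighbor assignment with
distance d_w(i,j) = sum_r w_r^2 |x_ir - x_jr|, penalized by
lambda * sum w_r^2.  Features whose learned weight exceeds a fraction tau
of the largest weight are kept and passed to a linear-kernel SVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .consistency import NetworkPartition
from .errors import ContractError
from .measures import (
    MEASURE_ORDER,
    MeasureParams,
    composite,
    pairwise_fc,
    vectorize_upper,
)

__all__ = [
    "CohortDataset",
    "ClassificationResult",
    "NCAParams",
    "nca_weights",
    "nca_select",
    "nested_loo_classify",
    "build_feature_table",
    "classify_networks",
]


@dataclass(frozen=True)
class CohortDataset:
    """Feature table for classification: subjects x p features, binary
    group labels, optional behavior scores."""

    subjects: tuple
    features: np.ndarray
    labels: np.ndarray
    behavior: np.ndarray | None = None

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if feats.ndim != 2 or feats.shape[0] != len(self.subjects):
            raise ContractError("features must be subjects x p")
        if not np.all(np.isfinite(feats)):
            raise ContractError("features contain missing/non-finite cells")
        if labels.shape != (len(self.subjects),):
            raise ContractError("labels length mismatch")
        if len(np.unique(labels)) != 2:
            raise ContractError("labels must contain exactly two classes")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class ClassificationResult:
    accuracy: float  # percent of left-out subjects labeled correctly
    auc: float
    selected_feature_counts: tuple
    seed: int
    predictions: tuple = ()
    decision_scores: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 100.0):
            raise ContractError("accuracy must be a percentage")
        if not (0.0 <= self.auc <= 1.0):
            raise ContractError("auc must be in [0, 1]")


@dataclass(frozen=True)
class NCAParams:
    """NCA feature-selection settings.

    ``lambda_grid`` entries are divided by the training-fold size; the
    value maximizing inner leave-one-out 1-NN accuracy (weighted distance)
    is kept.  ``tau`` is the selection threshold as a fraction of the
    maximum learned weight.
    """

    lambda_grid: tuple = (0.25, 0.5, 1.0, 2.0)
    tau: float = 0.01
    max_iter: int = 60


def _standardize_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def nca_weights(
    X: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 60
) -> np.ndarray:
    """Learn per-feature NCA weights (returned as w_r^2 >= 0).

    Maximizes (1/N) sum_i p_i - lam * sum_r w_r^2 where p_i is the
    probability that a stochastic neighbor of i (softmax over the weighted
    cityblock distances) shares i's class.  L-BFGS on w from w = 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ContractError("nca needs both classes in the training fold")
    # |x_ir - x_jr| tensor, shape (n, n, p)
    dabs = np.abs(X[:, None, :] - X[None, :, :])
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    eye = np.eye(n, dtype=bool)

    def neg_obj_grad(w):
        w2 = w * w
        d = dabs @ w2  # (n, n)
        d[eye] = np.inf
        d_shift = d - d.min(axis=1, keepdims=True)
        k = np.exp(-d_shift)
        k[eye] = 0.0
        denom = k.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        prob = k / denom
        pi = (prob * same).sum(axis=1)
        f = pi.mean() - lam * w2.sum()
        # gradient of f wrt w
        t1 = np.einsum("i,ij,ijr->r", pi, prob, dabs)
        t2 = np.einsum("ij,ijr->r", prob * same, dabs)
        grad = 2.0 * w * ((t1 - t2) / n - lam)
        return -f, -grad

    res = minimize(
        neg_obj_grad,
        x0=np.ones(p),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    return res.x**2


def _weighted_1nn_loo_accuracy(X, y, weights) -> float:
    """Leave-one-out 1-NN accuracy under the weighted cityblock distance;
    deterministic (first minimum wins)."""
    n = X.shape[0]
    d = np.abs(X[:, None, :] - X[None, :, :]) @ weights
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    return float(np.mean(y[nn] == y))


def nca_select(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    params: NCAParams | None = None,
) -> tuple:
    """Select feature indices by NCA weight on (already standardized)
    training data.

    Regularization is chosen from ``params.lambda_grid / n_train`` by inner
    leave-one-out 1-NN accuracy (ties -> smaller lambda).  Indices with
    weight > tau * max_weight are returned; if that set would be empty the
    single top-weight feature is kept.  Returns ``(indices, weights)``.
    """
    params = params or NCAParams()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    counts = np.unique(y, return_counts=True)[1]
    if len(counts) < 2 or counts.min() < 2:
        raise ContractError("need >= 2 subjects per class in the training fold")
    n = X.shape[0]
    best = None
    for lam_scale in params.lambda_grid:
        lam = lam_scale / n
        w = nca_weights(X, y, lam, params.max_iter)
        acc = _weighted_1nn_loo_accuracy(X, y, w)
        if best is None or acc > best[0] + 1e-12:
            best = (acc, lam_scale, w)
    weights = best[2]
    wmax = weights.max()
    if wmax <= 0:
        idx = np.array([0])
    else:
        idx = np.flatnonzero(weights > params.tau * wmax)
        if idx.size == 0:
            idx = np.array([int(np.argmax(weights))])
    return idx, weights


def nested_loo_classify(
    dataset: CohortDataset,
    params: NCAParams | None = None,
    seed: int = 0,
) -> ClassificationResult:
    """Nested leave-one-out classification with embedded NCA selection.

    For each held-out subject: standardize features by training-fold
    statistics, run NCA selection on the training fold, fit a linear-kernel
    SVM (C = 1) on the selected features, and predict the held-out subject.
    Accuracy is the percent of correct outer predictions; AUC is computed
    from the pooled signed decision values.  Deterministic given
    (dataset, params, seed).
    """
    params = params or NCAParams()
    X = dataset.features
    y = dataset.labels
    n = X.shape[0]
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ContractError("need >= 3 subjects per class for nested LOO")
    pos = classes[1]  # positive class: second in sorted order
    preds, scores, sel_counts = [], [], []
    for s in range(n):
        train = np.ones(n, dtype=bool)
        train[s] = False
        Xtr, ytr = X[train], y[train]
        mu, sd = _standardize_fit(Xtr)
        Xtr_z = (Xtr - mu) / sd
        xte_z = (X[s] - mu) / sd
        idx, _ = nca_select(Xtr_z, ytr, params)
        clf = SVC(kernel="linear", C=1.0, random_state=seed)
        clf.fit(Xtr_z[:, idx], ytr)
        score = float(clf.decision_function(xte_z[idx][None, :])[0])
        if score == 0.0:
            maj = classes[np.argmax([(ytr == c).sum() for c in classes])]
            warnings.warn("decision value exactly 0; assigning majority class",
                          stacklevel=2)
            pred = maj
        else:
            pred = clf.predict(xte_z[idx][None, :])[0]
        preds.append(pred)
        # orient the decision score toward the positive class
        if clf.classes_[1] != pos:
            score = -score
        scores.append(score)
        sel_counts.append(int(idx.size))
    preds = np.array(preds)
    accuracy = 100.0 * float(np.mean(preds == y))
    auc = float(roc_auc_score((y == pos).astype(int), scores))
    return ClassificationResult(
        accuracy=accuracy,
        auc=auc,
        selected_feature_counts=tuple(sel_counts),
        seed=seed,
        predictions=tuple(np.asarray(preds).tolist()),
        decision_scores=tuple(scores),
    )


def _network_bold(bold, members):
    """Column-subset of a BoldMatrix restricted to one network."""
    from .measures import BoldMatrix

    idx = [bold.region_ids.index(r) for r in members]
    return BoldMatrix(
        values=bold.values[:, idx],
        sampling_interval=bold.sampling_interval,
        region_ids=tuple(members),
    )


def build_feature_table(
    bolds,
    labels,
    members,
    measure: str,
    params: MeasureParams | None = None,
    behavior=None,
    subjects=None,
) -> CohortDataset:
    """Vectorized FC features for one network and measure (or the
    9-measure composite).

    Similarity measures contribute their absolute magnitudes; distances
    enter on their raw scale (fold-wise standardization inside the
    classifier handles the scale differences).
    """
    bolds = list(bolds)
    subjects = tuple(subjects or (f"sub-{i + 1:03d}" for i in range(len(bolds))))
    rows = []
    for bold in bolds:
        nb = _network_bold(bold, members)
        if measure == "composite":
            vecs = [vectorize_upper(pairwise_fc(nb, m, params)) for m in MEASURE_ORDER]
            row = composite(vecs)
            # similarity blocks as magnitudes
            block = vecs[0].values.size
            for bi, m in enumerate(MEASURE_ORDER):
                if m in ("corr", "xcorr"):
                    row[bi * block:(bi + 1) * block] = np.abs(
                        row[bi * block:(bi + 1) * block]
                    )
        else:
            vec = vectorize_upper(pairwise_fc(nb, measure, params)).values
            row = np.abs(vec) if measure in ("corr", "xcorr") else vec
        rows.append(row)
    return CohortDataset(
        subjects=subjects,
        features=np.vstack(rows),
        labels=np.asarray(labels),
        behavior=None if behavior is None else np.asarray(behavior, dtype=float),
    )


def classify_networks(
    bolds,
    labels,
    partition: NetworkPartition,
    measures=None,
    params: MeasureParams | None = None,
    nca_params: NCAParams | None = None,
    seed: int = 0,
):
    """Per-network x per-measure nested-LOO classification table.

    ``measures`` defaults to the nine single measures plus "composite".
    Networks with fewer than 2 regions are skipped with a warning.
    Returns a pandas DataFrame with accuracy, AUC and mean selected-feature
    count per cell.
    """
    import pandas as pd

    measures = list(measures or (list(MEASURE_ORDER) + ["composite"]))
    rows = []
    for network in partition.network_order:
        members = partition.members(network)
        if len(members) < 2:
            warnings.warn(f"network {network!r} has < 2 regions; skipped",
                          stacklevel=2)
            continue
        for measure in measures:
            ds = build_feature_table(bolds, labels, members, measure, params)
            res = nested_loo_classify(ds, nca_params, seed=seed)
            rows.append(
                {
                    "network": network,
                    "measure": measure,
                    "accuracy": res.accuracy,
                    "auc": res.auc,
                    "mean_selected": float(np.mean(res.selected_feature_counts)),
                }
            )
    return pd.DataFrame(rows)
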