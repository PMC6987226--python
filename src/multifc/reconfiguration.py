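"""Alternative brain configurations via shuffled clustering, and
brain-behavior stepwise regression.

The a-priori ("original") configuration assigns the 68 regions to 10
canonical networks.  An alternative reconfiguration re-derives the grouping
from one FC measure's group-mean matrix: the matrix is symmetrically
shuffled (rows and columns jointly permuted, to decouple the clustering
initialization from the a-priori ordering), the region connectivity
profiles are clustered with an L1-objective k-means (k-medians, k = 10),
and the clustered configuration is scored by the Dice overlap between the
thresholded group matrix and the idealized block pattern induced by the
clusters.  Repeating over many shuffles (1000 in the full protocol) and
keeping the argmax yields the best alternative reconfiguration, which is
then validated by regressing behavior on within-cluster mean FC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .consistency import (
    BinaryFCMask,
    NetworkPartition,
    binarize,
    dice,
    idealized_mask,
    pooled_threshold,
)
from .errors import ContractError, DegenerateInputError
from .measures import FCMatrix


@dataclass(frozen=True)
class ReconfigResult:
    """Outcome of a reconfiguration search."""

    best_partition: NetworkPartition
    best_dice: float
    dice_distribution: tuple
    original_dice: float
    best_restart: int
    restart_seeds: tuple
    threshold: float

    def __post_init__(self):
        if self.dice_distribution and not np.isclose(
            self.best_dice, max(self.dice_distribution)
        ):
            raise ContractError("best_dice must equal max(dice_distribution)")


@dataclass(frozen=True)
class RegressionSummary:
    """Final stepwise-selected OLS fit."""

    terms: tuple
    coefficients: dict
    r_squared: float
    adj_r_squared: float
    p_value: float
    n_obs: int

    def __post_init__(self):
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise ContractError("R^2 out of range")


# ---------------------------------------------------------------------------
# Shuffling and clustering
# ---------------------------------------------------------------------------


def shuffle_symmetric(fc: FCMatrix, seed: int):
    """Apply one uniform random permutation jointly to rows and columns.

    Preserves symmetry and the off-diagonal value multiset.  Returns the
    shuffled matrix and the permutation ``perm`` with
    ``shuffled[i, j] = original[perm[i], perm[j]]``.
    """
    rng = np.random.default_rng(seed)
    n = fc.n_regions
    perm = rng.permutation(n)
    vals = fc.values[np.ix_(perm, perm)]
    ids = tuple(fc.region_ids[p] for p in perm)
    shuffled = FCMatrix(
        values=vals,
        measure=fc.measure,
        polarity=fc.polarity,
        region_ids=ids,
        meta={**fc.meta, "permutation": tuple(int(p) for p in perm)},
    )
    return shuffled, perm


def _kmedians_labels(X: np.ndarray, k: int, seed: int, max_iter: int = 300):
    """L1 k-means (k-medians): cityblock assignment, per-coordinate median
    centroids, empty clusters reseeded from the farthest point."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if k > n:
        raise ContractError(f"k={k} exceeds number of rows {n}")
    # k-means++-style seeding under the L1 distance: spreads the initial
    # centers across well-separated profiles, which single-run Lloyd needs
    first = int(rng.integers(n))
    centers = [X[first]]
    for _ in range(1, k):
        d = np.min(
            [np.abs(X - c).sum(axis=1) for c in centers], axis=0
        )
        total = d.sum()
        if total == 0:
            centers.append(X[int(rng.integers(n))])
            continue
        centers.append(X[int(rng.choice(n, p=d / total))])
    centers = np.array(centers)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d = np.abs(X[:, None, :] - centers[None, :, :]).sum(axis=2)
        new_labels = np.argmin(d, axis=1)
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(d[np.arange(n), new_labels]))
                centers[c] = X[far]
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centers[c] = np.median(X[labels == c], axis=0)
    return labels


def kmeans_partition(fc: FCMatrix, k: int, seed: int) -> NetworkPartition:
    """Cluster the n region connectivity profiles (matrix rows) into k
    clusters with the L1 distance; returns the induced partition with
    clusters labeled c01.. in first-appearance order."""
    if fc.polarity != "similarity":
        raise ContractError("kmeans_partition requires similarity polarity")
    labels = _kmedians_labels(fc.values, k, seed)
    assignment = {
        r: f"c{labels[i] + 1:02d}" for i, r in enumerate(fc.region_ids)
    }
    return NetworkPartition(fc.region_ids, assignment)


# ---------------------------------------------------------------------------
# Reconfiguration search
# ---------------------------------------------------------------------------


def configuration_dice(
    observed_mask: BinaryFCMask, partition: NetworkPartition
) -> float:
    """Dice overlap between an observed binary pattern and the idealized
    block pattern induced by a partition.  Both are expressed on the same
    region set, so the value is invariant to how cluster labels are
    named and to any simultaneous reordering."""
    ideal = idealized_mask(partition)
    if ideal.region_ids != observed_mask.region_ids:
        # align by region id
        order = [ideal.region_ids.index(r) for r in observed_mask.region_ids]
        ideal = BinaryFCMask(
            values=ideal.values[np.ix_(order, order)],
            region_ids=observed_mask.region_ids,
            provenance=ideal.provenance,
        )
    return dice(observed_mask, ideal)


def reconfiguration_search(
    group_fc: FCMatrix,
    original_partition: NetworkPartition,
    k: int = 10,
    restarts: int = 1000,
    seed: int = 0,
    threshold: float | None = None,
    include_original: bool = False,
) -> ReconfigResult:
    """Search for the best alternative reconfiguration of a group-mean FC
    matrix.

    Per restart: shuffle the matrix symmetrically, cluster the shuffled
    rows with L1 k-means, map the labels back through the permutation, and
    score the induced idealized pattern against the thresholded group
    matrix with Dice.  ``threshold`` defaults to mean + 1 SD of this
    matrix's off-diagonal values (pass the subject-pooled threshold when
    per-subject matrices are available).  ``include_original`` injects the
    a-priori partition as restart 0 (verification mode: the maximum then
    dominates it by construction).  Ties resolve to the lowest restart
    index.
    """
    if group_fc.polarity != "similarity":
        raise ContractError("reconfiguration_search requires similarity polarity")
    if threshold is None:
        threshold = pooled_threshold([group_fc])
    observed = binarize(group_fc, threshold)
    if observed.upper().sum() == 0:
        raise DegenerateInputError(
            "threshold leaves no connections; degenerate (constant?) matrix"
        )
    original_dice = configuration_dice(observed, original_partition)
    rng = np.random.default_rng(seed)
    restart_seeds = tuple(int(s) for s in rng.integers(0, 2**31 - 1, size=restarts))
    dices = []
    best = None
    for r, rseed in enumerate(restart_seeds):
        if include_original and r == 0:
            partition = original_partition
            d = original_dice
        else:
            shuffled, perm = shuffle_symmetric(group_fc, rseed)
            labels_shuf = _kmedians_labels(shuffled.values, k, rseed)
            labels = np.empty_like(labels_shuf)
            labels[perm] = labels_shuf
            assignment = {
                rid: f"c{labels[i] + 1:02d}"
                for i, rid in enumerate(group_fc.region_ids)
            }
            partition = NetworkPartition(group_fc.region_ids, assignment)
            d = configuration_dice(observed, partition)
        dices.append(d)
        if best is None or d > best[0]:
            best = (d, r, partition)
    return ReconfigResult(
        best_partition=best[2],
        best_dice=float(best[0]),
        dice_distribution=tuple(dices),
        original_dice=float(original_dice),
        best_restart=int(best[1]),
        restart_seeds=restart_seeds,
        threshold=float(threshold),
    )


def mean_within_cluster_fc(
    subject_fc: FCMatrix, partition: NetworkPartition
) -> np.ndarray:
    """Per-cluster mean of the within-cluster off-diagonal FC values, in
    partition cluster order.  Singleton clusters yield NaN (no within-
    cluster edge) and are excluded downstream with a warning."""
    if subject_fc.polarity != "similarity":
        raise ContractError("mean_within_cluster_fc requires similarity polarity")
    out = []
    n_singleton = 0
    region_index = {r: i for i, r in enumerate(subject_fc.region_ids)}
    for lab in partition.network_order:
        idx = [region_index[r] for r in partition.members(lab)]
        if len(idx) < 2:
            out.append(np.nan)
            n_singleton += 1
            continue
        sub = subject_fc.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        out.append(float(sub[iu].mean()))
    if n_singleton == len(out):
        raise ContractError("all clusters are singletons")
    if n_singleton:
        warnings.warn(f"{n_singleton} singleton cluster(s) yield NaN",
                      stacklevel=2)
    return np.array(out)


# ---------------------------------------------------------------------------
# Stepwise regression
# ---------------------------------------------------------------------------


def _design(features: np.ndarray, terms, term_columns) -> np.ndarray:
    cols = [np.ones(features.shape[0])]
    for t in terms:
        cols.append(term_columns[t])
    return np.column_stack(cols)


def _adj_r2(y, X) -> float:
    n, p = X.shape
    if n - p <= 0:
        return -np.inf
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        raise DegenerateInputError("constant outcome")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def stepwise_regress(
    features: np.ndarray,
    outcome: np.ndarray,
    allow_interactions: bool = False,
    feature_names=None,
    improvement: float = 1e-4,
    max_steps: int = 200,
) -> RegressionSummary:
    """Forward-backward stepwise OLS selection by adjusted R^2.

    Starts from all linear terms; at each step the single add or remove
    move that most improves adjusted R^2 is taken, if the improvement
    exceeds ``improvement``.  With ``allow_interactions`` all pairwise
    products are candidates, without any hierarchy requirement (an
    interaction may enter on its own).  Plain R^2 never decreases when a
    term enters, which would make "maximize R^2" degenerate as a stepwise
    criterion; the adjusted form is the operative reading.  Returns the
    final OLS fit summary (R^2, model F-test p-value, coefficients).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ContractError("features must be subjects x q, matching outcome")
    n, q = X.shape
    if np.ptp(y) == 0:
        raise ContractError("constant outcome")
    names = list(feature_names or (f"f{i + 1}" for i in range(q)))
    if len(names) != q:
        raise ContractError("feature_names length mismatch")
    term_columns = {names[i]: X[:, i] for i in range(q)}
    candidates = list(names)
    if allow_interactions:
        for i, j in itertools.combinations(range(q), 2):
            lab = f"{names[i]}:{names[j]}"
            term_columns[lab] = X[:, i] * X[:, j]
            candidates.append(lab)
    max_terms = max(1, n - 3)
    current = list(names[: min(q, max_terms)])
    score = _adj_r2(y, _design(X, current, term_columns))
    seen = {tuple(sorted(current))}
    for _ in range(max_steps):
        best_add = best_rm = None
        if len(current) < max_terms:
            for c in candidates:
                if c not in current:
                    s = _adj_r2(y, _design(X, current + [c], term_columns))
                    if best_add is None or s > best_add[0]:
                        best_add = (s, current + [c])
        for c in current:
            trial = [t for t in current if t != c]
            s = _adj_r2(y, _design(X, trial, term_columns))
            if best_rm is None or s > best_rm[0]:
                best_rm = (s, trial)
        # an addition must strictly improve the fit; a removal is also taken
        # when it is free (adjusted R^2 unchanged within the threshold),
        # which prunes redundant terms from saturated fits
        move = None
        if best_add is not None and best_add[0] > score + improvement:
            move = best_add
        if best_rm is not None and best_rm[0] > score - improvement:
            if move is None or best_rm[0] >= move[0] - improvement:
                move = best_rm
        if move is None:
            break
        key = tuple(sorted(move[1]))
        if key in seen:
            break
        seen.add(key)
        score, current = move
    Xd = _design(X, current, term_columns)
    fit = sm.OLS(y, Xd).fit()
    r2 = float(fit.rsquared)
    if current:
        p_value = float(fit.f_pvalue)
        if not np.isfinite(p_value):
            # perfect fit: residual variance ~ 0
            p_value = 0.0 if fit.ssr <= 1e-12 * max(fit.centered_tss, 1.0) else 1.0
    else:
        p_value = 1.0
    coefs = {"intercept": float(fit.params[0])}
    for i, t in enumerate(current):
        coefs[t] = float(fit.params[i + 1])
    return RegressionSummary(
        terms=tuple(current),
        coefficients=coefs,
        r_squared=min(max(r2, 0.0), 1.0),
        adj_r_squared=float(fit.rsquared_adj) if current else 0.0,
        p_value=p_value,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# Brain-behavior comparison
# ---------------------------------------------------------------------------


def _subject_cluster_features(fc_by_subject, partition) -> np.ndarray:
    rows = [mean_within_cluster_fc(fc, partition) for fc in fc_by_subject]
    return np.vstack(rows)


def brain_behavior_compare(
    fc_by_measure: dict,
    behavior: np.ndarray,
    original_partition: NetworkPartition,
    alternative_partition: NetworkPartition,
    measures=None,
) -> pd.DataFrame:
    """Compare brain-behavior association strength between the original
    configuration and an alternative reconfiguration.

    ``fc_by_measure`` maps measure name -> per-subject similarity-scale
    FCMatrix list.  For each configuration and measure, behavior is
    regressed (stepwise) on each cluster's within-cluster mean FC; the
    cluster with the highest R^2 is recorded.  The per-measure best
    clusters then feed the composite run: the 9 best-cluster mean-FC
    features are standardized and stepwise-regressed with pairwise
    interactions.  Returns a long DataFrame with per-cluster rows and one
    composite row per configuration.
    """
    behavior = np.asarray(behavior, dtype=float).ravel()
    measures = list(measures or fc_by_measure.keys())
    rows = []
    for config_name, partition in (
        ("original", original_partition),
        ("alternative", alternative_partition),
    ):
        composite_cols = []
        for meas in measures:
            fc_list = fc_by_measure[meas]
            if len(fc_list) != behavior.size:
                raise ContractError("behavior must be present for all subjects")
            feats = _subject_cluster_features(fc_list, partition)
            best = None
            for ci, lab in enumerate(partition.network_order):
                col = feats[:, ci]
                if np.any(np.isnan(col)) or np.ptp(col) == 0:
                    continue
                summ = stepwise_regress(col[:, None], behavior,
                                        feature_names=[f"{meas}@{lab}"])
                rows.append(
                    {
                        "configuration": config_name,
                        "measure": meas,
                        "cluster": lab,
                        "r_squared": summ.r_squared,
                        "p_value": summ.p_value,
                        "terms": ";".join(summ.terms),
                    }
                )
                if best is None or summ.r_squared > best[0]:
                    best = (summ.r_squared, lab, col)
            if best is None:
                raise ContractError(
                    f"no usable cluster for measure {meas!r} in {config_name}"
                )
            composite_cols.append((meas, best[1], best[2]))
        comp = np.column_stack([c for _, _, c in composite_cols])
        mu = comp.mean(axis=0)
        sd = comp.std(axis=0, ddof=0)
        comp_z = (comp - mu) / np.where(sd > 0, sd, 1.0)
        summ = stepwise_regress(
            comp_z,
            behavior,
            allow_interactions=True,
            feature_names=[m for m, _, _ in composite_cols],
        )
        rows.append(
            {
                "configuration": config_name,
                "measure": "composite",
                "cluster": "+".join(f"{m}@{lab}" for m, lab, _ in composite_cols),
                "r_squared": summ.r_squared,
                "p_value": summ.p_value,
                "terms": ";".join(summ.terms),
            }
        )
    return pd.DataFrame(rows)


def improvement_percent(original: float, alternative: float) -> float:
    """Percent improvement of an alternative overlap relative to the
    original, rounded to two decimals: 100 * (alt - orig) / orig."""
    if original == 0:
        raise DegenerateInputError("original overlap is zero")
    return round(100.0 * (alternative - original) / original, 2)
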