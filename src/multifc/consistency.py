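"""Consistency of FC measures via binarized-pattern overlap.

Workflow: average subjects' similarity-scale FC matrices, threshold the mean
at one standard deviation above the grand mean of all subject values pooled
together, and compare the resulting binary connection pattern (a) between
task and resting-state conditions and (b) against an idealized block
pattern that is fully connected within each network and disconnected
between networks.  Overlap is the Sorensen-Dice coefficient
2|A&B| / (|A| + |B|) over upper-triangle edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateInputError
from .measures import FCMatrix, to_similarity


@dataclass(frozen=True)
class NetworkPartition:
    """Ordered assignment of regions to labeled networks (or clusters).

    ``network_order`` is the first-appearance order of the K labels;
    ``assignment`` maps every region to exactly one label.
    """

    region_ids: tuple
    assignment: dict

    def __post_init__(self):
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        object.__setattr__(self, "assignment", dict(self.assignment))
        if not self.region_ids:
            raise ContractError("partition needs at least one region")
        missing = [r for r in self.region_ids if r not in self.assignment]
        if missing:
            raise ContractError(f"regions missing from partition: {missing}")
        extra = [r for r in self.assignment if r not in self.region_ids]
        if extra:
            raise ContractError(f"partition assigns unknown regions: {extra}")

    @property
    def network_order(self) -> tuple:
        seen = []
        for r in self.region_ids:
            lab = self.assignment[r]
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    @property
    def n_networks(self) -> int:
        return len(self.network_order)

    def members(self, network) -> tuple:
        return tuple(r for r in self.region_ids if self.assignment[r] == network)

    def sizes(self) -> dict:
        return {k: len(self.members(k)) for k in self.network_order}

    def labels_array(self) -> np.ndarray:
        """Integer label per region, in region order, networks numbered by
        first appearance."""
        order = {k: i for i, k in enumerate(self.network_order)}
        return np.array([order[self.assignment[r]] for r in self.region_ids])

    def reordered_by_network(self) -> "NetworkPartition":
        """Same assignment with regions sorted so each network is a
        contiguous block (stable within networks)."""
        ordered = [r for k in self.network_order for r in self.members(k)]
        return NetworkPartition(tuple(ordered), self.assignment)


@dataclass(frozen=True)
class BinaryFCMask:
    """Symmetric 0/1 connection pattern with zero diagonal."""

    values: np.ndarray
    region_ids: tuple
    threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = np.asarray(self.values)
        if not np.all((vals == 0) | (vals == 1)):
            raise ContractError("mask entries must be 0 or 1")
        vals = vals.astype(np.int8)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        n = len(self.region_ids)
        if vals.shape != (n, n):
            raise ContractError("mask shape must match region_ids")
        if np.any(vals != vals.T):
            raise ContractError("mask must be symmetric")
        if np.any(np.diag(vals) != 0):
            raise ContractError("mask diagonal must be zero")

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.region_ids), k=1)
        return self.values[iu]


def group_mean_fc(matrices) -> FCMatrix:
    """Cell-wise arithmetic mean of subjects' FC matrices (same measure,
    same region order, similarity polarity)."""
    matrices = list(matrices)
    if not matrices:
        raise ContractError("no matrices to average")
    first = matrices[0]
    for m in matrices:
        if m.measure != first.measure:
            raise ContractError("mixed measures in group_mean_fc")
        if m.region_ids != first.region_ids:
            raise ContractError("mixed region orders in group_mean_fc")
        if m.polarity != "similarity":
            raise ContractError("group_mean_fc requires similarity polarity")
    mean = np.mean([m.values for m in matrices], axis=0)
    return FCMatrix(
        values=mean,
        measure=first.measure,
        polarity="similarity",
        region_ids=first.region_ids,
        meta={"n_subjects": len(matrices)},
    )


def pooled_threshold(matrices) -> float:
    """Mean + 1 population SD of all upper-triangle off-diagonal values
    pooled across subjects — "one standard deviation higher than the mean
    overall"."""
    pool = np.concatenate([np.asarray(m.off_diagonal_upper()) for m in matrices])
    if pool.size < 2:
        raise DegenerateInputError("need at least 2 pooled values")
    return float(pool.mean() + pool.std(ddof=0))


def binarize(mean_fc: FCMatrix, threshold: float) -> BinaryFCMask:
    """1 where the mean FC strictly exceeds the threshold; diagonal forced
    to 0.  Ties at the threshold stay 0."""
    if mean_fc.polarity != "similarity":
        raise ContractError("binarize requires similarity polarity")
    mask = (mean_fc.values > threshold).astype(np.int8)
    np.fill_diagonal(mask, 0)
    return BinaryFCMask(
        values=mask,
        region_ids=mean_fc.region_ids,
        threshold=threshold,
        provenance={"measure": mean_fc.measure, "rule": "mean+1sd, strict >"},
    )


def idealized_mask(partition: NetworkPartition) -> BinaryFCMask:
    """Idealized configuration: every within-network pair connected, every
    between-network pair disconnected.  Regions must be ordered so the
    blocks are contiguous for the matrix to look block-diagonal, but the
    mask itself only depends on the assignment."""
    labels = partition.labels_array()
    vals = (labels[:, None] == labels[None, :]).astype(np.int8)
    np.fill_diagonal(vals, 0)
    return BinaryFCMask(
        values=vals,
        region_ids=partition.region_ids,
        provenance={"kind": "idealized"},
    )


def dice(a: BinaryFCMask, b: BinaryFCMask) -> float:
    """Sorensen-Dice overlap 2|A&B| / (|A| + |B|) over upper-triangle
    edges.  Two empty masks are defined as perfectly overlapping (1.0),
    with a warning."""
    if a.region_ids != b.region_ids:
        raise ContractError("dice requires identical region sets and order")
    ua, ub = a.upper(), b.upper()
    denom = int(ua.sum()) + int(ub.sum())
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    return float(2.0 * int((ua & ub).sum()) / denom)


def _group_mask(fc_list, pooled_pool=None) -> BinaryFCMask:
    sims = []
    for m in fc_list:
        sims.append(to_similarity(m, pooled_values=pooled_pool))
    thr = pooled_threshold(sims)
    return binarize(group_mean_fc(sims), thr)


def group_binary_mask(matrices) -> BinaryFCMask:
    """Full E1-style pipeline for one condition and measure: convert every
    subject matrix to the similarity scale (distances rescaled with
    group-pooled min/max), average, and threshold at mean + 1 SD of the
    pooled values."""
    matrices = list(matrices)
    if not matrices:
        raise ContractError("no matrices")
    pool = None
    if matrices[0].polarity == "dissimilarity":
        pool = np.concatenate([m.off_diagonal_upper() for m in matrices])
    return _group_mask(matrices, pool)


def consistency_report(
    task_fc_by_subject: dict,
    rest_fc_by_subject: dict,
    partition: NetworkPartition,
    measures=None,
) -> pd.DataFrame:
    """Per-measure Dice overlaps: task-vs-rest and rest-vs-idealized.

    ``task_fc_by_subject`` / ``rest_fc_by_subject`` map measure name to the
    per-subject FCMatrix list for that condition; subjects must be matched
    (equal counts) across conditions.  Returns one row per measure and
    comparison.
    """
    measures = list(measures or task_fc_by_subject.keys())
    rows = []
    for meas in measures:
        if meas not in task_fc_by_subject or meas not in rest_fc_by_subject:
            raise ContractError(f"measure {meas!r} missing from a condition")
        task_list = list(task_fc_by_subject[meas])
        rest_list = list(rest_fc_by_subject[meas])
        if len(task_list) != len(rest_list):
            raise ContractError(
                f"subject mismatch for {meas!r}: "
                f"{len(task_list)} task vs {len(rest_list)} rest"
            )
        task_mask = group_binary_mask(task_list)
        rest_mask = group_binary_mask(rest_list)
        ideal = idealized_mask(partition)
        rows.append(
            {"measure": meas, "comparison": "task_vs_rest",
             "dice": dice(task_mask, rest_mask)}
        )
        rows.append(
            {"measure": meas, "comparison": "rest_vs_ideal",
             "dice": dice(rest_mask, ideal)}
        )
    return pd.DataFrame(rows, columns=["measure", "comparison", "dice"])
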