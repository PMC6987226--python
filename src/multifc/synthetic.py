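"""Synthetic BOLD cohorts with planted network structure.

The study data this package targets (resting-state fMRI, TR = 2.6 s,
~227-231 volumes, 68 regions in 10 canonical networks) are not publicly
deposited, so every pipeline is exercised on generated cohorts with known
ground truth instead.

The generative model is a latent-factor construction: each network k has a
band-limited (0.01-0.1 Hz) unit-variance latent signal u_k, and region i in
network k emits

    s_i = sqrt(w - b) * u_k + sqrt(b) * g + sqrt(1 - w) * e_i

with g a global band-limited component shared by all networks, e_i
independent band-limited noise, w the within-network dependence and
b < w the between-network dependence.  All three components have unit
variance, so the expected Pearson correlation is exactly w within a network
and b between networks — the planted parameter is directly recoverable,
which is what makes the pipeline tests sharp.  Non-linear measures (mutual
information, DTW, EMD) still see realistic band-limited trajectories rather
than white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consistency import NetworkPartition
from .errors import ConfigurationError, ContractError
from .measures import BoldMatrix, pearson

#: Ten networks summing to 68 regions, mirroring a whole-brain atlas scale.
DEFAULT_NETWORK_SIZES = (8, 8, 8, 7, 7, 7, 6, 6, 6, 5)

_MASK64 = (1 << 64) - 1


def mix_seed(master: int, index: int) -> int:
    """Derive a per-subject seed from (master, index) with a splitmix64
    step; stable across platforms, result < 2^31."""
    z = (int(master) + (index + 1) * 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    z ^= z >> 31
    return int(z & 0x7FFFFFFF)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-level generation parameters for one subject group."""

    network_sizes: tuple = DEFAULT_NETWORK_SIZES
    within_strength: float = 0.6
    between_strength: float = 0.0
    t: int = 227
    sampling_interval: float = 2.6
    band: tuple = (0.01, 0.1)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "network_sizes", tuple(self.network_sizes))
        if any(s < 1 for s in self.network_sizes):
            raise ContractError("network sizes must be positive")
        if not (0 <= self.between_strength < 1):
            raise ContractError("between_strength must be in [0, 1)")
        if self.within_strength > 0 and not (
            self.between_strength <= self.within_strength < 1
        ):
            raise ContractError("need between_strength <= within_strength < 1")
        if self.t < 8:
            raise ContractError("t must be >= 8")

    @property
    def n_regions(self) -> int:
        return sum(self.network_sizes)

    @property
    def network_labels(self) -> tuple:
        return tuple(f"net{k + 1:02d}" for k in range(len(self.network_sizes)))

    def region_ids(self) -> tuple:
        ids = []
        for k, size in enumerate(self.network_sizes):
            ids.extend(f"net{k + 1:02d}_r{i + 1:02d}" for i in range(size))
        return tuple(ids)

    def partition(self) -> NetworkPartition:
        assignment = {}
        for k, size in enumerate(self.network_sizes):
            for i in range(size):
                assignment[f"net{k + 1:02d}_r{i + 1:02d}"] = self.network_labels[k]
        return NetworkPartition(self.region_ids(), assignment)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level structure: two groups that differ in within-network
    dependence on ``effect_networks``, and a behavioral score linearly
    coupled to one network's mean FC."""

    n_group_a: int = 29
    n_group_b: int = 24
    effect_networks: tuple = ("net01",)
    effect_delta: float = 0.0
    behavior_network: str = "net02"
    behavior_intercept: float = 40.0
    behavior_slope: float = 20.0
    behavior_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "effect_networks", tuple(self.effect_networks))
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ContractError("each group needs at least 2 subjects")
        if self.behavior_noise_sd < 0:
            raise ContractError("behavior_noise_sd must be >= 0")


def _band_limited(rng: np.random.Generator, t: int, dt: float, band) -> np.ndarray:
    """White Gaussian noise hard-filtered to ``band`` in the frequency
    domain, then standardized to zero mean / unit variance."""
    lo, hi = band
    freqs = np.fft.rfftfreq(t, d=dt)
    keep = (freqs >= lo) & (freqs <= hi)
    if not np.any(keep):
        raise ConfigurationError(
            f"band {band} contains no achievable frequency at t={t}, dt={dt}"
        )
    spec = np.fft.rfft(rng.standard_normal(t))
    spec[~keep] = 0.0
    sig = np.fft.irfft(spec, n=t)
    sig -= sig.mean()
    sd = sig.std(ddof=0)
    if sd == 0:  # pragma: no cover - keep-mask guarantees content
        raise ConfigurationError("degenerate band-limited signal")
    return sig / sd


def generate_bold(
    spec: SyntheticSpec,
    subject_seed: int,
    within_override: dict | None = None,
) -> BoldMatrix:
    """One subject's t x n BOLD matrix under the latent-factor model.

    ``within_override`` maps network label -> within-strength, replacing
    ``spec.within_strength`` for those networks (used to plant group
    effects).  Deterministic given (spec.seed, subject_seed).
    """
    rng = np.random.default_rng(mix_seed(spec.seed, subject_seed))
    t, dt, band = spec.t, spec.sampling_interval, spec.band
    b = spec.between_strength
    latents = {
        lab: _band_limited(rng, t, dt, band) for lab in spec.network_labels
    }
    g = _band_limited(rng, t, dt, band) if b > 0 else None
    cols = []
    override = within_override or {}
    for k, lab in enumerate(spec.network_labels):
        w = float(override.get(lab, spec.within_strength))
        if not (b <= w < 1):
            raise ContractError(
                f"within strength {w} for {lab} must be in [between, 1)"
            )
        for _ in range(spec.network_sizes[k]):
            e = _band_limited(rng, t, dt, band)
            s = np.sqrt(max(w - b, 0.0)) * latents[lab] + np.sqrt(1.0 - w) * e
            if g is not None:
                s = s + np.sqrt(b) * g
            cols.append(s)
    values = np.column_stack(cols)
    values -= values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    values /= np.where(sd > 0, sd, 1.0)
    return BoldMatrix(
        values=values,
        sampling_interval=dt,
        region_ids=spec.region_ids(),
    )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    bold: BoldMatrix
    behavior: float
    seed: int


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort: subjects with group labels and behavior scores,
    plus the planted partition."""

    subjects: tuple
    partition: NetworkPartition
    spec: SyntheticSpec
    cohort_spec: CohortSpec
    meta: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def behavior(self) -> np.ndarray:
        return np.array([s.behavior for s in self.subjects])

    def bolds(self) -> list:
        return [s.bold for s in self.subjects]


def mean_network_pearson(bold: BoldMatrix, members) -> float:
    """Mean pairwise Pearson correlation among a network's regions."""
    idx = [bold.region_ids.index(r) for r in members]
    if len(idx) < 2:
        raise ContractError("network needs >= 2 regions")
    vals = []
    for a in range(len(idx)):
        for bq in range(a + 1, len(idx)):
            vals.append(pearson(bold.values[:, idx[a]], bold.values[:, idx[bq]]))
    return float(np.mean(vals))


def generate_cohort(spec: SyntheticSpec, cohort: CohortSpec) -> SyntheticCohort:
    """Generate the two-group cohort with a planted group effect and a
    behavior score.

    Group A uses the base within-strength everywhere; group B uses
    within + effect_delta on the effect networks only.  The behavior score
    is intercept + slope * (subject's mean within-behavior-network Pearson
    FC) + Gaussian noise.
    """
    for lab in cohort.effect_networks:
        if lab not in spec.network_labels:
            raise ContractError(f"unknown effect network {lab!r}")
    if cohort.behavior_network not in spec.network_labels:
        raise ContractError(f"unknown behavior network {cohort.behavior_network!r}")
    w_b = spec.within_strength + cohort.effect_delta
    if not (w_b < 1):
        raise ContractError("within_strength + effect_delta must be < 1")
    partition = spec.partition()
    behav_members = partition.members(cohort.behavior_network)
    noise_rng = np.random.default_rng(mix_seed(cohort.seed, 1_000_003))
    subjects = []
    idx = 0
    for group, count in (("A", cohort.n_group_a), ("B", cohort.n_group_b)):
        override = (
            {lab: w_b for lab in cohort.effect_networks} if group == "B" else None
        )
        for _ in range(count):
            bold = generate_bold(spec, subject_seed=idx, within_override=override)
            mfc = mean_network_pearson(bold, behav_members)
            score = (
                cohort.behavior_intercept
                + cohort.behavior_slope * mfc
                + cohort.behavior_noise_sd * noise_rng.standard_normal()
            )
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{idx + 1:03d}",
                    group=group,
                    bold=bold,
                    behavior=float(score),
                    seed=mix_seed(spec.seed, idx),
                )
            )
            idx += 1
    return SyntheticCohort(
        subjects=tuple(subjects),
        partition=partition,
        spec=spec,
        cohort_spec=cohort,
    )
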