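"""Pairwise functional-connectivity measures between BOLD time series.

A functional-connectivity (FC) value is a scalar statistical dependence
between the BOLD signals of two brain regions.  Nine measures are provided,
spanning time-domain (Pearson correlation, cross-correlation), frequency-
domain (magnitude-squared coherence), time-frequency (wavelet coherence),
information-theoretic (mutual information) similarity, and four
dissimilarities (Euclidean, cityblock, dynamic time warping, earth mover's
distance).  ``pairwise_fc`` assembles a symmetric n x n matrix for any of
them; ``composite`` concatenates the per-measure upper-triangle feature
vectors into the multi-metric FC representation.

Polarity matters downstream: similarity measures grow with connection
strength, dissimilarities shrink.  ``to_similarity`` maps everything onto a
common similarity scale in [0, 1] before thresholding or averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.spatial.distance import cityblock as _sp_cityblock
from scipy.spatial.distance import euclidean as _sp_euclidean

from .errors import (
    ConfigurationError,
    ContractError,
    DegenerateInputError,
    EstimationError,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


#: Fixed measure order of the composite multi-metric FC vector.
MEASURE_ORDER = (
    "corr",
    "xcorr",
    "coherence",
    "wcoherence",
    "mutual_info",
    "euclidean",
    "cityblock",
    "dtw",
    "emd",
)

SIMILARITY_MEASURES = frozenset(
    {"corr", "xcorr", "coherence", "wcoherence", "mutual_info"}
)
DISSIMILARITY_MEASURES = frozenset({"euclidean", "cityblock", "dtw", "emd"})


def measure_polarity(measure: str) -> str:
    if measure in SIMILARITY_MEASURES:
        return "similarity"
    if measure in DISSIMILARITY_MEASURES:
        return "dissimilarity"
    raise ContractError(f"unknown measure {measure!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoldMatrix:
    """One subject's region time-series: ``values`` is t timepoints x n
    regions, one column per region, in arbitrary BOLD units.

    ``sampling_interval`` is the repetition time in seconds (2.6 s for the
    resting-state acquisitions this package targets).
    """

    values: np.ndarray
    sampling_interval: float
    region_ids: tuple

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        if vals.ndim != 2:
            raise ContractError("BOLD values must be a 2-D t x n array")
        t, n = vals.shape
        if t < 8:
            raise ContractError(f"need at least 8 timepoints, got {t}")
        if n < 2:
            raise ContractError(f"need at least 2 regions, got {n}")
        if not np.all(np.isfinite(vals)):
            raise ContractError("BOLD values must all be finite")
        if len(self.region_ids) != n:
            raise ContractError("region_ids length must equal column count")
        if len(set(self.region_ids)) != n:
            raise ContractError("region_ids must be unique")
        if not (self.sampling_interval > 0):
            raise ContractError("sampling_interval must be positive")

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MeasureParams:
    """Estimator settings shared by all measures.

    Any field left ``None`` is resolved from the record length t and the
    sampling interval by :meth:`resolve`:

    max_lag        cross-correlation lag range, default ``t // 4`` samples
    n_bins         mutual-information bins, default 8 (rank-based,
                   near-equiprobable)
    welch_segment  coherence segment length, default ``2**floor(log2(t/4))``
    welch_overlap  segment overlap fraction, default 0.5
    band           frequency band of interest in Hz, default (0.01, 0.1) —
                   the standard resting-state BOLD passband
    wavelet_periods  Morlet scale range as periods in seconds, default
                   (10, 100) — the reciprocal of the band
    smoothing_width  number of adjacent scales averaged when smoothing the
                   wavelet spectra, default 3
    """

    max_lag: int | None = None
    n_bins: int = 8
    welch_segment: int | None = None
    welch_overlap: float = 0.5
    band: tuple = (0.01, 0.1)
    wavelet_periods: tuple = (10.0, 100.0)
    smoothing_width: int = 3
    full_band_fallback: bool = False

    def resolve(self, t: int, sampling_interval: float) -> "MeasureParams":
        """Return a copy with all derived defaults made concrete for a
        record of length ``t`` sampled every ``sampling_interval`` seconds."""
        max_lag = self.max_lag if self.max_lag is not None else max(1, t // 4)
        seg = self.welch_segment
        if seg is None:
            seg = int(2 ** math.floor(math.log2(max(t / 4, 2))))
        resolved = replace(self, max_lag=max_lag, welch_segment=seg)
        resolved.validate(t, sampling_interval)
        return resolved

    def validate(self, t: int, sampling_interval: float) -> None:
        nyquist = 0.5 / sampling_interval
        if self.max_lag is not None and not (0 < self.max_lag < t):
            raise ConfigurationError("max_lag must satisfy 0 < max_lag < t")
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        if not (0 <= self.welch_overlap < 1):
            raise ConfigurationError("welch_overlap must be in [0, 1)")
        lo, hi = self.band
        if not (0 <= lo < hi <= nyquist + 1e-12):
            raise ConfigurationError(
                f"band {self.band} must satisfy 0 <= low < high <= Nyquist "
                f"({nyquist:.4g} Hz)"
            )
        pmin, pmax = self.wavelet_periods
        if not (0 < pmin < pmax):
            raise ConfigurationError("wavelet_periods must satisfy 0 < min < max")
        if self.smoothing_width < 1:
            raise ConfigurationError("smoothing_width must be >= 1")


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric n x n dependence matrix for one measure.

    ``polarity`` records whether large values mean strong connection
    ("similarity") or weak connection ("dissimilarity")."""

    values: np.ndarray
    measure: str
    polarity: str
    region_ids: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        n = len(self.region_ids)
        if vals.shape != (n, n):
            raise ContractError("FC matrix shape must match region_ids")
        if np.nanmax(np.abs(vals - vals.T), initial=0.0) > 1e-9:
            raise ContractError("FC matrix must be symmetric within 1e-9")
        if self.polarity not in ("similarity", "dissimilarity"):
            raise ContractError(f"bad polarity {self.polarity!r}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def off_diagonal_upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class FCFeatureVector:
    """Row-major upper triangle (diagonal excluded) of one FC matrix;
    length n(n-1)/2."""

    values: np.ndarray
    measure: str
    n_regions: int

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = self.n_regions
        if vals.shape != (n * (n - 1) // 2,):
            raise ContractError("feature vector length must be n(n-1)/2")


# ---------------------------------------------------------------------------
# Scalar measures
# ---------------------------------------------------------------------------


def _as_signal(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise DegenerateInputError("empty signal")
    return x


def _check_pair(x, y):
    x, y = _as_signal(x), _as_signal(y)
    if x.size != y.size:
        raise ContractError(f"length mismatch: {x.size} vs {y.size}")
    return x, y


def pearson(x, y) -> float:
    """Pearson's correlation: covariance over the product of standard
    deviations; in [-1, 1], scale- and shift-invariant."""
    x, y = _check_pair(x, y)
    if x.size < 2:
        raise ContractError("need at least 2 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    nx = np.sqrt(xd @ xd)
    ny = np.sqrt(yd @ yd)
    if nx == 0 or ny == 0:
        raise DegenerateInputError("zero-variance signal in pearson")
    r = float((xd @ yd) / (nx * ny))
    return min(1.0, max(-1.0, r))


def cross_correlation(x, y, max_lag: int) -> tuple:
    """Peak normalized cross-correlation magnitude over lags |m| <= max_lag.

    Both signals are demeaned over the full record and the product is divided
    by the full-record norms, so the value at lag 0 equals Pearson's
    correlation exactly and the peak lies in [0, 1].  Returns
    ``(peak, lag)``; on ties the first (most negative) lag wins.
    """
    x, y = _check_pair(x, y)
    t = x.size
    if not (0 < max_lag < t):
        raise ConfigurationError("max_lag must satisfy 0 < max_lag < t")
    xd = x - x.mean()
    yd = y - y.mean()
    nx = np.sqrt(xd @ xd)
    ny = np.sqrt(yd @ yd)
    if nx == 0 or ny == 0:
        raise DegenerateInputError("zero-variance signal in cross_correlation")
    # full cross-correlation: c[m] = sum_i x[i+m] y[i], m = -(t-1)..(t-1)
    full = np.correlate(xd, yd, mode="full") / (nx * ny)
    lags = np.arange(-(t - 1), t)
    keep = np.abs(lags) <= max_lag
    vals = full[keep]
    lag_range = lags[keep]
    idx = int(np.argmax(np.abs(vals)))
    peak = float(np.abs(vals[idx]))
    return min(1.0, peak), int(lag_range[idx])


def coherence(
    x,
    y,
    sampling_interval: float,
    welch_segment: int,
    welch_overlap: float = 0.5,
    band: tuple = (0.01, 0.1),
    full_band_fallback: bool = False,
) -> float:
    """Peak magnitude-squared coherence |P_xy|^2 / (P_xx P_yy) inside
    ``band``, estimated by segment averaging with a Hamming taper.

    Requires at least two averaging segments — a single segment makes the
    estimate identically 1 at every frequency.
    """
    x, y = _check_pair(x, y)
    t = x.size
    noverlap = int(round(welch_overlap * welch_segment))
    step = welch_segment - noverlap
    if step <= 0:
        raise ConfigurationError("welch_overlap leaves no segment advance")
    n_segments = 1 + (t - welch_segment) // step if t >= welch_segment else 0
    if n_segments < 2:
        raise EstimationError(
            f"coherence needs >= 2 segments (got {n_segments}); "
            "shorten welch_segment"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance signal in coherence")
    freqs, cxy = sp_signal.coherence(
        x,
        y,
        fs=1.0 / sampling_interval,
        window="hamming",
        nperseg=welch_segment,
        noverlap=noverlap,
        detrend="constant",
    )
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band):
        if full_band_fallback:
            in_band = freqs > 0
        else:
            raise ConfigurationError(
                f"no frequency bin falls inside band {band} at resolution "
                f"{freqs[1] - freqs[0]:.4g} Hz"
            )
    peak = float(np.max(cxy[in_band]))
    return min(1.0, max(0.0, peak))


_MORLET = "cmor1.5-1.0"  # analytic Morlet; center frequency 1.0


def _cwt_morlet(x: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    coeffs, _ = pywt.cwt(x, scales, _MORLET, sampling_period=dt)
    return coeffs  # (n_scales, t) complex


def _smooth_spectrum(
    w: np.ndarray, scales: np.ndarray, smoothing_width: int
) -> np.ndarray:
    """Smooth a (possibly complex) wavelet spectrum in time with a
    scale-proportional Gaussian and across ``smoothing_width`` adjacent
    scales with a boxcar.  All weights nonnegative, so the smoothed
    coherence obeys the Cauchy-Schwarz bound."""
    out = np.empty_like(w)
    for i, s in enumerate(scales):
        sigma = max(s, 0.5)  # in samples; wavelet e-folding ~ sqrt(2)*scale
        if np.iscomplexobj(w):
            out[i] = gaussian_filter1d(
                w[i].real, sigma, mode="nearest"
            ) + 1j * gaussian_filter1d(w[i].imag, sigma, mode="nearest")
        else:
            out[i] = gaussian_filter1d(w[i], sigma, mode="nearest")
    if smoothing_width > 1 and len(scales) > 1:
        width = min(smoothing_width, len(scales))
        if np.iscomplexobj(out):
            out = uniform_filter1d(out.real, width, axis=0, mode="nearest") + (
                1j * uniform_filter1d(out.imag, width, axis=0, mode="nearest")
            )
        else:
            out = uniform_filter1d(out, width, axis=0, mode="nearest")
    return out


def _wavelet_scales(
    t: int, dt: float, periods: tuple, voices_per_octave: int = 8
) -> np.ndarray:
    pmin, pmax = periods
    # Keep scales whose cone of influence leaves at least one valid sample.
    pmax = min(pmax, t * dt / (2 * math.sqrt(2)) * 1.0)
    if pmax <= pmin:
        pmax = pmin * 2
    n_octaves = math.log2(pmax / pmin)
    n_scales = max(4, int(math.ceil(n_octaves * voices_per_octave)) + 1)
    period_grid = np.geomspace(pmin, pmax, n_scales)
    fc = pywt.central_frequency(_MORLET)
    return period_grid * fc / dt  # scale in samples


def wavelet_coherence(
    x,
    y,
    sampling_interval: float,
    wavelet_periods: tuple = (10.0, 100.0),
    smoothing_width: int = 3,
    _cwt_cache: dict | None = None,
    _cache_keys: tuple | None = None,
) -> float:
    """Peak squared wavelet coherence over the time-scale plane.

    Analytic Morlet transform on scales spanning ``wavelet_periods``;
    cross- and auto-spectra are smoothed in time (scale-proportional
    Gaussian) and across scales (boxcar) before forming
    |S(W_x W_y*)|^2 / (S(|W_x|^2) S(|W_y|^2)).  Points inside the cone of
    influence (closer than sqrt(2)*scale to either edge) are excluded.
    Smoothing is essential: without it the ratio is identically 1.
    """
    x, y = _check_pair(x, y)
    t = x.size
    if t < 32:
        raise ContractError("wavelet coherence needs t >= 32")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance signal in wavelet_coherence")
    dt = sampling_interval
    scales = _wavelet_scales(t, dt, wavelet_periods)

    def cwt_of(sig, key):
        if _cwt_cache is not None and key is not None and key in _cwt_cache:
            return _cwt_cache[key]
        w = _cwt_morlet(sig, scales, dt)
        if _cwt_cache is not None and key is not None:
            _cwt_cache[key] = w
        return w

    kx, ky = _cache_keys if _cache_keys is not None else (None, None)
    wx = cwt_of(x, kx)
    wy = cwt_of(y, ky)
    s_xy = _smooth_spectrum(wx * np.conj(wy), scales, smoothing_width)
    s_xx = _smooth_spectrum(np.abs(wx) ** 2, scales, smoothing_width)
    s_yy = _smooth_spectrum(np.abs(wy) ** 2, scales, smoothing_width)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(s_xy) ** 2 / (s_xx * s_yy)
    # cone of influence: e-folding time sqrt(2)*scale (in samples)
    times = np.arange(t)
    valid = np.zeros_like(coh, dtype=bool)
    for i, s in enumerate(scales):
        margin = math.sqrt(2.0) * s
        valid[i] = (times >= margin) & (times <= t - 1 - margin)
    valid &= np.isfinite(coh)
    if not np.any(valid):
        raise EstimationError("no points outside the cone of influence")
    peak = float(np.max(coh[valid]))
    if peak > 1.0 + 1e-6:
        raise EstimationError(f"wavelet coherence {peak} exceeds 1 beyond tolerance")
    return min(1.0, peak)


def _rank_bins(x: np.ndarray, n_bins: int) -> tuple:
    """Near-equiprobable rank binning; ties share a bin.  Returns the bin
    index per sample and the number of occupied bins."""
    codes = np.asarray(
        pd.qcut(x, n_bins, labels=False, duplicates="drop"), dtype=float
    )
    if np.any(np.isnan(codes)):  # constant input: every edge was dropped
        return np.zeros(x.size, dtype=int), 1
    codes = codes.astype(int)
    return codes, int(codes.max()) + 1


def mutual_information(x, y, n_bins: int = 8) -> float:
    """Plug-in mutual information (nats) over a rank-binned joint.

    Each signal is discretized into ``n_bins`` near-equiprobable bins
    (monotone-invariant); I = sum p(x,y) log[p(x,y) / (p(x)p(y))].
    A constant signal occupies a single bin and yields 0 with a warning.
    """
    x, y = _check_pair(x, y)
    t = x.size
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    if t < n_bins:
        raise ContractError("need t >= n_bins samples")
    bx, kx = _rank_bins(x, n_bins)
    by, ky = _rank_bins(y, n_bins)
    if kx < 2 or ky < 2:
        warnings.warn(
            "constant signal: single occupied bin, mutual information is 0",
            stacklevel=2,
        )
        return 0.0
    return discrete_mutual_information(_joint_mass(bx, by, kx, ky))


def _joint_mass(bx, by, kx, ky) -> np.ndarray:
    joint = np.zeros((kx, ky))
    np.add.at(joint, (bx, by), 1.0)
    return joint / joint.sum()


def discrete_mutual_information(joint: np.ndarray) -> float:
    """Mutual information (nats) of a joint probability mass matrix."""
    joint = np.asarray(joint, dtype=float)
    if joint.min() < 0 or not np.isclose(joint.sum(), 1.0):
        raise ContractError("joint mass must be nonnegative and sum to 1")
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    ratio = joint[nz] / np.outer(px, py)[nz]
    return float(np.sum(joint[nz] * np.log(ratio)))


def binned_entropy(x, n_bins: int = 8) -> float:
    """Entropy (nats) of the rank-binned marginal; the mutual-information
    self-value I(x; x)."""
    x = _as_signal(x)
    bx, kx = _rank_bins(x, n_bins)
    counts = np.bincount(bx, minlength=kx).astype(float)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def euclidean(x, y) -> float:
    """l2 norm of the difference; 0 iff the signals are identical."""
    x, y = _check_pair(x, y)
    return float(_sp_euclidean(x, y))


def cityblock(x, y) -> float:
    """l1 norm of the difference; always >= the Euclidean distance."""
    x, y = _check_pair(x, y)
    return float(_sp_cityblock(x, y))


@_njit(cache=False)
def _dtw_dp(x, y):  # pragma: no cover - numba-compiled
    m = x.shape[0]
    n = y.shape[0]
    prev = np.empty(n)
    curr = np.empty(n)
    prev[0] = abs(x[0] - y[0])
    for j in range(1, n):
        prev[j] = prev[j - 1] + abs(x[0] - y[j])
    for i in range(1, m):
        curr[0] = prev[0] + abs(x[i] - y[0])
        for j in range(1, n):
            c = abs(x[i] - y[j])
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = c + best
        prev, curr = curr, prev
    return prev[n - 1]


def dtw(x, y) -> float:
    """Dynamic time warping distance with steps (1,0), (0,1), (1,1) and
    local cost |x_i - y_j|.

    The minimum cumulative cost over monotone boundary-to-boundary warping
    paths; for equal-length signals the diagonal path is feasible, so
    dtw <= cityblock.
    """
    x, y = _as_signal(x), _as_signal(y)
    return float(_dtw_dp(np.ascontiguousarray(x), np.ascontiguousarray(y)))


def emd(x, y) -> float:
    """Earth mover's (1-Wasserstein) distance between the signals viewed as
    distributions over their time indices.

    Amplitudes are shifted by the signal minimum (BOLD values may be
    negative) and normalized to unit mass; the ground distance between time
    indices i and j is |i - j| samples.  With unit total mass on a unit grid
    the optimal-transport cost equals sum_i |CDF_x(i) - CDF_y(i)|.
    """
    x, y = _as_signal(x), _as_signal(y)
    if x.size != y.size:
        raise ContractError("emd here requires equal-length signals")
    wx = x - x.min()
    wy = y - y.min()
    sx, sy = wx.sum(), wy.sum()
    if sx <= 0 or sy <= 0:
        raise DegenerateInputError("constant signal has zero mass after shift")
    px = wx / sx
    py = wy / sy
    return float(np.abs(np.cumsum(px - py)[:-1]).sum())


# ---------------------------------------------------------------------------
# Matrix assembly and plumbing
# ---------------------------------------------------------------------------


def _self_value(measure: str, col: np.ndarray, params: MeasureParams) -> float:
    if measure == "mutual_info":
        return binned_entropy(col, params.n_bins)
    return 1.0 if measure in SIMILARITY_MEASURES else 0.0


def pairwise_fc(
    bold: BoldMatrix, measure: str, params: MeasureParams | None = None
) -> FCMatrix:
    """Apply one measure to every unordered region pair of a BOLD matrix.

    The diagonal holds the measure's self-value (1 for correlation-like
    measures, the binned entropy for mutual information, 0 for distances);
    downstream thresholding and vectorization never read it.
    """
    if measure not in MEASURE_ORDER:
        raise ContractError(f"unknown measure {measure!r}")
    params = (params or MeasureParams()).resolve(bold.t, bold.sampling_interval)
    n = bold.n_regions
    vals = np.zeros((n, n))
    meta: dict = {"params": params}
    lags = np.zeros((n, n), dtype=int) if measure == "xcorr" else None
    cwt_cache: dict = {}
    cols = [np.ascontiguousarray(bold.values[:, i]) for i in range(n)]
    for i in range(n):
        vals[i, i] = _self_value(measure, cols[i], params)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                v = _pair_value(
                    measure, cols[i], cols[j], bold.sampling_interval, params,
                    cwt_cache, (i, j),
                )
                if measure == "xcorr":
                    v, lag = v
                    lags[i, j] = lags[j, i] = lag
            except (DegenerateInputError, EstimationError) as exc:
                raise type(exc)(
                    f"{measure} failed for region pair "
                    f"({bold.region_ids[i]!r}, {bold.region_ids[j]!r}): {exc}"
                ) from exc
            vals[i, j] = vals[j, i] = v
    if lags is not None:
        meta["lags"] = lags
    return FCMatrix(
        values=vals,
        measure=measure,
        polarity=measure_polarity(measure),
        region_ids=bold.region_ids,
        meta=meta,
    )


def _pair_value(measure, x, y, dt, params, cwt_cache, cache_keys):
    if measure == "corr":
        return pearson(x, y)
    if measure == "xcorr":
        return cross_correlation(x, y, params.max_lag)
    if measure == "coherence":
        return coherence(
            x, y, dt, params.welch_segment, params.welch_overlap, params.band,
            params.full_band_fallback,
        )
    if measure == "wcoherence":
        return wavelet_coherence(
            x, y, dt, params.wavelet_periods, params.smoothing_width,
            _cwt_cache=cwt_cache, _cache_keys=cache_keys,
        )
    if measure == "mutual_info":
        return mutual_information(x, y, params.n_bins)
    if measure == "euclidean":
        return euclidean(x, y)
    if measure == "cityblock":
        return cityblock(x, y)
    if measure == "dtw":
        return dtw(x, y)
    if measure == "emd":
        return emd(x, y)
    raise ContractError(f"unknown measure {measure!r}")


def to_similarity(fc: FCMatrix, pooled_values=None) -> FCMatrix:
    """Map any FC matrix onto a common similarity scale in [0, 1].

    Similarity measures: elementwise absolute value (only magnitudes are
    compared across measures).  Dissimilarity measures: 1 minus the min-max
    rescaled distance, with the min/max taken over ``pooled_values`` when
    supplied (e.g. pooled across a subject group) and over this matrix's
    off-diagonal entries otherwise.  The diagonal of a converted distance
    matrix is set to 1 (perfect self-similarity).  Idempotent on similarity
    polarity.
    """
    if fc.polarity == "similarity":
        return FCMatrix(
            values=np.abs(fc.values),
            measure=fc.measure,
            polarity="similarity",
            region_ids=fc.region_ids,
            meta={**fc.meta, "rescaled": "abs"},
        )
    pool = (
        np.asarray(pooled_values, dtype=float).ravel()
        if pooled_values is not None
        else fc.off_diagonal_upper()
    )
    lo, hi = float(pool.min()), float(pool.max())
    if hi <= lo:
        raise DegenerateInputError(
            "constant off-diagonal distances cannot be min-max rescaled"
        )
    sim = 1.0 - (fc.values - lo) / (hi - lo)
    sim = np.clip(sim, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return FCMatrix(
        values=sim,
        measure=fc.measure,
        polarity="similarity",
        region_ids=fc.region_ids,
        meta={**fc.meta, "rescaled": "minmax", "rescale_range": (lo, hi)},
    )


def vectorize_upper(fc: FCMatrix) -> FCFeatureVector:
    """Row-major upper triangle excluding the diagonal, length n(n-1)/2."""
    return FCFeatureVector(
        values=fc.off_diagonal_upper(), measure=fc.measure, n_regions=fc.n_regions
    )


def matrix_from_upper(
    vec: FCFeatureVector, region_ids, polarity=None, diagonal=0.0
) -> FCMatrix:
    """Rebuild a symmetric matrix from an upper-triangle feature vector."""
    n = vec.n_regions
    if len(region_ids) != n:
        raise ContractError("region_ids length mismatch")
    vals = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals[iu] = vec.values
    vals = vals + vals.T
    np.fill_diagonal(vals, diagonal)
    return FCMatrix(
        values=vals,
        measure=vec.measure,
        polarity=polarity or measure_polarity(vec.measure),
        region_ids=tuple(region_ids),
    )


def composite(vectors) -> np.ndarray:
    """Concatenate the nine per-measure feature vectors, in the fixed order
    corr | xcorr | coherence | wcoherence | mutual_info | euclidean |
    cityblock | dtw | emd, into the multi-metric FC vector of length
    9 * n(n-1)/2."""
    vectors = list(vectors)
    if tuple(v.measure for v in vectors) != MEASURE_ORDER:
        raise ContractError(
            "composite requires exactly the nine measures in order "
            f"{MEASURE_ORDER}"
        )
    lengths = {v.values.size for v in vectors}
    if len(lengths) != 1:
        raise ContractError("all feature vectors must have the same length")
    return np.concatenate([v.values for v in vectors])
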