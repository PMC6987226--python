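import numpy as np
import pytest
from helpers import (
    cross_corr_enumerate,
    dtw_enumerate,
    emd_linprog,
    pearson_direct,
    welch_msc,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from multifc.errors import (
    ConfigurationError,
    ContractError,
    DegenerateInputError,
    EstimationError,
)
from multifc.measures import (
    MEASURE_ORDER,
    BoldMatrix,
    FCFeatureVector,
    MeasureParams,
    cityblock,
    coherence,
    composite,
    cross_correlation,
    discrete_mutual_information,
    dtw,
    emd,
    euclidean,
    matrix_from_upper,
    mutual_information,
    pairwise_fc,
    pearson,
    to_similarity,
    vectorize_upper,
    wavelet_coherence,
)

# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 2, 3), (1, 2, 3), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # hand evaluation of the formula
    ],
)
def test_pearson_known_values(x, y, expected):
    assert pearson(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_scale_shift_invariance(rng):
    x = rng.standard_normal(50)
    y = rng.standard_normal(50)
    assert pearson(3 * x + 7, -2 * y + 1) == pytest.approx(
        -pearson(x, y), abs=1e-12
    )


def test_pearson_zero_variance_is_an_error():
    with pytest.raises(DegenerateInputError):
        pearson(np.ones(10), np.arange(10.0))


# ---------------------------------------------------------------------------
# Cross-correlation
# ---------------------------------------------------------------------------


def test_cross_correlation_self_peak_at_zero(rng):
    x = rng.standard_normal(60)
    peak, lag = cross_correlation(x, x, max_lag=15)
    assert peak == pytest.approx(1.0, abs=1e-12)
    assert lag == 0


def test_cross_correlation_detects_circular_shift():
    t = 64
    x = np.sin(2 * np.pi * np.arange(t) / 16)
    y = np.roll(x, 2)
    peak, lag = cross_correlation(x, y, max_lag=8)
    assert peak == pytest.approx(1.0, abs=0.05)
    assert abs(lag) == 2


def test_cross_correlation_matches_lag_enumeration(rng):
    for _ in range(30):
        t = int(rng.integers(8, 24))
        x = rng.standard_normal(t)
        y = rng.standard_normal(t)
        max_lag = int(rng.integers(1, t))
        table = cross_corr_enumerate(x, y, max_lag)
        exp_peak = max(abs(v) for v in table.values())
        peak, lag = cross_correlation(x, y, max_lag)
        assert peak == pytest.approx(exp_peak, abs=1e-10)
        assert abs(table[lag]) == pytest.approx(exp_peak, abs=1e-10)


def test_cross_correlation_at_lag_zero_equals_pearson(rng):
    for _ in range(25):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        table = cross_corr_enumerate(x, y, 1)
        assert table[0] == pytest.approx(pearson(x, y), abs=1e-10)
        assert pearson(x, y) == pytest.approx(pearson_direct(x, y), abs=1e-12)


def test_cross_correlation_sparse_spike_example():
    x = np.array([1.0, 0.0, 0.0, 0.0])
    y = np.array([0.0, 0.0, 1.0, 0.0])
    table = cross_corr_enumerate(x, y, 3)
    exp_peak = max(abs(v) for v in table.values())
    peak, lag = cross_correlation(x, y, max_lag=3)
    assert peak == pytest.approx(exp_peak, abs=1e-12)
    assert abs(table[lag]) == pytest.approx(exp_peak, abs=1e-12)


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------


def test_coherence_self_is_one(rng):
    x = rng.standard_normal(256)
    assert coherence(x, x, 1.0, 64, band=(0.01, 0.4)) == pytest.approx(1.0)


def test_coherence_phase_offset_sinusoids():
    t = np.arange(512)
    f0 = 0.05
    x = np.sin(2 * np.pi * f0 * t)
    y = np.sin(2 * np.pi * f0 * t + 1.2)
    c = coherence(x, y, 1.0, 128, band=(0.01, 0.1))
    assert c == pytest.approx(1.0, abs=1e-3)  # up to spectral leakage


def test_coherence_matches_independent_welch_oracle(rng):
    x = rng.standard_normal(1024)
    y = rng.standard_normal(1024)
    nperseg = 256  # 1024/256 at 50% overlap -> 7 averaged segments
    oracle = welch_msc(x, y, nperseg, nperseg // 2)
    freqs = np.fft.rfftfreq(nperseg, d=1.0)
    band = (0.01, 0.4)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    expected = float(oracle[in_band].max())
    got = coherence(x, y, 1.0, nperseg, 0.5, band)
    assert got == pytest.approx(expected, abs=1e-8)
    assert got < 1.0  # independent noise never reaches self-coherence


def test_coherence_single_segment_rejected(rng):
    x = rng.standard_normal(64)
    with pytest.raises(EstimationError):
        coherence(x, x, 1.0, welch_segment=64)


def test_coherence_empty_band_rejected(rng):
    x = rng.standard_normal(256)
    with pytest.raises(ConfigurationError):
        coherence(x, x, 1.0, 64, band=(0.0001, 0.001))


# ---------------------------------------------------------------------------
# Wavelet coherence
# ---------------------------------------------------------------------------


def test_wavelet_coherence_self_and_sign_blind(rng):
    x = rng.standard_normal(128)
    assert wavelet_coherence(x, x, 2.6) == pytest.approx(1.0, abs=1e-6)
    assert wavelet_coherence(x, -x, 2.6) == pytest.approx(1.0, abs=1e-6)


def test_wavelet_coherence_common_component_orders_means(rng):
    """A shared in-band oscillation must raise the mean peak coherence
    relative to fully independent noise."""
    t = 227
    dt = 2.6
    time = np.arange(t) * dt
    carrier = np.sin(2 * np.pi * 0.04 * time)
    shared, independent = [], []
    for _ in range(30):
        nx = rng.standard_normal(t)
        ny = rng.standard_normal(t)
        shared.append(
            wavelet_coherence(carrier + 0.7 * nx, carrier + 0.7 * ny, dt)
        )
        independent.append(
            wavelet_coherence(rng.standard_normal(t), rng.standard_normal(t), dt)
        )
    assert np.mean(shared) > np.mean(independent)


def test_wavelet_coherence_bounded(rng):
    for _ in range(10):
        v = wavelet_coherence(rng.standard_normal(96), rng.standard_normal(96), 2.6)
        assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------


def test_mutual_information_deterministic_joint_is_log2():
    joint = np.array([[0.5, 0.0], [0.0, 0.5]])
    assert discrete_mutual_information(joint) == pytest.approx(np.log(2))


def test_mutual_information_self_equals_entropy(rng):
    x = rng.standard_normal(16)  # 16 = 4 bins x 4 samples each
    assert mutual_information(x, x, n_bins=4) == pytest.approx(np.log(4))


def test_mutual_information_independent_near_zero():
    """Plug-in MI of independent uniforms: bias ~ (B-1)^2 / (2t) nats."""
    vals = []
    for seed in range(12):
        r = np.random.default_rng(seed)
        vals.append(
            mutual_information(r.uniform(size=10000), r.uniform(size=10000), 4)
        )
    assert np.mean(vals) < 0.01


def test_mutual_information_constant_signal_warns(rng):
    with pytest.warns(UserWarning, match="constant"):
        assert mutual_information(np.ones(20), rng.standard_normal(20)) == 0.0


def test_mutual_information_nonnegative_and_bounded(rng):
    from multifc.measures import binned_entropy

    for _ in range(20):
        x = rng.standard_normal(64)
        y = rng.standard_normal(64)
        i = mutual_information(x, y, 4)
        assert 0.0 <= i
        assert i <= min(binned_entropy(x, 4), binned_entropy(y, 4)) + 1e-12


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def test_distance_known_values():
    assert euclidean((0, 0), (3, 4)) == pytest.approx(5.0)
    assert cityblock((0, 0), (3, 4)) == pytest.approx(7.0)
    assert euclidean((1, 2), (1, 2)) == 0.0
    assert cityblock((1, 2), (1, 2)) == 0.0


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=2, max_size=12),
    st.lists(st.floats(-50, 50), min_size=2, max_size=12),
    st.lists(st.floats(-50, 50), min_size=2, max_size=12),
    st.floats(-5, 5),
)
def test_distance_properties(xs, ys, zs, c):
    size = min(len(xs), len(ys), len(zs))
    x, y, z = (np.array(v[:size]) for v in (xs, ys, zs))
    # l1 dominates l2
    assert cityblock(x, y) >= euclidean(x, y) - 1e-9
    # homogeneity
    assert euclidean(c * x, c * y) == pytest.approx(abs(c) * euclidean(x, y),
                                                    abs=1e-6)
    # triangle inequality
    assert euclidean(x, z) <= euclidean(x, y) + euclidean(y, z) + 1e-9
    assert cityblock(x, z) <= cityblock(x, y) + cityblock(y, z) + 1e-9


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------


def test_dtw_trivial_cases():
    assert dtw([3.0, 1.0, 4.0], [3.0, 1.0, 4.0]) == 0.0
    assert dtw([0.0, 1.0], [0.0, 1.0, 1.0]) == 0.0  # warping absorbs repeat


def test_dtw_matches_path_enumeration(rng):
    for _ in range(100):
        m = int(rng.integers(1, 7))
        n = int(rng.integers(1, 7))
        x = rng.integers(-5, 6, size=m).astype(float)
        y = rng.integers(-5, 6, size=n).astype(float)
        assert dtw(x, y) == pytest.approx(dtw_enumerate(x, y), abs=1e-12)


def test_dtw_bounded_by_cityblock(rng):
    for _ in range(50):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        assert dtw(x, y) <= cityblock(x, y) + 1e-9


# ---------------------------------------------------------------------------
# Earth mover's distance
# ---------------------------------------------------------------------------


def test_emd_trivial_cases():
    x = np.array([0.0, 5.0, 0.0, 0.0, 0.0])
    assert emd(x, x) == 0.0
    a = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    assert emd(a, b) == pytest.approx(3.0)


def test_emd_constant_signal_rejected():
    with pytest.raises(DegenerateInputError):
        emd(np.full(5, 2.0), np.arange(5.0))


def test_emd_matches_transportation_lp(rng):
    for _ in range(40):
        n = int(rng.integers(2, 11))
        x = rng.uniform(0, 1, size=n)
        y = rng.uniform(0, 1, size=n)
        assert emd(x, y) == pytest.approx(
            emd_linprog(x - x.min(), y - y.min()), abs=1e-8
        )


# ---------------------------------------------------------------------------
# Matrix assembly, polarity, vectorization, composite
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("measure", MEASURE_ORDER)
def test_pairwise_fc_symmetry_and_bounds(small_bold, measure):
    fc = pairwise_fc(small_bold, measure)
    v = fc.values
    assert np.max(np.abs(v - v.T)) <= 1e-9
    off = fc.off_diagonal_upper()
    if measure in ("corr",):
        assert np.all((-1 - 1e-12 <= off) & (off <= 1 + 1e-12))
    elif measure in ("xcorr", "coherence", "wcoherence"):
        assert np.all((0 <= off) & (off <= 1 + 1e-9))
    else:
        assert np.all(off >= 0)
    if fc.polarity == "dissimilarity":
        assert np.all(np.diag(v) == 0)


def test_pairwise_fc_identical_columns_corr(small_bold):
    vals = np.tile(small_bold.values[:, :1], (1, 4))
    bold = BoldMatrix(values=vals, sampling_interval=2.6,
                      region_ids=("a", "b", "c", "d"))
    fc = pairwise_fc(bold, "corr")
    assert np.allclose(fc.off_diagonal_upper(), 1.0)


def test_pairwise_fc_names_offending_pair():
    vals = np.random.default_rng(0).standard_normal((16, 3))
    vals[:, 1] = 5.0  # constant region
    bold = BoldMatrix(values=vals, sampling_interval=2.6,
                      region_ids=("ok", "flat", "ok2"))
    with pytest.raises(DegenerateInputError, match="flat"):
        pairwise_fc(bold, "corr")


def test_pairwise_fc_deterministic(small_bold):
    a = pairwise_fc(small_bold, "mutual_info")
    b = pairwise_fc(small_bold, "mutual_info")
    assert np.array_equal(a.values, b.values)


def test_to_similarity_absolute_value(small_bold):
    fc = pairwise_fc(small_bold, "corr")
    sim = to_similarity(fc)
    assert np.allclose(sim.values, np.abs(fc.values))
    again = to_similarity(sim)  # idempotent on similarity polarity
    assert np.array_equal(again.values, sim.values)


def test_to_similarity_rescales_distances():
    from multifc.measures import FCMatrix

    vals = np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 4.0], [2.0, 4.0, 0.0]])
    fc = FCMatrix(values=vals, measure="euclidean", polarity="dissimilarity",
                  region_ids=("a", "b", "c"))
    sim = to_similarity(fc)
    assert sim.values[0, 1] == pytest.approx(1.0)  # distance 0 -> similarity 1
    assert sim.values[0, 2] == pytest.approx(0.5)
    assert sim.values[1, 2] == pytest.approx(0.0)
    with pytest.raises(DegenerateInputError):
        to_similarity(
            FCMatrix(values=np.ones((3, 3)) - np.eye(3), measure="euclidean",
                     polarity="dissimilarity", region_ids=("a", "b", "c"))
        )


def test_vectorize_and_rebuild_roundtrip(small_bold):
    fc = pairwise_fc(small_bold, "corr")
    vec = vectorize_upper(fc)
    n = fc.n_regions
    assert vec.values.size == n * (n - 1) // 2
    rebuilt = matrix_from_upper(vec, fc.region_ids, diagonal=1.0)
    assert np.allclose(rebuilt.values, fc.values)


@pytest.mark.parametrize("n, expected", [(2, 1), (35, 595)])
def test_feature_vector_length(n, expected):
    vec = FCFeatureVector(values=np.zeros(expected), measure="corr",
                          n_regions=n)
    assert vec.values.size == expected


def test_composite_order_and_length():
    n = 3
    block = n * (n - 1) // 2
    vecs = [
        FCFeatureVector(values=np.full(block, float(i)), measure=m, n_regions=n)
        for i, m in enumerate(MEASURE_ORDER)
    ]
    combined = composite(vecs)
    assert combined.size == 9 * block  # 5355 at n=35: 9 * 595
    for i in range(9):
        assert np.all(combined[i * block:(i + 1) * block] == float(i))
    with pytest.raises(ContractError):
        composite(list(reversed(vecs)))


def test_measure_params_validation():
    with pytest.raises(ConfigurationError):
        MeasureParams(band=(0.2, 0.1)).resolve(100, 2.6)
    with pytest.raises(ConfigurationError):
        MeasureParams(n_bins=1).resolve(100, 2.6)
    resolved = MeasureParams().resolve(227, 2.6)
    assert resolved.max_lag == 56
    assert resolved.welch_segment == 32
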