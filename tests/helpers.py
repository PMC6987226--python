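"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the DTW oracle
enumerates warping paths instead of running the DP recurrence, the EMD
oracle solves the transportation linear program, and the Welch oracle
re-implements segment-averaged coherence from FFT primitives.
"""

import numpy as np
from scipy.optimize import linprog


def dtw_enumerate(x, y):
    """Minimum path cost over ALL monotone boundary-to-boundary warping
    paths with steps (1,0), (0,1), (1,1); exhaustive search with
    branch-and-bound pruning (exact)."""
    x = list(x)
    y = list(y)
    m, n = len(x), len(y)
    best = [float("inf")]

    def rec(i, j, cost):
        cost += abs(x[i] - y[j])
        if cost >= best[0]:
            return
        if i == m - 1 and j == n - 1:
            best[0] = cost
            return
        if i + 1 < m and j + 1 < n:
            rec(i + 1, j + 1, cost)
        if i + 1 < m:
            rec(i + 1, j, cost)
        if j + 1 < n:
            rec(i, j + 1, cost)

    rec(0, 0, 0.0)
    return best[0]


def emd_linprog(px, py):
    """Optimal-transport cost between two histograms on the integer grid
    with ground distance |i - j|, solved as the transportation LP."""
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    px = px / px.sum()
    py = py / py.sum()
    m, n = px.size, py.size
    cost = np.abs(np.subtract.outer(np.arange(m), np.arange(n))).ravel()
    a_eq = []
    b_eq = []
    for i in range(m):
        row = np.zeros(m * n)
        row[i * n:(i + 1) * n] = 1.0
        a_eq.append(row)
        b_eq.append(px[i])
    for j in range(n):
        row = np.zeros(m * n)
        row[j::n] = 1.0
        a_eq.append(row)
        b_eq.append(py[j])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)


def welch_msc(x, y, nperseg, noverlap):
    """Segment-averaged magnitude-squared coherence from FFT primitives
    (periodic Hamming taper, per-segment demeaning)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    step = nperseg - noverlap
    grid = np.arange(nperseg)
    win = 0.54 - 0.46 * np.cos(2 * np.pi * grid / nperseg)
    pxx = pyy = 0.0
    pxy = 0.0 + 0.0j
    for s in range(0, x.size - nperseg + 1, step):
        xs = x[s:s + nperseg]
        ys = y[s:s + nperseg]
        xf = np.fft.rfft((xs - xs.mean()) * win)
        yf = np.fft.rfft((ys - ys.mean()) * win)
        pxx = pxx + (xf * np.conj(xf)).real
        pyy = pyy + (yf * np.conj(yf)).real
        pxy = pxy + xf * np.conj(yf)
    return np.abs(pxy) ** 2 / (pxx * pyy)


def pearson_direct(x, y):
    """Pearson correlation spelled out: covariance over the product of
    standard deviations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))


def cross_corr_enumerate(x, y, max_lag):
    """Direct evaluation of the demeaned, full-record-normalized
    cross-correlation at every lag |m| <= max_lag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = x.size
    xd = x - x.mean()
    yd = y - y.mean()
    norm = np.sqrt((xd**2).sum() * (yd**2).sum())
    out = {}
    for m in range(-max_lag, max_lag + 1):
        total = 0.0
        for i in range(t):
            if 0 <= i + m < t:
                total += xd[i + m] * yd[i]
        out[m] = total / norm
    return out
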