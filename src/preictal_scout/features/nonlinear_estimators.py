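"""Nonlinear time-series estimators used by the univariate nonlinear bank.

All estimators operate on a 1-D array and return a scalar (NaN when the
series is too short or degenerate for the estimator).  Parameter
conventions follow the standard literature forms: sample/approximate
entropy with embedding dimension m and tolerance r (a multiple of the
series SD), Higuchi's fractal dimension with k_max curve scales,
detrended fluctuation analysis with least-squares linear detrending in
log-spaced boxes, rescaled-range Hurst, and Lempel-Ziv complexity of the
median-binarized sequence.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import linregress


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """Delay-embedding matrix of m-length templates (delay 1)."""
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln(A/B) with A, B the counts of template pairs
    matching within Chebyshev tolerance r at lengths m+1 and m
    (self-matches excluded).  r defaults to 0.2 * SD(x)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 2:
        return np.nan
    if r is None:
        sd = x.std()
        if sd == 0:
            return np.nan
        r = 0.2 * sd
    counts = []
    for mm in (m, m + 1):
        emb = _embed(x, mm)
        d = cdist(emb, emb, metric="chebyshev")
        match = (d <= r).sum() - emb.shape[0]  # exclude self-matches
        counts.append(match)
    b, a = counts
    if a == 0 or b == 0:
        return np.nan
    return -np.log(a / b)


def approximate_entropy(x: np.ndarray, m: int = 2,
                        r: float | None = None) -> float:
    """ApEn(m, r) = Phi(m) - Phi(m+1), Phi the mean log fraction of
    templates within Chebyshev tolerance r (self-matches included)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < m + 2:
        return np.nan
    if r is None:
        sd = x.std()
        if sd == 0:
            return np.nan
        r = 0.2 * sd

    def phi(mm: int) -> float:
        emb = _embed(x, mm)
        d = cdist(emb, emb, metric="chebyshev")
        c = (d <= r).mean(axis=1)
        return float(np.log(c).mean())

    return phi(m) - phi(m + 1)


def permutation_entropy(x: np.ndarray, order: int = 3,
                        normalize: bool = True) -> float:
    """Shannon entropy of the ordinal-pattern distribution (delay 1);
    normalized by log(order!) when ``normalize``."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < order + 1:
        return np.nan
    patterns = np.argsort(_embed(x, order), axis=1, kind="stable")
    codes = (patterns * order ** np.arange(order)).sum(axis=1)  # radix code
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    if normalize:
        h /= np.log(float(math.factorial(order)))
    return float(h)


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi's fractal dimension from the scaling of mean curve length
    L(k) ~ k^(-D) over scales 1..k_max."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < k_max + 2:
        return np.nan
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (idx.size - 1) / k
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    valid = lk > 0
    if valid.sum() < 2:
        return np.nan
    slope = linregress(np.log(1.0 / np.arange(1, k_max + 1)[valid]),
                       np.log(lk[valid])).slope
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension log(n)/(log(n) + log(d/L)) with L the total
    path length and d the maximum distance from the first point."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size - 1
    if n < 2:
        return np.nan
    length = np.abs(np.diff(x)).sum()
    if length == 0:
        return np.nan
    d = np.abs(x - x[0]).max()
    if d == 0:
        return np.nan
    return float(np.log10(n) / (np.log10(n) + np.log10(d / length)))


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from the count of sign changes of the
    first difference."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 3:
        return np.nan
    d = np.diff(x)
    nz = d[d != 0]
    if nz.size < 2:
        return np.nan
    n_delta = (np.diff(np.sign(nz)) != 0).sum()
    if n_delta == 0:
        return np.nan
    return float(np.log10(n) / (np.log10(n)
                                + np.log10(n / (n + 0.4 * n_delta))))


def dfa_exponent(x: np.ndarray, min_box: int = 4,
                 n_scales: int = 10) -> float:
    """Detrended fluctuation analysis scaling exponent alpha of the
    integrated, mean-centred series (linear detrending; log-spaced box
    sizes from ``min_box`` to n/4).  White noise gives alpha ~= 0.5."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 4 * min_box:
        return np.nan
    y = np.cumsum(x - x.mean())
    scales = np.unique(np.floor(np.logspace(
        np.log10(min_box), np.log10(n // 4), n_scales)).astype(int))
    flucts = []
    for s in scales:
        n_boxes = n // s
        segs = y[:n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s)
        t_c = t - t.mean()
        beta = (segs * t_c).sum(axis=1) / (t_c ** 2).sum()
        alpha0 = segs.mean(axis=1)
        resid = segs - (alpha0[:, None] + beta[:, None] * t_c[None, :])
        flucts.append(np.sqrt((resid ** 2).mean()))
    flucts = np.asarray(flucts)
    valid = flucts > 0
    if valid.sum() < 2:
        return np.nan
    return float(linregress(np.log(scales[valid]),
                            np.log(flucts[valid])).slope)


def hurst_rs(x: np.ndarray, min_box: int = 16, n_scales: int = 8) -> float:
    """Rescaled-range (R/S) Hurst exponent over log-spaced box sizes."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2 * min_box:
        return np.nan
    scales = np.unique(np.floor(np.logspace(
        np.log10(min_box), np.log10(n // 2), n_scales)).astype(int))
    rs = []
    used = []
    for s in scales:
        n_boxes = n // s
        segs = x[:n_boxes * s].reshape(n_boxes, s)
        dev = segs - segs.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        sd = segs.std(axis=1)
        ok = sd > 0
        if ok.sum() == 0:
            continue
        rs.append((r[ok] / sd[ok]).mean())
        used.append(s)
    rs = np.asarray(rs)
    valid = rs > 0
    if valid.sum() < 2:
        return np.nan
    return float(linregress(np.log(np.asarray(used)[valid]),
                            np.log(rs[valid])).slope)


def lempel_ziv_complexity(x: np.ndarray, normalize: bool = True) -> float:
    """Lempel-Ziv (LZ76) phrase count of the median-binarized sequence,
    normalized by n / log2(n)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2:
        return np.nan
    s = (x > np.median(x)).astype(np.uint8).tobytes()
    # LZ76 parsing (Kaspar-Schuster formulation)
    i, c, u, v, vmax = 0, 1, 1, 1, 1
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            vmax = max(v, vmax)
            i += 1
            if i == u:
                c += 1
                u += vmax
                i, v, vmax = 0, 1, 1
            else:
                v = 1
    if v != 1:
        c += 1
    if normalize:
        return float(c / (n / np.log2(n)))
    return float(c)
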