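"""Per-channel univariate features on 5-s non-overlapping windows.

Two configurable banks are provided: a linear bank (Welch band powers and
spectral shape descriptors plus time-domain statistics and Hjorth
parameters) and a nonlinear bank (entropies, fractal dimensions, scaling
exponents).  Spectral estimation uses Welch with 1-s Hann segments and
50% overlap inside each window; relative band powers are normalized by
the summed power of the five clinical bands, per window.

Invalid windows (overlapping artifact or excluded intervals, or
degenerate, e.g. constant) are emitted with ``validity = False`` and NaN
rows so row timestamps stay aligned with the window grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft
from scipy import signal as sps

from ..preprocess import AnalysisWindow, Segment
from .bands import DEFAULT_BANDS
from . import nonlinear_estimators as nle

WINDOW_S = 5.0

LINEAR_MEASURES = (
    [f"power_{b.name}" for b in DEFAULT_BANDS]
    + [f"relpower_{b.name}" for b in DEFAULT_BANDS]
    + ["total_power", "sef50", "sef90", "peak_freq", "mean_freq",
       "bandwidth", "spectral_entropy",
       "mean", "variance", "skewness", "kurtosis", "rms", "line_length",
       "zero_crossings", "hjorth_activity", "hjorth_mobility",
       "hjorth_complexity", "decorrelation_time", "energy"]
)

NONLINEAR_MEASURES = (
    "sample_entropy", "approximate_entropy",
    "perm_entropy_3", "perm_entropy_4", "perm_entropy_5",
    "higuchi_fd", "katz_fd", "petrosian_fd",
    "dfa", "hurst_rs", "hjorth_complexity_diff", "lempel_ziv",
)


@dataclass
class FeatureMatrix:
    """Windows x features table with relative timestamps and validity.

    ``window_times`` hold window *start* times in seconds relative to
    seizure onset (negative before onset, half-open [t, t + 5 s)).
    """

    values: np.ndarray
    feature_names: list
    window_times: np.ndarray
    group: str
    validity: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.window_times = np.asarray(self.window_times, dtype=np.float64)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.values.shape[0] != self.window_times.size:
            raise ValueError("row count must equal window count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def window_signal(segments, onset: float,
                  window_s: float = WINDOW_S,
                  analysis: AnalysisWindow | None = None,
                  artifact_mask: np.ndarray | None = None,
                  mask_t0: float | None = None,
                  mask_fs: float | None = None):
    """Cut 10-min segments into consecutive half-open 5-s windows.

    Returns ``(windows, times, validity)`` where ``windows`` is
    (n_windows, n_channels, window_samples), ``times`` are window starts
    in seconds relative to ``onset``, and ``validity`` is False for
    windows overlapping the artifact mask or an excluded interval of
    ``analysis``.  Windows never cross segment boundaries; a trailing
    ragged tail shorter than ``window_s`` is dropped.
    """
    wins, times, valid = [], [], []
    for seg in segments:
        fs = seg.fs
        wlen = int(round(window_s * fs))
        n_w = seg.signal.shape[1] // wlen
        for k in range(n_w):
            t_abs = seg.start_time + k * window_s
            wins.append(seg.signal[:, k * wlen:(k + 1) * wlen])
            times.append(t_abs - onset)
            ok = True
            if analysis is not None and analysis.is_excluded(
                    t_abs, t_abs + window_s):
                ok = False
            if ok and artifact_mask is not None:
                fs_m = mask_fs if mask_fs is not None else fs
                a = int(round((t_abs - (mask_t0 or 0.0)) * fs_m))
                b = a + int(round(window_s * fs_m))
                a = max(a, 0)
                if a < artifact_mask.size and artifact_mask[a:b].any():
                    ok = False
            valid.append(ok)
    if not wins:
        n_ch = segments[0].signal.shape[0] if segments else 0
        return (np.empty((0, n_ch, 0)), np.empty(0), np.empty(0, dtype=bool))
    return (np.stack(wins), np.asarray(times), np.asarray(valid, dtype=bool))


def _psd(windows: np.ndarray, fs: float):
    """Welch PSD with 1-s Hann segments, 50% overlap, over the last axis."""
    nperseg = min(int(fs), windows.shape[-1])
    return sps.welch(windows, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, axis=-1)


def linear_features(windows: np.ndarray, fs: float,
                    bands=DEFAULT_BANDS) -> np.ndarray:
    """Linear bank for a batch of windows.

    Parameters
    ----------
    windows : ndarray, shape (n_windows, n_channels, n_samples)
    fs : sampling rate in Hz

    Returns
    -------
    ndarray, shape (n_windows, n_channels, n_measures) ordered as
    ``LINEAR_MEASURES``.  Zero-variance windows yield NaN for the
    measures that are undefined there (relative powers, Hjorth mobility
    and complexity, spectral descriptors).
    """
    windows = np.atleast_3d(np.asarray(windows, dtype=np.float64))
    n_w, n_ch, n_s = windows.shape
    freqs, psd = _psd(windows, fs)

    band_power = np.stack(
        [psd[..., (freqs >= b.low) & (freqs < b.high)].sum(axis=-1)
         * (freqs[1] - freqs[0]) for b in bands], axis=-1)
    band_total = band_power.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_power = np.where(band_total > 0, band_power / band_total, np.nan)

    lo, hi = bands[0].low, bands[-1].high
    in_range = (freqs >= lo) & (freqs < hi)
    f_r = freqs[in_range]
    p_r = psd[..., in_range]
    total = p_r.sum(axis=-1)
    df = freqs[1] - freqs[0]
    total_power = total * df

    cum = np.cumsum(p_r, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum_frac = cum / total[..., None]

    def sef(q):
        idx = (cum_frac >= q).argmax(axis=-1)
        out = f_r[idx]
        return np.where(total > 0, out, np.nan)

    sef50, sef90 = sef(0.5), sef(0.9)
    peak = np.where(total > 0, f_r[p_r.argmax(axis=-1)], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_f = (p_r * f_r).sum(axis=-1) / total
        bw = np.sqrt((p_r * (f_r[None, None, :] - mean_f[..., None]) ** 2
                      ).sum(axis=-1) / total)
        p_norm = p_r / total[..., None]
        ent = -np.nansum(np.where(p_norm > 0, p_norm * np.log(p_norm), 0.0),
                         axis=-1) / np.log(p_r.shape[-1])
    mean_f = np.where(total > 0, mean_f, np.nan)
    bw = np.where(total > 0, bw, np.nan)
    ent = np.where(total > 0, ent, np.nan)

    mean = windows.mean(axis=-1)
    centred = windows - mean[..., None]
    c2 = centred * centred
    var = c2.mean(axis=-1)
    m3 = (c2 * centred).mean(axis=-1)
    m4 = (c2 * c2).mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = m3 / var ** 1.5
        kurt = m4 / var ** 2 - 3.0  # excess kurtosis
    rms = np.sqrt((windows ** 2).mean(axis=-1))
    diff1 = np.diff(windows, axis=-1)
    line_length = np.abs(diff1).mean(axis=-1)
    sign = np.sign(windows)
    zc = (np.diff(sign, axis=-1) != 0).sum(axis=-1).astype(float)
    var_d1 = diff1.var(axis=-1)
    var_d2 = np.diff(diff1, axis=-1).var(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mobility = np.where(var > 0, np.sqrt(var_d1 / var), np.nan)
        mob_d = np.where(var_d1 > 0, np.sqrt(var_d2 / var_d1), np.nan)
        complexity = mob_d / mobility
    energy = (windows ** 2).sum(axis=-1)
    skew = np.where(var > 0, skew, np.nan)
    kurt = np.where(var > 0, kurt, np.nan)

    # decorrelation time: first lag (s) where autocorrelation < 1/e
    nfft = fft.next_fast_len(2 * n_s)
    spec = fft.rfft(centred, n=nfft, axis=-1)
    acorr = fft.irfft((spec * np.conj(spec)).real, n=nfft,
                      axis=-1)[..., :int(fs)]
    with np.errstate(invalid="ignore", divide="ignore"):
        acorr_n = acorr / acorr[..., :1]
    below = acorr_n < (1.0 / np.e)
    first = below.argmax(axis=-1).astype(float)
    never = ~below.any(axis=-1)
    first[never] = float(int(fs))
    decorr = np.where(var > 0, first / fs, np.nan)

    out = np.concatenate([
        band_power, rel_power,
        np.stack([total_power, sef50, sef90, peak, mean_f, bw, ent,
                  mean, var, skew, kurt, rms, line_length, zc,
                  var, mobility, complexity, decorr, energy], axis=-1),
    ], axis=-1)
    return out


def nonlinear_features(windows: np.ndarray, fs: float) -> np.ndarray:
    """Nonlinear bank (see ``NONLINEAR_MEASURES``) for a batch of windows.

    Estimators that cannot be computed for a window (too short, zero
    variance) yield NaN for that entry.
    """
    windows = np.atleast_3d(np.asarray(windows, dtype=np.float64))
    n_w, n_ch, _ = windows.shape
    out = np.full((n_w, n_ch, len(NONLINEAR_MEASURES)), np.nan)
    for i in range(n_w):
        for c in range(n_ch):
            x = windows[i, c]
            if x.std() == 0:
                continue
            d1 = np.diff(x)
            var_d1 = d1.var()
            var_d2 = np.diff(d1).var()
            hjc = np.nan
            if var_d1 > 0 and x.var() > 0:
                mob = np.sqrt(var_d1 / x.var())
                mob_d = np.sqrt(var_d2 / var_d1) if var_d1 > 0 else np.nan
                hjc = mob_d / mob
            out[i, c] = [
                nle.sample_entropy(x),
                nle.approximate_entropy(x),
                nle.permutation_entropy(x, 3),
                nle.permutation_entropy(x, 4),
                nle.permutation_entropy(x, 5),
                nle.higuchi_fd(x),
                nle.katz_fd(x),
                nle.petrosian_fd(x),
                nle.dfa_exponent(x),
                nle.hurst_rs(x),
                hjc,
                nle.lempel_ziv_complexity(x),
            ]
    return out


def _flatten(per_channel: np.ndarray, channel_names, measures):
    n_w = per_channel.shape[0]
    flat = per_channel.reshape(n_w, -1)
    names = [f"{ch}|{m}" for ch in channel_names for m in measures]
    return flat, names


def extract_univariate(windows: np.ndarray, times: np.ndarray,
                       validity: np.ndarray, fs: float, channel_names,
                       group: str = "univariate_linear") -> FeatureMatrix:
    """Assemble a :class:`FeatureMatrix` for one univariate group.

    Windows whose feature row is entirely NaN (degenerate input) are
    additionally marked invalid.
    """
    if group == "univariate_linear":
        per_ch = linear_features(windows, fs)
        measures = LINEAR_MEASURES
    elif group == "univariate_nonlinear":
        per_ch = nonlinear_features(windows, fs)
        measures = NONLINEAR_MEASURES
    else:
        raise ValueError(f"unknown univariate group: {group}")
    values, names = _flatten(per_ch, channel_names, measures)
    validity = np.asarray(validity, dtype=bool) & ~np.all(
        np.isnan(values), axis=1)
    return FeatureMatrix(values=values, feature_names=names,
                         window_times=times, group=group, validity=validity)
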