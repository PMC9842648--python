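"""Multivariate features: band-specific connectivity and global graph measures.

For each 5-s window and each clinical band, the band-filtered signals give
a symmetric channels x channels connectivity matrix (default estimator:
absolute Pearson correlation; magnitude-squared coherence and phase-locking
value available).  Each matrix is proportionally thresholded (top ``q``
fraction of off-diagonal edges retained, weights kept) and summarized by
global graph measures, so each (band, estimator) contributes one small set
of scalar features per window.

Path-based measures use the weight-to-length transform ``length = 1/w``;
on a disconnected thresholded graph the characteristic path length is
computed on the largest component and flagged.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy import signal as sps

from .bands import DEFAULT_BANDS
from .univariate import FeatureMatrix

GRAPH_MEASURES = (
    "mean_strength", "mean_clustering", "transitivity", "char_path_length",
    "global_efficiency", "local_efficiency", "mean_betweenness",
    "max_betweenness", "assortativity", "modularity", "density",
)


def _band_filter(x: np.ndarray, fs: float, low: float, high: float
                 ) -> np.ndarray:
    sos = sps.butter(2, [low, min(high, 0.99 * fs / 2)], btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def connectivity(window: np.ndarray, fs: float, band,
                 estimator: str = "abs_pearson") -> np.ndarray:
    """Pairwise connectivity of one window in one band.

    Parameters
    ----------
    window : ndarray (n_channels, n_samples)
    band : BandDefinition
    estimator : 'abs_pearson' | 'coherence' | 'plv'

    Returns a symmetric matrix with unit diagonal; rows/columns of
    zero-variance channels are NaN.
    """
    x = _band_filter(np.asarray(window, dtype=np.float64), fs,
                     band.low, band.high)
    n_ch = x.shape[0]
    sd = x.std(axis=-1)
    dead = sd == 0
    if estimator == "abs_pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(x)
        m = np.abs(c)
    elif estimator == "coherence":
        m = np.eye(n_ch)
        nperseg = min(int(fs), x.shape[-1])
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                f, cxy = sps.coherence(x[i], x[j], fs=fs, nperseg=nperseg)
                sel = (f >= band.low) & (f < band.high)
                m[i, j] = m[j, i] = cxy[sel].mean() if sel.any() else np.nan
    elif estimator == "plv":
        phase = np.angle(sps.hilbert(x, axis=-1))
        z = np.exp(1j * phase)
        m = np.abs(z @ z.conj().T) / x.shape[-1]
    else:
        raise ValueError(f"unknown estimator: {estimator}")
    np.fill_diagonal(m, 1.0)
    m[dead, :] = np.nan
    m[:, dead] = np.nan
    return m


def _batch_abs_pearson(windows: np.ndarray, fs: float, band) -> np.ndarray:
    """Vectorized absolute Pearson connectivity for a window batch."""
    x = _band_filter(np.asarray(windows, dtype=np.float64), fs,
                     band.low, band.high)
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xn = x / sd[..., None]
    cov = np.einsum("wcs,wds->wcd", xn, xn) / x.shape[-1]
    m = np.abs(cov)
    dead = sd == 0
    m[dead[:, :, None] | dead[:, None, :]] = np.nan
    idx = np.arange(m.shape[1])
    m[:, idx, idx] = 1.0
    return m


def proportional_threshold(matrix: np.ndarray, q: float = 0.3) -> np.ndarray:
    """Keep the strongest fraction ``q`` of off-diagonal edges (weights
    retained, the rest zeroed).  Symmetric input assumed."""
    m = np.array(matrix, dtype=np.float64)
    np.fill_diagonal(m, 0.0)
    iu = np.triu_indices_from(m, k=1)
    w = m[iu]
    finite = np.isfinite(w)
    n_keep = int(round(q * finite.sum()))
    out = np.zeros_like(m)
    if n_keep == 0:
        return out
    order = np.argsort(np.where(finite, w, -np.inf))[::-1][:n_keep]
    keep_i, keep_j = iu[0][order], iu[1][order]
    out[keep_i, keep_j] = w[order]
    out[keep_j, keep_i] = w[order]
    return out


def graph_features(matrix: np.ndarray, q: float = 0.3,
                   threshold: bool = True) -> dict:
    """Global graph measures of a (thresholded) weighted connectivity matrix.

    Returns a dict over ``GRAPH_MEASURES`` plus a ``disconnected`` flag.
    NaN entries in the matrix are treated as absent edges.
    """
    m = np.array(matrix, dtype=np.float64)
    m[~np.isfinite(m)] = 0.0
    if threshold:
        m = proportional_threshold(m, q)
    else:
        np.fill_diagonal(m, 0.0)
    n = m.shape[0]
    g = nx.from_numpy_array(m)
    # remove zero-weight edges introduced by from_numpy_array on explicit 0s
    g.remove_edges_from([(u, v) for u, v, d in g.edges(data=True)
                         if d["weight"] <= 0])
    for _, _, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"]

    out = {}
    strengths = [s for _, s in g.degree(weight="weight")]
    out["mean_strength"] = float(np.mean(strengths)) if strengths else 0.0
    out["mean_clustering"] = float(np.mean(list(
        nx.clustering(g, weight="weight").values()))) if n else np.nan
    out["transitivity"] = float(nx.transitivity(g))

    disconnected = not nx.is_connected(g) if n else True
    if n and g.number_of_edges():
        if disconnected:
            comp = max(nx.connected_components(g), key=len)
            sub = g.subgraph(comp)
        else:
            sub = g
        if sub.number_of_nodes() > 1:
            out["char_path_length"] = float(
                nx.average_shortest_path_length(sub, weight="length"))
        else:
            out["char_path_length"] = np.nan
    else:
        out["char_path_length"] = np.nan

    # weighted global efficiency: mean over ordered pairs of 1/d
    eff = 0.0
    if g.number_of_edges():
        for src, dists in nx.all_pairs_dijkstra_path_length(g, weight="length"):
            eff += sum(1.0 / d for t, d in dists.items() if t != src and d > 0)
        eff /= n * (n - 1)
    out["global_efficiency"] = float(eff)
    out["local_efficiency"] = float(nx.local_efficiency(g)) if n else np.nan

    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    out["mean_betweenness"] = float(np.mean(list(bc.values()))) if bc else np.nan
    out["max_betweenness"] = float(np.max(list(bc.values()))) if bc else np.nan
    try:
        out["assortativity"] = float(
            nx.degree_assortativity_coefficient(g))
    except (ZeroDivisionError, ValueError):
        out["assortativity"] = np.nan
    if not np.isfinite(out["assortativity"]):
        out["assortativity"] = np.nan
    if g.number_of_edges():
        comms = nx.algorithms.community.greedy_modularity_communities(
            g, weight="weight")
        out["modularity"] = float(nx.algorithms.community.modularity(
            g, comms, weight="weight"))
    else:
        out["modularity"] = np.nan
    out["density"] = float(nx.density(g))
    out["disconnected"] = disconnected
    return out


def extract_multivariate(windows: np.ndarray, times: np.ndarray,
                         validity: np.ndarray, fs: float,
                         bands=DEFAULT_BANDS,
                         estimators=("abs_pearson",),
                         q: float = 0.3) -> FeatureMatrix:
    """Band x estimator x graph-measure features for a batch of windows."""
    windows = np.asarray(windows, dtype=np.float64)
    n_w = windows.shape[0]
    names = [f"{b.name}|{est}|{m}" for b in bands for est in estimators
             for m in GRAPH_MEASURES]
    values = np.full((n_w, len(names)), np.nan)
    col = 0
    for b in bands:
        for est in estimators:
            if est == "abs_pearson":
                mats = _batch_abs_pearson(windows, fs, b)
            else:
                mats = np.stack([connectivity(w, fs, b, est)
                                 for w in windows])
            for i in range(n_w):
                if not validity[i]:
                    continue
                feats = graph_features(mats[i], q=q)
                values[i, col:col + len(GRAPH_MEASURES)] = [
                    feats[m] for m in GRAPH_MEASURES]
            col += len(GRAPH_MEASURES)
    validity = np.asarray(validity, dtype=bool) & ~np.all(
        np.isnan(values), axis=1)
    return FeatureMatrix(values=values, feature_names=names,
                         window_times=times, group="multivariate",
                         validity=validity)
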