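"""Per-seizure feature-matrix preparation.

Rows failing validity are removed, missing estimator outputs are
median-imputed per feature, constant and quasi-constant features are
dropped (quasi-constant: the modal value accounts for strictly more than
half of the rows, with values compared after rounding to 12 significant
digits to absorb floating-point ties), and the retained columns are
z-scored with the n-1 standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features.univariate import FeatureMatrix


class EmptyMatrixError(RuntimeError):
    """All features were degenerate; the seizure cannot be analysed."""


@dataclass
class PreparedMatrix:
    """Z-scored analysis matrix with its preparation provenance."""

    values: np.ndarray
    feature_names: list
    window_times: np.ndarray
    group: str
    dropped_features: dict = field(default_factory=dict)  # name -> reason
    normalization: dict = field(default_factory=dict)     # name -> (mean, sd)
    imputed_counts: dict = field(default_factory=dict)    # name -> n imputed

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def _round_sig(col: np.ndarray, digits: int = 12) -> np.ndarray:
    out = col.copy()
    nz = np.isfinite(col) & (col != 0)
    if nz.any():
        mag = np.floor(np.log10(np.abs(col[nz])))
        scale = 10.0 ** (digits - 1 - mag)
        out[nz] = np.round(col[nz] * scale) / scale
    return out


def drop_degenerate_features(matrix: FeatureMatrix,
                             impute: bool = True) -> PreparedMatrix:
    """Apply validity filtering, median imputation and the constant /
    quasi-constant drop rules (no normalization yet)."""
    keep_rows = matrix.validity
    values = matrix.values[keep_rows]
    times = matrix.window_times[keep_rows]
    n = values.shape[0]
    if n == 0:
        raise EmptyMatrixError(f"{matrix.group}: no valid windows")

    dropped, imputed = {}, {}
    keep_cols = []
    for j, name in enumerate(matrix.feature_names):
        col = values[:, j]
        nan = ~np.isfinite(col)
        if nan.all():
            dropped[name] = "constant"
            continue
        if nan.any():
            if not impute:
                dropped[name] = "constant"
                continue
            col = col.copy()
            col[nan] = np.median(col[~nan])
            values[:, j] = col
            imputed[name] = int(nan.sum())
        rounded = _round_sig(col)
        _, counts = np.unique(rounded, return_counts=True)
        modal = counts.max()
        if modal == n:
            dropped[name] = "constant"
        elif modal > n / 2:
            dropped[name] = "quasi_constant"
        else:
            keep_cols.append(j)

    if not keep_cols:
        raise EmptyMatrixError(
            f"{matrix.group}: all {len(matrix.feature_names)} features "
            "constant or quasi-constant")
    names = [matrix.feature_names[j] for j in keep_cols]
    return PreparedMatrix(values=values[:, keep_cols], feature_names=names,
                          window_times=times, group=matrix.group,
                          dropped_features=dropped,
                          imputed_counts={k: v for k, v in imputed.items()
                                          if k in names})


def zscore(prepared: PreparedMatrix) -> PreparedMatrix:
    """Standardize each retained column to mean 0, SD 1 (ddof = 1)."""
    mu = prepared.values.mean(axis=0)
    sd = prepared.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [n for n, s in zip(prepared.feature_names, sd) if s == 0]
        raise RuntimeError(
            f"zero SD after degeneracy drop (internal error): {bad[:5]}")
    prepared.values = (prepared.values - mu) / sd
    prepared.normalization = {
        name: (float(m), float(s))
        for name, m, s in zip(prepared.feature_names, mu, sd)}
    return prepared


def prepare(matrix: FeatureMatrix) -> PreparedMatrix:
    """Full preparation: validity filter, impute, drop degenerate, z-score."""
    return zscore(drop_degenerate_features(matrix))
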