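"""File interfaces: EDF signals, delimited seizure rosters, interval masks.

Recordings travel as EDF so the synthetic and real-data paths share I/O.
Reading goes through :mod:`mne`; writing uses a minimal in-package EDF
encoder (16-bit, 1-s data records) sufficient for fixed-rate continuous
signals.  Rosters are CSV with ISO-8601 timestamps; the numeric timeline
origin (second 0) is 2000-01-01T00:00:00 UTC.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EEGRecord, SeizureEvent, SeizureRoster

#: absolute datetime corresponding to timeline second 0
TIME_ORIGIN = dt.datetime(2000, 1, 1, tzinfo=dt.timezone.utc)


def _to_datetime(seconds: float) -> dt.datetime:
    return TIME_ORIGIN + dt.timedelta(seconds=float(seconds))


def _to_seconds(stamp) -> float:
    ts = pd.Timestamp(stamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return (ts - pd.Timestamp(TIME_ORIGIN)).total_seconds()


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path) -> Path:
    """Write an :class:`EEGRecord` as EDF (16-bit, 1-s data records).

    The sampling rate must be a positive integer; a trailing partial
    second is zero-padded.  Physical units are microvolts.
    """
    path = Path(path)
    fs = int(round(record.fs))
    if abs(fs - record.fs) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = np.asarray(record.signal, dtype=np.float64)
    n_ch, n = x.shape
    n_rec = int(np.ceil(n / fs))
    if n_rec * fs != n:
        x = np.pad(x, ((0, 0), (0, n_rec * fs - n)))

    pmin = np.floor(x.min(axis=1))
    pmax = np.ceil(x.max(axis=1))
    same = pmax <= pmin
    pmax[same] = pmin[same] + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((x - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    start = _to_datetime(record.start_time)
    header = b"".join([
        _ascii(0, 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii(start.strftime("%d.%m.%y"), 8),
        _ascii(start.strftime("%H.%M.%S"), 8),
        _ascii(256 * (1 + n_ch), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(n_ch, 4),
    ])
    fields = [
        [_ascii(name, 16) for name in record.channel_names],      # label
        [_ascii("", 80)] * n_ch,                                  # transducer
        [_ascii("uV", 8)] * n_ch,                                 # dimension
        [_ascii(f"{v:g}", 8) for v in pmin],
        [_ascii(f"{v:g}", 8) for v in pmax],
        [_ascii(dmin, 8)] * n_ch,
        [_ascii(dmax, 8)] * n_ch,
        [_ascii("", 80)] * n_ch,                                  # prefilter
        [_ascii(fs, 8)] * n_ch,                                   # samples/rec
        [_ascii("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        # records: for each second, all channels' samples contiguously
        rec_view = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec_view).tobytes())
    return path


def read_edf(path) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne holds volts internally
    meas = raw.info["meas_date"]
    start = (meas - TIME_ORIGIN).total_seconds() if meas is not None else 0.0
    return EEGRecord(signal=data, fs=float(raw.info["sfreq"]),
                     channel_names=tuple(raw.ch_names), start_time=start)


ROSTER_COLUMNS = ["seizure_id", "onset", "offset", "vigilance", "type"]


def write_roster(roster: SeizureRoster, path) -> Path:
    """Roster as CSV with ISO-8601 UTC onset/offset columns."""
    path = Path(path)
    rows = [{
        "seizure_id": ev.seizure_id,
        "onset": _to_datetime(ev.onset).isoformat(),
        "offset": _to_datetime(ev.offset).isoformat(),
        "vigilance": ev.vigilance if ev.vigilance is not None else "",
        "type": ev.seizure_type if ev.seizure_type is not None else "",
    } for ev in roster]
    pd.DataFrame(rows, columns=ROSTER_COLUMNS).to_csv(path, index=False)
    return path


def read_roster(path) -> SeizureRoster:
    df = pd.read_csv(path, dtype={"vigilance": "string", "type": "string"})
    events = []
    for _, row in df.iterrows():
        events.append(SeizureEvent(
            seizure_id=int(row["seizure_id"]),
            onset=_to_seconds(row["onset"]),
            offset=_to_seconds(row["offset"]),
            vigilance=(None if pd.isna(row.get("vigilance")) or row["vigilance"] == ""
                       else str(row["vigilance"])),
            seizure_type=(None if pd.isna(row.get("type")) or row["type"] == ""
                          else str(row["type"]))))
    return SeizureRoster(events)


def write_mask_intervals(mask: np.ndarray, fs: float, path,
                         reason: str = "artifact") -> Path:
    """Export a per-sample boolean mask as a text file of intervals
    (tab-separated ``start_s  end_s  reason``, half-open in seconds)."""
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    edges = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1) / fs
    ends = np.flatnonzero(edges == -1) / fs
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\treason\n")
        for a, b in zip(starts, ends):
            fh.write(f"{a:.6f}\t{b:.6f}\t{reason}\n")
    return path


def read_mask_intervals(path, n_samples: int, fs: float) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    mask = np.zeros(n_samples, dtype=bool)
    for _, row in df.iterrows():
        a = int(round(row["start_s"] * fs))
        b = int(round(row["end_s"] * fs))
        mask[max(a, 0):min(b, n_samples)] = True
    return mask


def write_feature_matrix(matrix, path_base) -> Path:
    """Feature matrix as tidy CSV plus a JSON sidecar header.

    Writes ``<base>.csv`` (window_time, validity, one column per feature)
    and ``<base>.json`` (group, feature names, registry info).
    """
    base = Path(path_base)
    df = pd.DataFrame(matrix.values, columns=matrix.feature_names)
    df.insert(0, "window_time_s", matrix.window_times)
    df.insert(1, "valid", matrix.validity.astype(int))
    df.to_csv(base.with_suffix(".csv"), index=False)
    header = {"group": matrix.group,
              "n_windows": int(matrix.n_windows),
              "feature_names": list(matrix.feature_names)}
    base.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return base.with_suffix(".csv")


def write_prepared_matrix(prepared, path_base) -> Path:
    """PreparedMatrix as CSV plus its preparation provenance as JSON
    (dropped features with reasons, normalization parameters, imputation
    counts) so the matrix can be reproduced exactly."""
    base = Path(path_base)
    df = pd.DataFrame(prepared.values, columns=prepared.feature_names)
    df.insert(0, "window_time_s", prepared.window_times)
    df.to_csv(base.with_suffix(".csv"), index=False)
    meta = {"group": prepared.group,
            "dropped_features": prepared.dropped_features,
            "normalization": {k: list(v)
                              for k, v in prepared.normalization.items()},
            "imputed_counts": prepared.imputed_counts}
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return base.with_suffix(".csv")


def write_solution(embedding, solution, window_times, path) -> Path:
    """Selected embedding + clustering solution as one CSV
    (window_time, x, y, z, label, method, n_neighbors, min_dist, DI)."""
    import numpy as _np

    path = Path(path)
    nn, md = solution.embedding_params
    df = pd.DataFrame({
        "window_time_s": window_times,
        "x": embedding[:, 0], "y": embedding[:, 1], "z": embedding[:, 2],
        "label": solution.labels,
        "method": solution.method,
        "n_neighbors": nn, "min_dist": md,
        "dunn_index": (_np.nan if _np.isnan(solution.dunn_index)
                       else solution.dunn_index),
    })
    df.to_csv(path, index=False)
    return path
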