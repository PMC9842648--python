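"""EEG preprocessing: lead-seizure selection, analysis windows, filtering,
bad-segment rejection, segmentation and average re-referencing.

The analysis is seizure-centric: for each lead seizure (one preceded by at
least ``LEAD_GAP_HOURS`` of seizure-free recording) an analysis window
covering up to 4.5 h before onset is built, with the 10-min seizure
prediction horizon (SPH) and any postictal overlap from a previous seizure
excluded.  Signals are band-pass filtered (0.5-100 Hz, 4th-order
Butterworth), notch filtered at the mains frequency (2nd-order IIR), split
into 10-min segments and re-referenced to the instantaneous average across
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

#: canonical 10-20 montage used throughout (19 scalp electrodes)
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

LEAD_GAP_HOURS = 4.5
SPH_MINUTES = 10.0
POSTICTAL_MINUTES = 30.0
SEGMENT_MINUTES = 10.0


@dataclass
class EEGRecord:
    """Multichannel EEG signal.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Unique, ordered channel labels.
    start_time : float
        Absolute time of the first sample, in seconds on the recording
        timeline (synthetic recordings use seconds since roster origin).
    """

    signal: np.ndarray
    fs: float
    channel_names: tuple
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class SeizureEvent:
    seizure_id: int
    onset: float          # absolute seconds
    offset: float
    vigilance: str | None = None
    seizure_type: str | None = None

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValueError("offset must be >= onset")


@dataclass
class SeizureRoster:
    """Ordered seizure annotations with strictly increasing onsets."""

    events: list

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("seizure onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def previous_event(self, event: SeizureEvent) -> SeizureEvent | None:
        """The roster event whose onset immediately precedes ``event``'s."""
        prev = None
        for e in self.events:
            if e.onset >= event.onset:
                break
            prev = e
        return prev


@dataclass
class AnalysisWindow:
    """Per-seizure pre-onset analysis interval with exclusions.

    ``span`` is the half-open absolute interval [onset - 4.5 h, onset - SPH)
    (clipped at the available recording start).  ``excluded_intervals``
    holds merged absolute intervals removed from the span (the postictal
    tail of a previous seizure); the SPH itself is outside the span by
    construction.
    """

    seizure_id: int
    span: tuple
    onset: float
    sph_minutes: float = SPH_MINUTES
    postictal_minutes: float = POSTICTAL_MINUTES
    excluded_intervals: list = field(default_factory=list)

    @property
    def effective_duration_hours(self) -> float:
        excl = sum(b - a for a, b in self.excluded_intervals)
        return (self.span[1] - self.span[0] - excl) / 3600.0

    def is_excluded(self, t0: float, t1: float) -> bool:
        """True if [t0, t1) overlaps any excluded interval or leaves the span."""
        if t0 < self.span[0] or t1 > self.span[1]:
            return True
        return any(t0 < b and t1 > a for a, b in self.excluded_intervals)


def select_lead_seizures(roster: SeizureRoster,
                         min_gap_hours: float = LEAD_GAP_HOURS) -> SeizureRoster:
    """Keep lead seizures: the first one, and every seizure whose onset is at
    least ``min_gap_hours`` after the previous seizure's offset.

    The filter is idempotent and preserves order and ids.
    """
    gap = min_gap_hours * 3600.0
    kept = []
    prev_offset = None
    for ev in roster:
        if prev_offset is None or ev.onset - prev_offset >= gap:
            kept.append(ev)
        prev_offset = ev.offset
    return SeizureRoster(kept)


def build_analysis_window(seizure: SeizureEvent,
                          roster: SeizureRoster,
                          sph_min: float = SPH_MINUTES,
                          postictal_min: float = POSTICTAL_MINUTES,
                          max_hours: float = LEAD_GAP_HOURS,
                          available_start: float | None = None) -> AnalysisWindow:
    """Build the pre-onset analysis window for a lead seizure.

    The span covers up to ``max_hours`` before onset, ending at
    onset - ``sph_min``.  If a previous seizure exists, the overlap of
    [prev_offset, prev_offset + postictal_min] with the span is excluded.
    ``available_start`` clips the span when the recording is shorter than
    ``max_hours`` (synthetic small-window runs).
    """
    onset = seizure.onset
    lo = onset - max_hours * 3600.0
    if available_start is not None:
        lo = max(lo, available_start)
    hi = onset - sph_min * 60.0
    prev = roster.previous_event(seizure)
    excluded = []
    if prev is not None:
        if prev.onset >= lo:
            raise ValueError(
                f"seizure {seizure.seizure_id}: previous seizure onset inside "
                "the analysis window; not a lead seizure")
        a, b = prev.offset, prev.offset + postictal_min * 60.0
        a, b = max(a, lo), min(b, hi)
        if b > a:
            excluded.append((a, b))
    return AnalysisWindow(seizure_id=seizure.seizure_id, span=(lo, hi),
                          onset=onset, sph_minutes=sph_min,
                          postictal_minutes=postictal_min,
                          excluded_intervals=excluded)


def _bandpass_sos(fs: float, low: float = 0.5, high: float = 100.0,
                  order: int = 4):
    return sps.butter(order, [low, high], btype="bandpass", fs=fs,
                      output="sos")


def filter_signal(record: EEGRecord, low: float = 0.5, high: float = 100.0,
                  notch_hz: float = 50.0, notch_q: float = 30.0) -> EEGRecord:
    """Zero-phase 0.5-100 Hz band-pass (4th-order Butterworth) followed by a
    2nd-order 50 Hz notch.

    Forward-backward application keeps the timing of preictal transitions
    unchanged at the cost of doubling the effective filter order.
    """
    if record.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {record.fs} Hz too low for a {high} Hz band edge")
    sos = _bandpass_sos(record.fs, low, high)
    x = sps.sosfiltfilt(sos, record.signal, axis=1)
    b, a = sps.iirnotch(notch_hz, notch_q, fs=record.fs)
    x = sps.filtfilt(b, a, x, axis=1)
    return replace(record, signal=x)


@dataclass(frozen=True)
class BadSegmentParams:
    """Thresholds of the rule-based artifact detector (config defaults;
    the detector flags flatlines, rail saturation and abnormal peaks)."""

    flat_eps: float = 1e-3      # µV, |first difference| below => flat
    flat_min_s: float = 2.0
    rail_uv: float = 500.0      # saturation rail amplitude
    sat_min_s: float = 0.5
    z_peak: float = 8.0
    guard_s: float = 1.0


def _runs_longer_than(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Keep only True-runs of at least ``min_len`` samples."""
    out = np.zeros_like(mask)
    if not mask.any():
        return out
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            out[s:e] = True
    return out


def detect_bad_segments(record: EEGRecord,
                        params: BadSegmentParams = BadSegmentParams()
                        ) -> np.ndarray:
    """Per-sample boolean artifact mask (True = bad), any-channel union of:

    - flatline: |first difference| < ``flat_eps`` for >= ``flat_min_s``;
    - saturation: |amplitude| >= ``rail_uv`` for >= ``sat_min_s``;
    - abnormal peak: |z-scored amplitude| > ``z_peak`` (per channel).

    The mask is dilated by ``guard_s`` on both sides.
    """
    fs = record.fs
    x = record.signal
    mask = np.zeros(record.n_samples, dtype=bool)
    flat_len = max(int(round(params.flat_min_s * fs)), 1)
    sat_len = max(int(round(params.sat_min_s * fs)), 1)
    for ch in range(record.n_channels):
        xi = x[ch]
        d = np.abs(np.diff(xi, prepend=xi[0]))
        mask |= _runs_longer_than(d < params.flat_eps, flat_len)
        mask |= _runs_longer_than(np.abs(xi) >= params.rail_uv, sat_len)
        sd = xi.std()
        if sd > 0:
            mask |= np.abs(xi - xi.mean()) > params.z_peak * sd
    guard = int(round(params.guard_s * fs))
    if guard > 0 and mask.any():
        kernel = np.ones(2 * guard + 1, dtype=np.int32)
        mask = np.convolve(mask.astype(np.int32), kernel, mode="same") > 0
    return mask


@dataclass
class Segment:
    """A 10-min (or trailing partial) portion of a record, re-referenced."""

    signal: np.ndarray
    fs: float
    start_time: float
    partial: bool = False


def segment_and_rereference(record: EEGRecord,
                            segment_min: float = SEGMENT_MINUTES) -> list:
    """Split into non-overlapping ``segment_min`` segments and subtract the
    instantaneous mean across channels (average reference).

    A trailing partial segment is kept and flagged ``partial`` so callers
    may exclude it.
    """
    seg_len = int(round(segment_min * 60.0 * record.fs))
    segments = []
    for s0 in range(0, record.n_samples, seg_len):
        chunk = record.signal[:, s0:s0 + seg_len]
        if chunk.shape[1] == 0:
            break
        chunk = chunk - chunk.mean(axis=0, keepdims=True)
        segments.append(Segment(signal=chunk, fs=record.fs,
                                start_time=record.start_time + s0 / record.fs,
                                partial=chunk.shape[1] < seg_len))
    return segments
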