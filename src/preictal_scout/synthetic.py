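"""Synthetic multichannel EEG with a controllable preictal regime.

The generator produces the statistical structure the downstream analysis
assumes, without attempting biophysical realism:

- interictal background: per-channel colored noise shaped into the five
  clinical bands (delta..gamma) with configurable relative amplitudes,
  plus a shared common source so baseline inter-channel connectivity is
  nonzero;
- an injected preictal regime on a 5-s window grid inside the 120 min
  before onset, realized as a multiplicative shift of selected band
  amplitudes and/or of the common-source coupling, at a configurable
  effect size and window density;
- optional sleep-wake modulation alternating band weights with a fixed
  period;
- optional artifacts (flatlines, rail saturation, spike bursts) placed in
  a fraction of 10-min segments.

Everything is reproducible from a single integer seed.  Seizure onset is
the last sample of the recording; window timestamps are negative seconds
relative to onset, half-open windows [t, t+5 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import CHANNELS_1020, EEGRecord, SeizureEvent, SeizureRoster

WINDOW_S = 5.0
SPH_MINUTES = 10.0

#: relative band amplitudes of the background (1/f-like decay)
DEFAULT_BAND_WEIGHTS = {
    "delta": 1.0, "theta": 0.6, "alpha": 0.5, "beta": 0.3, "gamma": 0.15,
}
BAND_EDGES = {
    "delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0), "gamma": (30.0, 47.0),
}

#: per unit effect size, relative amplitude change of each band during the
#: preictal regime (alpha rises, beta falls — an arbitrary but fixed choice
#: giving both signed directions)
PREICTAL_BAND_SHIFT = {"alpha": 0.25, "beta": -0.20}
#: during "sleep", slow activity rises and alpha drops
SLEEP_BAND_SHIFT = {"delta": 0.25, "alpha": -0.20}


@dataclass
class SynthConfig:
    """Study-condition parameters of a synthetic pre-onset recording.

    ``effect_size`` is a standardized shift (z units of the interictal
    feature distribution, approximately realized through band-amplitude
    gains); ``preictal_density`` is the fraction of 5-s windows inside
    [start, start - duration] that carry the shift.
    """

    n_channels: int = 19
    fs: float = 256.0
    window_hours: float = 4.5
    preictal_start: float = 45.0      # minutes before onset
    preictal_duration: float = 20.0   # minutes
    preictal_density: float = 1.0
    effect_size: float = 3.0          # z units
    effect_target: tuple = ("bands", "coupling")
    sleepwake_period: float = 0.0     # minutes; 0 = off
    sleepwake_effect: float = 2.0     # z units
    artifact_rate: float = 0.0        # fraction of 10-min segments
    band_weights: dict = field(default_factory=lambda: dict(DEFAULT_BAND_WEIGHTS))
    coupling: float = 0.4             # baseline common-source mixing scale
    amplitude_uv: float = 20.0        # target per-channel SD in µV
    rng_seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0.0 <= self.preictal_density <= 1.0:
            raise ValueError("preictal_density must lie in [0, 1]")
        if self.effect_size != 0 and self.preictal_duration > 0:
            if self.preictal_start > 120.0:
                raise ValueError("preictal_start must be <= 120 min")
            if self.preictal_start - self.preictal_duration < 0:
                raise ValueError("preictal interval extends past onset")
            if self.preictal_start - self.preictal_duration < SPH_MINUTES:
                raise ValueError("preictal interval extends into the SPH")
            if self.preictal_start * 60.0 > self.window_hours * 3600.0:
                raise ValueError("preictal interval starts before the recording")


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests.

    ``preictal_window_starts`` are window start times in seconds relative
    to onset (negative, on the 5-s grid); ``sleepwake_vector`` is one
    binary value (1 = wake) per 5-s window over the full recording;
    ``artifact_mask`` is per sample.
    """

    preictal_window_starts: np.ndarray
    sleepwake_vector: np.ndarray
    artifact_mask: np.ndarray
    seizure_onset: float
    seizure_offsets: tuple = ()

    @property
    def preictal_start_min(self) -> float | None:
        if self.preictal_window_starts.size == 0:
            return None
        return -float(self.preictal_window_starts.min()) / 60.0

    @property
    def preictal_duration_min(self) -> float | None:
        if self.preictal_window_starts.size == 0:
            return None
        s = self.preictal_window_starts
        return float(s.max() - s.min() + WINDOW_S) / 60.0


def _band_noise(rng: np.random.Generator, shape: tuple, fs: float,
                band: tuple) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (per row)."""
    lo, hi = band
    sos = sps.butter(2, [lo, min(hi, 0.99 * fs / 2)], btype="bandpass",
                     fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _choose_preictal_windows(config: SynthConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """Window start times (s relative to onset) carrying the shift; realizes
    the requested density within one window."""
    if config.effect_size == 0 or config.preictal_duration <= 0:
        return np.empty(0)
    t0 = -config.preictal_start * 60.0
    n_span = int(round(config.preictal_duration * 60.0 / WINDOW_S))
    starts = t0 + WINDOW_S * np.arange(n_span)
    m = int(round(config.preictal_density * n_span))
    if m >= n_span:
        return starts
    if m == 0:
        return np.empty(0)
    idx = np.sort(rng.choice(n_span, size=m, replace=False))
    return starts[idx]


def generate_recording(config: SynthConfig) -> tuple:
    """Generate one pre-onset recording and its ground truth.

    Returns
    -------
    (EEGRecord, GroundTruth)
        The record has ``n_channels x window_hours*3600*fs`` samples and
        ends at seizure onset (``record.end_time`` is the onset).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    fs = config.fs
    n = int(round(config.window_hours * 3600.0 * fs))
    n_ch = config.n_channels
    t = (np.arange(n) - n) / fs + 1.0 / fs  # seconds relative to onset, <= 0

    # --- per-window regime indicators ----------------------------------
    n_win = int(np.ceil(n / (WINDOW_S * fs)))
    win_starts = -(n_win - np.arange(n_win)) * WINDOW_S  # relative to onset
    pre_starts = _choose_preictal_windows(config, rng)
    pre_win = np.isin(np.round(win_starts, 6), np.round(pre_starts, 6))
    pre_sample = np.repeat(pre_win, int(WINDOW_S * fs))[-n:]

    if config.sleepwake_period > 0:
        half = config.sleepwake_period * 60.0 / 2.0
        phase = np.floor((t - t[0]) / half).astype(int)
        wake_sample = (phase % 2 == 0)
        wake_win = (np.floor((win_starts - win_starts[0]) / half).astype(int)
                    % 2 == 0)
    else:
        wake_sample = np.ones(n, dtype=bool)
        wake_win = np.ones(n_win, dtype=bool)

    # --- band-structured background with regime gains ------------------
    x = np.zeros((n_ch, n))
    for band, w in config.band_weights.items():
        comp = _band_noise(rng, (n_ch, n), fs, BAND_EDGES[band])
        gain = np.full(n, w)
        if "bands" in config.effect_target and band in PREICTAL_BAND_SHIFT:
            g = 1.0 + PREICTAL_BAND_SHIFT[band] * config.effect_size
            gain = np.where(pre_sample, gain * max(g, 0.05), gain)
        if config.sleepwake_period > 0 and band in SLEEP_BAND_SHIFT:
            g = 1.0 + SLEEP_BAND_SHIFT[band] * config.sleepwake_effect
            gain = np.where(~wake_sample, gain * max(g, 0.05), gain)
        x += comp * gain

    # shared common source (alpha-band) => nonzero baseline connectivity;
    # mixing coefficients vary across channels so average re-referencing
    # does not cancel it exactly
    common = _band_noise(rng, (n,), fs, BAND_EDGES["alpha"])
    mix = config.coupling * rng.uniform(0.5, 1.5, size=n_ch)
    c_gain = np.ones(n)
    if "coupling" in config.effect_target:
        c_gain = np.where(pre_sample, 1.0 + 0.25 * config.effect_size, c_gain)
    x += mix[:, None] * (common * c_gain)[None, :]

    scale = config.amplitude_uv / np.sqrt(
        sum(w ** 2 for w in config.band_weights.values()) + config.coupling ** 2)
    x *= scale

    # --- artifacts ------------------------------------------------------
    artifact_mask = np.zeros(n, dtype=bool)
    seg_len = int(600 * fs)
    n_seg = n // seg_len
    n_bad = int(round(config.artifact_rate * n_seg))
    if n_bad > 0:
        bad_segs = rng.choice(n_seg, size=n_bad, replace=False)
        for seg in bad_segs:
            kind = rng.integers(3)
            if kind == 0:          # flatline, 4 s
                dur = int(4 * fs)
            elif kind == 1:        # rail saturation, 1.5 s
                dur = int(1.5 * fs)
            else:                  # spike burst, 1 s
                dur = int(1 * fs)
            s0 = seg * seg_len + int(rng.integers(0, seg_len - dur))
            sl = slice(s0, s0 + dur)
            if kind == 0:
                x[:, sl] = x[:, [s0]]
            elif kind == 1:
                x[:, sl] = 500.0 * np.sign(x[:, [s0]] + 1e-12)
            else:
                burst = 15.0 * config.amplitude_uv * sps.windows.hann(dur)
                x[:, sl] += burst[None, :] * rng.choice([-1, 1], size=(n_ch, 1))
            artifact_mask[sl] = True

    names = (CHANNELS_1020[:n_ch] if n_ch <= len(CHANNELS_1020)
             else tuple(f"CH{i + 1}" for i in range(n_ch)))
    record = EEGRecord(signal=x, fs=fs, channel_names=names, start_time=0.0)
    truth = GroundTruth(
        preictal_window_starts=pre_starts,
        sleepwake_vector=wake_win.astype(np.int8),
        artifact_mask=artifact_mask,
        seizure_onset=record.end_time,
    )
    return record, truth


def generate_roster(n_seizures: int,
                    gap_hours=None,
                    seed: int = 0,
                    base_time: float = 0.0,
                    vigilance_states=("awake", "sleep"),
                    seizure_types=("FOA", "FOIA", "FBTC")) -> SeizureRoster:
    """Roster of ``n_seizures`` events with given offset-to-onset gaps.

    ``gap_hours`` is a sequence of ``n_seizures - 1`` inter-seizure gaps
    (previous offset to next onset); defaults to i.i.d. uniform 2-12 h.
    Seizure durations are uniform 60-180 s.  Vigilance and type labels are
    sampled from the given categories.
    """
    rng = np.random.default_rng(seed)
    if n_seizures == 0:
        return SeizureRoster([])
    if gap_hours is None:
        gap_hours = rng.uniform(2.0, 12.0, size=max(n_seizures - 1, 0))
    gap_hours = np.asarray(gap_hours, dtype=float)
    if gap_hours.size != n_seizures - 1:
        raise ValueError("need n_seizures - 1 gaps")
    if np.any(gap_hours <= 0):
        raise ValueError("gaps must be positive")
    events = []
    tcur = base_time
    for i in range(n_seizures):
        if i > 0:
            tcur += gap_hours[i - 1] * 3600.0
        dur = float(rng.uniform(60.0, 180.0))
        events.append(SeizureEvent(
            seizure_id=i + 1, onset=tcur, offset=tcur + dur,
            vigilance=str(rng.choice(vigilance_states)),
            seizure_type=str(rng.choice(seizure_types))))
        tcur += dur
    return SeizureRoster(events)
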