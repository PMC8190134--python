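"""Filtering, gait-event detection, and steady-state trimming.

Heel strikes are taken as the per-cycle local maxima of the low-pass-filtered
anteroposterior acceleration; toe-offs as those of the vertical acceleration.
A minimum peak separation derived from the signal's dominant autocorrelation
lag enforces one event per gait cycle, and supernumerary peaks between
consecutive heel strikes are discarded (the larger survives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal as sps

from gaitfall.errors import DataError, DetectionError, ParameterError
from gaitfall.synthetic import SIDES, ImuRecording


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass configuration (defaults: order 2, 10 Hz cutoff,
    zero-phase forward-backward application)."""

    order: int = 2
    cutoff: float = 10.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")


@dataclass(frozen=True)
class EventSeries:
    """Heel-strike and toe-off sample indices per side."""

    hs: Mapping[str, np.ndarray]
    to: Mapping[str, np.ndarray]
    sampling_rate: float

    def __post_init__(self) -> None:
        for side in self.hs:
            for name, arr in (("hs", self.hs[side]), ("to", self.to[side])):
                a = np.asarray(arr)
                if a.size > 1 and not np.all(np.diff(a) > 0):
                    raise DataError(f"{name}[{side}] indices not strictly increasing")

    def n_strides(self, side: str) -> int:
        return max(len(self.hs[side]) - 1, 0)


def lowpass(series: np.ndarray, sampling_rate: float,
            spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the Butterworth low-pass; zero-phase (filtfilt) by default."""
    series = np.asarray(series, dtype=float)
    nyquist = sampling_rate / 2.0
    if spec.cutoff >= nyquist:
        raise ParameterError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist {nyquist} Hz")
    if len(series) <= 3 * spec.order:
        raise DataError("series too short for the requested filter order")
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=sampling_rate,
                     output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, series)
    return sps.sosfilt(sos, series)


def dominant_cycle_lag(series: np.ndarray, sampling_rate: float,
                       min_lag_s: float = 0.4, max_lag_s: float = 2.5) -> int:
    """Dominant gait-cycle period in samples, from the autocorrelation peak
    within a physiologic lag window."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    if not np.any(x):
        raise DetectionError("flat signal: no dominant cycle")
    acf = np.correlate(x, x, mode="full")[len(x) - 1:]
    lo = max(int(min_lag_s * sampling_rate), 1)
    hi = min(int(max_lag_s * sampling_rate), len(acf) - 1)
    if hi <= lo:
        raise DetectionError("signal shorter than one expected gait cycle")
    return lo + int(np.argmax(acf[lo:hi + 1]))


def _pick_peaks(series: np.ndarray, distance: int, channel: str) -> np.ndarray:
    height = series.mean() + 0.25 * series.std()
    peaks, _ = sps.find_peaks(series, distance=max(distance, 1), height=height)
    if peaks.size == 0:
        raise DetectionError(f"no peaks found on {channel} channel")
    return peaks


def _enforce_alternation(hs: np.ndarray, to: np.ndarray,
                         to_heights: np.ndarray) -> np.ndarray:
    """Keep at most one toe-off strictly inside each heel-strike interval
    (the largest), and drop toe-offs outside [first HS, last HS]."""
    kept: list[int] = []
    for lo, hi in zip(hs[:-1], hs[1:]):
        mask = (to > lo) & (to < hi)
        if mask.any():
            cand = np.flatnonzero(mask)
            kept.append(int(to[cand[np.argmax(to_heights[cand])]]))
    return np.asarray(kept, dtype=int)


def detect_events(recording: ImuRecording, spec: FilterSpec = FilterSpec(),
                  min_cycle_fraction: float = 0.5) -> EventSeries:
    """Detect heel strikes (anteroposterior maxima) and toe-offs (vertical
    maxima) on the filtered channels of one foot's recording."""
    if not 0.0 < min_cycle_fraction < 1.0:
        raise ParameterError("min_cycle_fraction must lie in (0, 1)")
    fs = recording.sampling_rate
    ap = lowpass(recording.accel_ap, fs, spec)
    vert = lowpass(recording.accel_vert, fs, spec)
    lag = dominant_cycle_lag(ap, fs)
    distance = int(min_cycle_fraction * lag)
    hs = _pick_peaks(ap, distance, "anteroposterior")
    to = _pick_peaks(vert, distance, "vertical")
    to = _enforce_alternation(hs, to, vert[to])
    return EventSeries(hs={recording.side: hs}, to={recording.side: to},
                       sampling_rate=fs)


def detect_events_both(recordings: Mapping[str, ImuRecording],
                       spec: FilterSpec = FilterSpec(),
                       min_cycle_fraction: float = 0.5) -> EventSeries:
    """Run detection per foot and merge into a single two-sided series."""
    hs: dict[str, np.ndarray] = {}
    to: dict[str, np.ndarray] = {}
    fs = None
    for side in SIDES:
        ev = detect_events(recordings[side], spec, min_cycle_fraction)
        hs[side] = ev.hs[side]
        to[side] = ev.to[side]
        fs = ev.sampling_rate
    return EventSeries(hs=hs, to=to, sampling_rate=fs)


def trim_transients(events: EventSeries, n_start: int = 2,
                    n_end: int = 2) -> EventSeries:
    """Drop the first ``n_start`` and last ``n_end`` heel-strike-to-heel-strike
    cycles per side (acceleration/deceleration strides), with their toe-offs."""
    if n_start < 0 or n_end < 0:
        raise ParameterError("trim counts must be non-negative")
    if n_start == 0 and n_end == 0:
        return events
    hs_out: dict[str, np.ndarray] = {}
    to_out: dict[str, np.ndarray] = {}
    for side in events.hs:
        hs = np.asarray(events.hs[side])
        remaining = (len(hs) - 1) - n_start - n_end
        if remaining < 2:
            raise DataError(
                f"side {side}: {len(hs) - 1} strides, need >= 2 after trimming "
                f"{n_start}+{n_end}")
        hs_new = hs[n_start: len(hs) - n_end]
        to = np.asarray(events.to[side])
        to_out[side] = to[(to > hs_new[0]) & (to < hs_new[-1])]
        hs_out[side] = hs_new
    return EventSeries(hs=hs_out, to=to_out, sampling_rate=events.sampling_rate)
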