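"""Spatiotemporal gait variables computed from detected event series.

Nine variables per walking speed: walking speed, stride length, cadence,
stance phase, stride time, stride-to-stride variability (CV) of stride
length / stance phase / stride time, and gait asymmetry (log-ratio of the
bilateral mean swing times).  Walking speed and stride length additionally
get height-normalized variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from gaitfall.errors import DataError, ParameterError, UndefinedValueError
from gaitfall.signal_processing import EventSeries


def walking_speed(distance: float, duration: float) -> float:
    """Mean walking speed (m/s) = distance / duration."""
    if duration <= 0:
        raise ParameterError("duration must be positive")
    return distance / duration


def cadence(step_count: int, duration: float) -> float:
    """Cadence (steps/min) = steps x 60 / duration (s)."""
    if duration <= 0:
        raise ParameterError("duration must be positive")
    return step_count * 60.0 / duration


def stride_times(hs: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Per-stride durations (s) from consecutive same-foot heel strikes."""
    hs = np.asarray(hs)
    if len(hs) < 2:
        raise DataError("need at least 2 heel strikes for a stride")
    return np.diff(hs) / sampling_rate


def stride_lengths(hs: np.ndarray, sampling_rate: float, speed: float) -> np.ndarray:
    """Per-stride lengths (m) = stride time (s) x walking speed (m/s)."""
    if speed <= 0:
        raise ParameterError("speed must be positive")
    return stride_times(hs, sampling_rate) * speed


def stance_phases(hs: np.ndarray, to: np.ndarray,
                  sampling_rate: float | None = None) -> np.ndarray:
    """Per-stride stance phase (%) — the fraction of each heel-strike-to-
    heel-strike cycle spent before the toe-off inside that cycle.

    Each stride interval [HS_n, HS_n+1) must contain exactly one toe-off;
    this pairing covers both the recording-starts-on-stance and the
    recording-starts-mid-swing index conventions.
    """
    hs = np.asarray(hs, dtype=float)
    to = np.asarray(to, dtype=float)
    if len(hs) < 2:
        raise DataError("need at least 2 heel strikes for a stride")
    out = np.empty(len(hs) - 1)
    for i, (lo, hi) in enumerate(zip(hs[:-1], hs[1:])):
        inside = to[(to > lo) & (to < hi)]
        if len(inside) != 1:
            raise DataError(
                f"stride {i}: expected exactly 1 toe-off in [{lo}, {hi}), "
                f"found {len(inside)}")
        out[i] = (inside[0] - lo) / (hi - lo) * 100.0
    return out


def swing_times(hs: np.ndarray, to: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Per-stride swing durations (s): toe-off to the next heel strike."""
    hs = np.asarray(hs, dtype=float)
    stance_pct = stance_phases(hs, to)
    stride = np.diff(hs) / sampling_rate
    return stride * (1.0 - stance_pct / 100.0)


def gait_asymmetry(swing_left_mean: float, swing_right_mean: float) -> float:
    """Bilateral asymmetry (%) = 100 x |ln(shorter mean swing / longer)|."""
    if swing_left_mean <= 0 or swing_right_mean <= 0:
        raise ParameterError("swing times must be positive")
    short, long = sorted((swing_left_mean, swing_right_mean))
    return abs(math.log(short / long)) * 100.0


def coefficient_of_variation(values: np.ndarray, ddof: int = 1) -> float:
    """CV (%) = standard deviation / mean x 100 (sample SD by default)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise DataError("need at least 2 values for a CV")
    mean = values.mean()
    if mean == 0:
        raise UndefinedValueError("CV undefined for zero mean")
    return float(np.std(values, ddof=ddof) / mean * 100.0)


def normalize_by_height(value: float, height: float) -> float:
    if height <= 0:
        raise ParameterError("height must be positive")
    return value / height


@dataclass(frozen=True)
class GaitFeatures:
    """The nine per-speed gait variables plus height-normalized variants."""

    walking_speed: float
    stride_length: float
    cadence: float
    stance_phase: float
    stride_time: float
    cv_stride_length: float
    cv_stance_phase: float
    cv_stride_time: float
    gait_asymmetry: float
    walking_speed_norm: float
    stride_length_norm: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def extract_features(events: EventSeries, walkway_distance: float = 20.0,
                     height: float = 1.6, distance_fraction: float = 1.0,
                     pool_feet: bool = True) -> GaitFeatures:
    """Assemble the full gait-variable set from a trimmed two-sided series.

    ``walkway_distance * distance_fraction`` is the distance covered by the
    retained (steady-state) strides; duration is measured first-to-last heel
    strike across both feet; cadence counts every heel strike in the window.
    CVs pool per-stride values across feet by default (``pool_feet=False``
    computes them per foot and averages).
    """
    sides = list(events.hs)
    if len(sides) != 2:
        raise DataError("extract_features needs events for both feet")
    fs = events.sampling_rate
    all_hs = np.concatenate([events.hs[s] for s in sides])
    duration = (all_hs.max() - all_hs.min()) / fs
    if duration <= 0:
        raise DataError("degenerate event series: zero walking duration")
    speed = walking_speed(walkway_distance * distance_fraction, duration)
    cad = cadence(len(all_hs), duration)

    per_side = {
        s: {
            "stride_time": stride_times(events.hs[s], fs),
            "stride_length": stride_lengths(events.hs[s], fs, speed),
            "stance_phase": stance_phases(events.hs[s], events.to[s]),
            "swing": swing_times(events.hs[s], events.to[s], fs),
        }
        for s in sides
    }

    def pooled(key: str) -> np.ndarray:
        return np.concatenate([per_side[s][key] for s in sides])

    def cv_of(key: str) -> float:
        if pool_feet:
            return coefficient_of_variation(pooled(key))
        return float(np.mean([coefficient_of_variation(per_side[s][key])
                              for s in sides]))

    swing_means = [float(per_side[s]["swing"].mean()) for s in sides]
    return GaitFeatures(
        walking_speed=speed,
        stride_length=float(pooled("stride_length").mean()),
        cadence=cad,
        stance_phase=float(pooled("stance_phase").mean()),
        stride_time=float(pooled("stride_time").mean()),
        cv_stride_length=cv_of("stride_length"),
        cv_stance_phase=cv_of("stance_phase"),
        cv_stride_time=cv_of("stride_time"),
        gait_asymmetry=gait_asymmetry(swing_means[0], swing_means[1]),
        walking_speed_norm=normalize_by_height(speed, height),
        stride_length_norm=normalize_by_height(
            float(pooled("stride_length").mean()), height),
    )
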