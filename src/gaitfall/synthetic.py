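"""Synthetic IMU walking signals and cohort tables with known ground truth.

Two generators live here:

* :func:`simulate_imu_walk` builds per-foot accelerometer/gyroscope traces in
  which each heel strike is planted as a dominant pulse on the anteroposterior
  channel and each toe-off as a pulse on the vertical channel, so peak-based
  event detection has an exact oracle.
* :func:`simulate_cohort` draws participant feature tables from group-specific
  distributions (high vs low fall risk), together with fall-questionnaire
  answers that are consistent with the stored label under a configurable
  risk rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gaitfall import risk
from gaitfall.errors import ParameterError

SIDES = ("left", "right")
SPEEDS = ("slower", "preferred", "faster")

#: the nine per-speed gait variables, in reporting order
GAIT_VARIABLES = (
    "walking_speed",
    "stride_length",
    "cadence",
    "stance_phase",
    "stride_time",
    "cv_stride_length",
    "cv_stance_phase",
    "cv_stride_time",
    "gait_asymmetry",
)

#: continuous demographic/cognitive variables drawn per group
DEMOGRAPHIC_VARIABLES = ("age", "bmi", "pa_met_min_wk", "education_level", "mmse")

ACCEL_RANGE_G = 6.0
GYRO_RANGE_DPS = 500.0

# heel-strike / toe-off pulse shape: FWHM ~50 ms Gaussian
_PULSE_SIGMA_S = 0.021
_PULSE_AMPLITUDE_G = 1.2
_BASELINE_AMPLITUDE_G = 0.05
_TRANSIENT_RAMP = 1.35  # first/last transient stride is this much slower


# ---------------------------------------------------------------------------
# raw-signal generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitPlan:
    """Parameters of one simulated straight-line walk (both feet)."""

    n_strides: int = 10
    stride_time_mean: float = 1.0
    stride_time_sd: float = 0.0
    stance_fraction: float = 0.6
    walking_speed: float = 1.2
    left_right_swing_offset: float = 0.0
    n_transient_strides: int = 2
    sampling_rate: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 2:
            raise ParameterError("n_strides must be >= 2")
        if self.stride_time_mean <= 0:
            raise ParameterError("stride_time_mean must be positive")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ParameterError("stance_fraction must lie in (0, 1)")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.stride_time_sd < 0 or self.noise_sd < 0:
            raise ParameterError("standard deviations must be non-negative")
        if self.n_transient_strides < 0:
            raise ParameterError("n_transient_strides must be non-negative")
        swing = (1.0 - self.stance_fraction) * self.stride_time_mean
        if abs(self.left_right_swing_offset) >= 2.0 * swing:
            raise ParameterError("left_right_swing_offset exceeds the swing time")


@dataclass(frozen=True)
class ImuRecording:
    """One foot's IMU trace: tri-axial acceleration (g) and angular rate (deg/s)."""

    side: str
    time: np.ndarray
    accel_ap: np.ndarray
    accel_vert: np.ndarray
    accel_ml: np.ndarray
    gyro_x: np.ndarray
    gyro_y: np.ndarray
    gyro_z: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("accel_ap", "accel_vert", "accel_ml", "gyro_x", "gyro_y", "gyro_z"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"channel {name} length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class GroundTruth:
    """Planted event indices per side plus the steady-state sample window."""

    hs_samples: Mapping[str, np.ndarray]
    to_samples: Mapping[str, np.ndarray]
    steady_start: int
    steady_end: int

    def steady_hs(self, side: str) -> np.ndarray:
        hs = self.hs_samples[side]
        return hs[(hs >= self.steady_start) & (hs <= self.steady_end)]

    def steady_to(self, side: str) -> np.ndarray:
        to = self.to_samples[side]
        return to[(to >= self.steady_start) & (to <= self.steady_end)]


@dataclass(frozen=True)
class WalkSimulation:
    left: ImuRecording
    right: ImuRecording
    truth: GroundTruth

    @property
    def recordings(self) -> dict[str, ImuRecording]:
        return {"left": self.left, "right": self.right}


def _stride_schedule(plan: GaitPlan, rng: np.random.Generator) -> np.ndarray:
    """Per-stride durations: ramped transients, then steady strides, then ramps."""
    nt = plan.n_transient_strides
    steady = plan.stride_time_mean + plan.stride_time_sd * rng.standard_normal(plan.n_strides)
    steady = np.clip(steady, 0.3 * plan.stride_time_mean, None)
    if nt == 0:
        return steady
    accel = np.linspace(_TRANSIENT_RAMP, 1.0, nt + 1)[:-1] * plan.stride_time_mean
    decel = np.linspace(1.0, _TRANSIENT_RAMP, nt + 1)[1:] * plan.stride_time_mean
    return np.concatenate([accel, steady, decel])


def _plant_pulses(time: np.ndarray, event_times: np.ndarray) -> np.ndarray:
    out = np.zeros_like(time)
    for t0 in event_times:
        out += _PULSE_AMPLITUDE_G * np.exp(-0.5 * ((time - t0) / _PULSE_SIGMA_S) ** 2)
    return out


def simulate_imu_walk(plan: GaitPlan) -> WalkSimulation:
    """Simulate a two-foot walk; peaks of the AP channel mark heel strikes,
    peaks of the vertical channel mark toe-offs, at known sample indices.

    Transient (acceleration/deceleration) strides with linearly ramped
    durations are prepended/appended; the steady-state window in the returned
    :class:`GroundTruth` excludes them.
    """
    fs = plan.sampling_rate
    dt = 1.0 / fs
    ss = np.random.SeedSequence(plan.seed)
    rng_sched, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    start_pad = 0.5
    hs_times: dict[str, np.ndarray] = {}
    to_times: dict[str, np.ndarray] = {}
    for side in SIDES:
        strides = _stride_schedule(plan, rng_sched)
        # quantize each stride and stance duration to the sample grid so the
        # planted schedule is exactly representable (zero-noise oracle)
        strides = np.round(strides * fs) / fs
        t0 = start_pad + (0.5 * plan.stride_time_mean if side == "right" else 0.0)
        t0 = np.round(t0 * fs) / fs
        hs = t0 + np.concatenate([[0.0], np.cumsum(strides)])
        # swing asymmetry: left swing lengthened, right shortened by offset/2
        swing = (1.0 - plan.stance_fraction) * strides
        swing = swing + (0.5 if side == "left" else -0.5) * plan.left_right_swing_offset
        stance = np.round((strides - swing) * fs) / fs
        to = hs[:-1] + stance
        hs_times[side] = np.round(hs * fs) / fs
        to_times[side] = np.round(to * fs) / fs

    t_end = max(hs_times[s][-1] for s in SIDES) + start_pad
    n = int(round(t_end * fs)) + 1
    time = np.arange(n) * dt

    hs_idx = {s: np.round(hs_times[s] * fs).astype(int) for s in SIDES}
    to_idx = {s: np.round(to_times[s] * fs).astype(int) for s in SIDES}

    nt = plan.n_transient_strides
    steady_start = min(hs_idx[s][nt] for s in SIDES)
    steady_end = max(hs_idx[s][nt + plan.n_strides] for s in SIDES)
    truth = GroundTruth(hs_samples=hs_idx, to_samples=to_idx,
                        steady_start=steady_start, steady_end=steady_end)

    cycle_hz = 1.0 / plan.stride_time_mean
    recs: dict[str, ImuRecording] = {}
    for side in SIDES:
        base = _BASELINE_AMPLITUDE_G * np.sin(2 * np.pi * cycle_hz * time)
        ap = base + _plant_pulses(time, hs_times[side])
        vert = base * 0.8 + _plant_pulses(time, to_times[side]) + 1.0  # gravity offset
        ml = _BASELINE_AMPLITUDE_G * np.cos(2 * np.pi * cycle_hz * time)
        noise = lambda: plan.noise_sd * rng_noise.standard_normal(n)  # noqa: E731
        gyro_scale = 40.0  # deg/s swing-phase rotation, plumbing only
        recs[side] = ImuRecording(
            side=side,
            time=time,
            accel_ap=np.clip(ap + noise(), -ACCEL_RANGE_G, ACCEL_RANGE_G),
            accel_vert=np.clip(vert + noise(), -ACCEL_RANGE_G, ACCEL_RANGE_G),
            accel_ml=np.clip(ml + noise(), -ACCEL_RANGE_G, ACCEL_RANGE_G),
            gyro_x=np.clip(gyro_scale * np.sin(2 * np.pi * cycle_hz * time)
                           + 50 * plan.noise_sd * rng_noise.standard_normal(n),
                           -GYRO_RANGE_DPS, GYRO_RANGE_DPS),
            gyro_y=np.clip(gyro_scale * np.cos(2 * np.pi * cycle_hz * time)
                           + 50 * plan.noise_sd * rng_noise.standard_normal(n),
                           -GYRO_RANGE_DPS, GYRO_RANGE_DPS),
            gyro_z=np.clip(50 * plan.noise_sd * rng_noise.standard_normal(n),
                           -GYRO_RANGE_DPS, GYRO_RANGE_DPS),
            sampling_rate=fs,
        )
    return WalkSimulation(left=recs["left"], right=recs["right"], truth=truth)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

_TABLE_DEMOGRAPHICS = {
    #               high-risk         low-risk
    "age":            ((74.2, 5.4), (72.2, 4.9)),
    "bmi":            ((25.1, 3.1), (24.5, 2.7)),
    "pa_met_min_wk":  ((1389.7, 1409.7), (2182.6, 1932.4)),
    "education_level": ((1.7, 1.1), (2.3, 1.1)),
    "mmse":           ((25.7, 3.3), (26.9, 2.6)),
}

_TABLE_GAIT = {
    "slower": {
        "walking_speed":   ((0.8, 0.1), (0.9, 0.1)),
        "stride_length":   ((1.1, 0.1), (1.2, 0.1)),
        "cadence":         ((97.9, 11.1), (97.7, 10.7)),
        "stance_phase":    ((59.5, 1.7), (59.0, 1.6)),
        "stride_time":     ((1.2, 0.1), (1.2, 0.1)),
        "cv_stride_length": ((3.0, 1.4), (2.5, 1.2)),
        "cv_stance_phase": ((5.0, 2.5), (4.2, 2.0)),
        "cv_stride_time":  ((3.0, 1.4), (2.5, 1.1)),
        "gait_asymmetry":  ((2.8, 2.6), (2.5, 2.3)),
    },
    "preferred": {
        "walking_speed":   ((1.1, 0.2), (1.2, 0.2)),
        "stride_length":   ((1.1, 0.2), (1.3, 0.1)),
        "cadence":         ((114.8, 10.3), (116.7, 10.1)),
        "stance_phase":    ((58.0, 1.8), (57.2, 1.6)),
        "stride_time":     ((1.0, 0.1), (1.0, 0.1)),
        "cv_stride_length": ((2.2, 1.3), (1.9, 0.9)),
        "cv_stance_phase": ((3.3, 2.0), (2.8, 1.4)),
        "cv_stride_time":  ((2.2, 1.3), (1.9, 0.9)),
        "gait_asymmetry":  ((2.1, 2.1), (2.0, 2.0)),
    },
    "faster": {
        "walking_speed":   ((1.4, 0.2), (1.5, 0.2)),
        "stride_length":   ((1.3, 0.2), (1.4, 0.2)),
        "cadence":         ((127.8, 12.1), (131.8, 11.1)),
        "stance_phase":    ((56.3, 1.9), (55.3, 1.7)),
        "stride_time":     ((0.9, 0.1), (0.9, 0.1)),
        "cv_stride_length": ((2.0, 1.3), (1.7, 0.8)),
        "cv_stance_phase": ((2.6, 1.4), (2.2, 1.1)),
        "cv_stride_time":  ((2.0, 1.3), (1.7, 0.8)),
        "gait_asymmetry":  ((2.3, 2.2), (1.9, 1.8)),
    },
}


def continuous_feature_names() -> list[str]:
    """Ordered list of the continuous generated features (demographics + gait)."""
    names = list(DEMOGRAPHIC_VARIABLES)
    for speed in SPEEDS:
        names.extend(f"{speed}_{v}" for v in GAIT_VARIABLES)
    return names


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for a synthetic participant cohort.

    ``distributions[group][feature] == (mean, sd)`` for each continuous
    feature; ``group`` is ``"high"`` or ``"low"``.  ``feature_correlation``
    is either ``None`` (independent draws — easier than the real, correlated
    task) or a positive semi-definite matrix over
    :func:`continuous_feature_names` applied as a Gaussian copula.
    """

    n_participants: int = 746
    p_high_risk: float = 290 / 746
    distributions: Mapping[str, Mapping[str, tuple[float, float]]] = field(default_factory=dict)
    feature_correlation: np.ndarray | None = None
    p_female: float = 0.5
    exact_stratification: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be positive")
        if not 0.0 <= self.p_high_risk <= 1.0:
            raise ParameterError("p_high_risk must lie in [0, 1]")
        names = continuous_feature_names()
        for group in ("high", "low"):
            if group not in self.distributions:
                raise ParameterError(f"missing distributions for group {group!r}")
            missing = [v for v in names if v not in self.distributions[group]]
            if missing:
                raise ParameterError(f"group {group!r} missing features: {missing}")
            for v in names:
                _, sd = self.distributions[group][v]
                if sd < 0:
                    raise ParameterError(f"negative SD for {group}/{v}")
        if self.feature_correlation is not None:
            corr = np.asarray(self.feature_correlation, dtype=float)
            k = len(names)
            if corr.shape != (k, k):
                raise ParameterError(f"feature_correlation must be {k}x{k}")
            eig = np.linalg.eigvalsh((corr + corr.T) / 2)
            if eig.min() < -1e-8:
                raise ParameterError("feature_correlation is not positive semi-definite")


def default_cohort_spec(n_participants: int = 746, seed: int = 0,
                        exact_stratification: bool = True) -> CohortSpec:
    """Cohort spec whose per-group means/SDs equal the reference group tables
    (demographics and 9 gait variables x 3 speeds), with a 290/746 high-risk
    fraction."""
    dists: dict[str, dict[str, tuple[float, float]]] = {"high": {}, "low": {}}
    for var, (hi, lo) in _TABLE_DEMOGRAPHICS.items():
        dists["high"][var] = hi
        dists["low"][var] = lo
    for speed in SPEEDS:
        for var, (hi, lo) in _TABLE_GAIT[speed].items():
            dists["high"][f"{speed}_{var}"] = hi
            dists["low"][f"{speed}_{var}"] = lo
    return CohortSpec(
        n_participants=n_participants,
        p_high_risk=290 / 746,
        distributions=dists,
        exact_stratification=exact_stratification,
        seed=seed,
    )


def _draw_group_features(spec: CohortSpec, group: str, n: int,
                         rng: np.random.Generator) -> pd.DataFrame:
    names = continuous_feature_names()
    means = np.array([spec.distributions[group][v][0] for v in names])
    sds = np.array([spec.distributions[group][v][1] for v in names])
    if spec.feature_correlation is None:
        z = rng.standard_normal((n, len(names)))
    else:
        corr = np.asarray(spec.feature_correlation, dtype=float)
        # eigendecomposition copula root: tolerant of PSD (rank-deficient) input
        w, v = np.linalg.eigh((corr + corr.T) / 2)
        root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        z = rng.standard_normal((n, len(names))) @ root.T
    return pd.DataFrame(means + sds * z, columns=names)


def simulate_cohort(spec: CohortSpec,
                    rule: risk.RiskRule | None = None) -> pd.DataFrame:
    """Draw a cohort table: one row per participant.

    Columns: ``participant_id``, demographics (incl. ``sex``: 1 = female),
    questionnaire (``fell_6mo``, ``n_falls_6mo``, ``fear_of_falling``),
    ``risk_label`` (1 = high risk), and ``<speed>_<gait variable>`` columns.
    The questionnaire is synthesized by inverting ``rule`` so that
    :func:`gaitfall.risk.classify_fall_risk` reproduces ``risk_label``.
    """
    rule = rule if rule is not None else risk.default_rule()
    ss = np.random.SeedSequence(spec.seed)
    rng_label, rng_feat, rng_q = (np.random.default_rng(s) for s in ss.spawn(3))

    n = spec.n_participants
    if spec.exact_stratification:
        n_high = int(round(n * spec.p_high_risk))
        labels = np.zeros(n, dtype=int)
        labels[rng_label.choice(n, size=n_high, replace=False)] = 1
    else:
        labels = (rng_label.random(n) < spec.p_high_risk).astype(int)

    frames = []
    for group, value in (("high", 1), ("low", 0)):
        idx = np.flatnonzero(labels == value)
        feats = _draw_group_features(spec, group, len(idx), rng_feat)
        feats.index = idx
        frames.append(feats)
    features = pd.concat(frames).sort_index()

    questionnaires = [risk.sample_questionnaire(int(lbl), rule, rng_q) for lbl in labels]
    out = pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "sex": (rng_feat.random(n) < spec.p_female).astype(int),
        "fell_6mo": [int(q.fell_6mo) for q in questionnaires],
        "n_falls_6mo": [q.n_falls_6mo for q in questionnaires],
        "fear_of_falling": [int(q.fear_of_falling) for q in questionnaires],
        "risk_label": labels,
    })
    out = pd.concat([out, features], axis=1)
    ordered = (["participant_id"] + list(DEMOGRAPHIC_VARIABLES) + ["sex"]
               + ["fell_6mo", "n_falls_6mo", "fear_of_falling", "risk_label"]
               + [c for c in features.columns if c not in DEMOGRAPHIC_VARIABLES])
    return out[ordered]


def with_mean_shift(spec: CohortSpec, feature: str, delta: float,
                    group: str = "high") -> CohortSpec:
    """Return a copy of ``spec`` with one group mean shifted by ``delta``
    (used to study separability as a function of between-group gap)."""
    dists = {g: dict(v) for g, v in spec.distributions.items()}
    mean, sd = dists[group][feature]
    dists[group][feature] = (mean + delta, sd)
    return replace(spec, distributions=dists)
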