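"""Plain-text interchange formats.

* IMU CSV (one file per foot): ``time_s, accel_ap_g, accel_vert_g,
  accel_ml_g, gyro_x_dps, gyro_y_dps, gyro_z_dps`` with a mandatory header,
  plus a JSON sidecar holding ``sampling_rate``, ``side``, and (for
  synthetic data) the planted ground truth.
* Events CSV: ``side, event_type, sample_index, time_s``.
* Cohort CSV: one row per participant (see ``synthetic.simulate_cohort``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gaitfall.errors import SchemaError
from gaitfall.signal_processing import EventSeries
from gaitfall.synthetic import GroundTruth, ImuRecording, WalkSimulation

IMU_COLUMNS = ["time_s", "accel_ap_g", "accel_vert_g", "accel_ml_g",
               "gyro_x_dps", "gyro_y_dps", "gyro_z_dps"]


def write_imu_csv(recording: ImuRecording, path: Path,
                  truth: GroundTruth | None = None) -> None:
    path = Path(path)
    pd.DataFrame({
        "time_s": recording.time,
        "accel_ap_g": recording.accel_ap,
        "accel_vert_g": recording.accel_vert,
        "accel_ml_g": recording.accel_ml,
        "gyro_x_dps": recording.gyro_x,
        "gyro_y_dps": recording.gyro_y,
        "gyro_z_dps": recording.gyro_z,
    }).to_csv(path, index=False)
    sidecar = {"sampling_rate": recording.sampling_rate, "side": recording.side}
    if truth is not None:
        sidecar["ground_truth"] = {
            "hs_samples": {s: np.asarray(v).tolist()
                           for s, v in truth.hs_samples.items()},
            "to_samples": {s: np.asarray(v).tolist()
                           for s, v in truth.to_samples.items()},
            "steady_start": int(truth.steady_start),
            "steady_end": int(truth.steady_end),
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_imu_csv(path: Path) -> ImuRecording:
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"IMU CSV missing column(s): {', '.join(missing)}")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ImuRecording(
        side=sidecar["side"],
        time=table["time_s"].to_numpy(),
        accel_ap=table["accel_ap_g"].to_numpy(),
        accel_vert=table["accel_vert_g"].to_numpy(),
        accel_ml=table["accel_ml_g"].to_numpy(),
        gyro_x=table["gyro_x_dps"].to_numpy(),
        gyro_y=table["gyro_y_dps"].to_numpy(),
        gyro_z=table["gyro_z_dps"].to_numpy(),
        sampling_rate=float(sidecar["sampling_rate"]),
    )


def write_walk(sim: WalkSimulation, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for side, rec in sim.recordings.items():
        write_imu_csv(rec, out_dir / f"{side}.csv", truth=sim.truth)


def write_events_csv(events: EventSeries, path: Path) -> None:
    rows = []
    for side in events.hs:
        for kind, indices in (("hs", events.hs[side]), ("to", events.to[side])):
            for idx in np.asarray(indices):
                rows.append({"side": side, "event_type": kind,
                             "sample_index": int(idx),
                             "time_s": idx / events.sampling_rate})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path: Path, sampling_rate: float) -> EventSeries:
    table = pd.read_csv(path)
    required = {"side", "event_type", "sample_index"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"events CSV missing column(s): {', '.join(sorted(missing))}")
    hs, to = {}, {}
    for side, group in table.groupby("side"):
        hs[side] = np.sort(group.loc[group.event_type == "hs",
                                     "sample_index"].to_numpy(int))
        to[side] = np.sort(group.loc[group.event_type == "to",
                                     "sample_index"].to_numpy(int))
    return EventSeries(hs=hs, to=to, sampling_rate=sampling_rate)
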