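"""Serialization of sessions, spike trains and photometry recordings.

Event tables go to CSV (event_type, onset_s, offset_s), spike trains to an
HDF5 group per unit (with a CSV fallback), photometry to HDF5 with a
sampling-rate attribute, and configs to YAML.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .task_synth import (
    PhotometryRecording,
    SessionEvents,
    SpikeTrain,
    SyntheticSession,
    UnitGroundTruth,
)

__all__ = [
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
    "write_spike_trains_hdf5",
    "read_spike_trains_hdf5",
    "write_spike_trains_csv",
    "write_photometry_hdf5",
    "read_photometry_hdf5",
    "write_config_yaml",
    "read_config_yaml",
    "session_checksum_payload",
]


def events_to_frame(events: SessionEvents) -> pd.DataFrame:
    rows = []
    for t in np.asarray(events.cue_onsets_s, float):
        rows.append(("cue", t, t + events.cue_duration_s))
    for t in np.asarray(events.reward_times_s, float):
        rows.append(("reward", t, t))
    for on, off in events.lick_bouts:
        rows.append(("lick", on, off))
    for on, off in events.movement_bouts:
        rows.append(("movement", on, off))
    df = pd.DataFrame(rows, columns=["event_type", "onset_s", "offset_s"])
    df.attrs["session_duration_s"] = events.session_duration_s
    return df


def write_events_csv(events: SessionEvents, path: str | Path) -> None:
    df = events_to_frame(events)
    # keep the session duration on a comment line so the table round-trips
    with open(path, "w") as fh:
        fh.write(f"# session_duration_s={events.session_duration_s!r}\n")
        df.to_csv(fh, index=False)


def read_events_csv(path: str | Path) -> SessionEvents:
    with open(path) as fh:
        header = fh.readline()
        duration = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    cues = df.loc[df.event_type == "cue"]
    rewards = df.loc[df.event_type == "reward", "onset_s"].to_numpy()
    cue_dur = float((cues.offset_s - cues.onset_s).iloc[0]) if len(cues) else 1.0
    licks = [(r.onset_s, r.offset_s) for r in df[df.event_type == "lick"].itertuples()]
    moves = [(r.onset_s, r.offset_s) for r in df[df.event_type == "movement"].itertuples()]
    return SessionEvents(cues.onset_s.to_numpy(), rewards, licks, moves,
                         duration, cue_duration_s=cue_dur)


def write_spike_trains_hdf5(session: SyntheticSession, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for train in session.spike_trains:
            g = f.create_group(train.unit_id)
            g.create_dataset("spike_times_s", data=np.asarray(train.spike_times_s, float))
            truth = session.ground_truth[train.unit_id]
            g.attrs["population"] = truth.population
            g.attrs["encoded"] = ",".join(sorted(truth.encoded))
            g.attrs["dominant"] = truth.dominant


def read_spike_trains_hdf5(path: str | Path) -> tuple[list[SpikeTrain], dict[str, UnitGroundTruth]]:
    trains, truth = [], {}
    with h5py.File(path, "r") as f:
        for unit_id in sorted(f.keys()):
            g = f[unit_id]
            trains.append(SpikeTrain(unit_id, g["spike_times_s"][...]))
            encoded = frozenset(x for x in str(g.attrs["encoded"]).split(",") if x)
            truth[unit_id] = UnitGroundTruth(str(g.attrs["population"]),
                                             encoded, str(g.attrs["dominant"]))
    return trains, truth


def write_spike_trains_csv(session: SyntheticSession, path: str | Path) -> None:
    rows = []
    for train in session.spike_trains:
        pop = session.ground_truth[train.unit_id].population
        for t in np.asarray(train.spike_times_s, float):
            rows.append((train.unit_id, pop, t))
    pd.DataFrame(rows, columns=["unit_id", "population", "spike_time_s"]).to_csv(
        path, index=False)


def write_photometry_hdf5(rec: PhotometryRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=np.asarray(rec.activity, float))
        f.create_dataset("reference", data=np.asarray(rec.reference, float))
        f.attrs["fs_hz"] = rec.fs_hz


def read_photometry_hdf5(path: str | Path,
                         events: SessionEvents | None = None) -> PhotometryRecording:
    with h5py.File(path, "r") as f:
        return PhotometryRecording(f["activity"][...], f["reference"][...],
                                   float(f.attrs["fs_hz"]), events=events)


def write_config_yaml(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def session_checksum_payload(session: SyntheticSession) -> bytes:
    """Canonical byte serialization of a session, for determinism checks."""
    payload = {
        "cues": np.asarray(session.events.cue_onsets_s).tolist(),
        "rewards": np.asarray(session.events.reward_times_s).tolist(),
        "licks": session.events.lick_bouts,
        "moves": session.events.movement_bouts,
        "units": {t.unit_id: np.asarray(t.spike_times_s).tolist()
                  for t in session.spike_trains},
        "truth": {u: [g.population, sorted(g.encoded), g.dominant]
                  for u, g in session.ground_truth.items()},
    }
    return json.dumps(payload, sort_keys=True).encode()
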