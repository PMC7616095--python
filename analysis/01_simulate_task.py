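#!/usr/bin/env python
"""Generate the synthetic study data: one Pavlovian session per
projection-defined population (DMS, DLS, VLS, NAc core) with spike trains
and ground-truth encoding labels.

Writes events.csv and spikes_<population>.h5 under the results directory and
prints the session layout (trial count, cue-reward delay, ITI statistics).
"""
import argparse
from pathlib import Path

import numpy as np

from dopadist import io as did_io
from dopadist.pipeline import simulate_stage, validate_config
from dopadist.task_synth import POPULATIONS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = validate_config({"seed": args.seed})
    sessions = simulate_stage(config)
    first = sessions[POPULATIONS[0]]
    did_io.write_events_csv(first.events, args.out / "events.csv")
    for pop, session in sessions.items():
        did_io.write_spike_trains_hdf5(session, args.out / f"spikes_{pop}.h5")
        did_io.write_events_csv(session.events, args.out / f"events_{pop}.csv")

    cues = np.asarray(first.events.cue_onsets_s)
    rewards = np.asarray(first.events.reward_times_s)
    itis = cues[1:] - rewards[:-1]
    print(f"populations: {', '.join(sessions)}")
    print(f"trials per session: {len(cues)}; cue->reward delay "
          f"{set(np.round(rewards - cues, 9))} s")
    print(f"ITI range [{itis.min():.2f}, {itis.max():.2f}] s, "
          f"median {np.median(itis):.2f} s")
    for pop, session in sessions.items():
        rates = [len(t.spike_times_s) / session.events.session_duration_s
                 for t in session.spike_trains]
        print(f"{pop}: {len(rates)} units, mean session rate "
              f"{np.mean(rates):.2f} Hz")


if __name__ == "__main__":
    main()
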