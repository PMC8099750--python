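#!/usr/bin/env python
"""Derive per-sample flight-state variables for every track.

Reads the track CSV, smooths positions (Savitzky-Golay), computes approach
velocity V, acceleration A, relative rate of expansion r = V/y and time to
contact tau = y/V, and writes one long-form kinematics CSV.
"""

import argparse
from pathlib import Path

import pandas as pd

import beeland as bl
from beeland.kinematics import kinematics_frame


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = bl.PipelineConfig()
    tracks = bl.read_tracks(args.in_dir / "tracks.csv")
    frames, n_decel = [], 0
    for tr in tracks:
        kt = bl.compute_state_variables(tr, cfg)
        frames.append(kinematics_frame(kt))
        n_decel += len(bl.deceleration_phases(kt))
    out = pd.concat(frames, ignore_index=True)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out_dir / "kinematics.csv", index=False,
               float_format="%.8g")
    print(f"computed state variables for {len(tracks)} tracks "
          f"({n_decel} deceleration phases)")
    print(f"  -> {args.out_dir/'kinematics.csv'}")


if __name__ == "__main__":
    main()
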