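#!/usr/bin/env python
"""Qualify, classify and segment every simulated track.

Reads the track CSVs written by 01_simulate_cohorts.py, applies the
qualification filter (>=1.31 um long, >=6.55 um total path, >=3 successive
frames), classifies each qualifying filament's preferred direction (70% of
moving time), segments bouts, and writes per-condition bout and track-class
tables under results/.  Prints pooled bout statistics per direction.
"""

from pathlib import Path

import pandas as pd

from nfkin.pipeline import analyze_movie, bouts_to_frame
from nfkin.track_core import read_movie_metadata, read_tracks

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"


def main() -> None:
    for cond_dir in sorted(SIM.iterdir()):
        if not cond_dir.is_dir():
            continue
        analyses = []
        for csv in sorted(cond_dir.glob("*.csv")):
            meta = read_movie_metadata(csv.with_suffix("").with_suffix(
                ".meta.json"))
            analyses.append(analyze_movie(read_tracks(csv, meta)))
        cond = cond_dir.name
        bouts = bouts_to_frame(analyses)
        bouts.to_csv(ROOT / "results" / f"bouts_{cond}.csv", index=False)
        classes = pd.DataFrame([vars(c) for a in analyses for c in a.classes])
        classes.to_csv(ROOT / "results" / f"trackclass_{cond}.csv", index=False)

        scored = bouts[bouts.truncated == "none"]
        print(f"\n{cond}: {len(classes)} qualifying filaments, "
              f"{len(scored)} complete bouts")
        for direction in ("anterograde", "retrograde"):
            sel = scored[scored.direction == direction]
            if len(sel):
                print(f"  {direction:11s}: n={len(sel):4d}  "
                      f"velocity {sel.velocity_um_s.mean():.3f} um/s  "
                      f"duration {sel.duration_s.mean():5.1f} s  "
                      f"distance {sel.distance_um.mean():.2f} um")


if __name__ == "__main__":
    main()
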