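#!/usr/bin/env python
"""Simulate the three experimental arms and write them to disk.

Generates study-sized cohorts of 15-minute movies (4-s frames) from the
calibrated condition presets — 51 control, 40 mutant (N256S-kinesin-1A),
50 wild-type-overexpression — and writes one track CSV plus a JSON metadata
sidecar per movie under scratch/sim/<condition>/ (bulk
intermediates; derived tables land in results/).
"""

import json
from pathlib import Path

from nfkin.motion_sim import get_preset
from nfkin.pipeline import simulate_cohort
from nfkin.track_core import write_movie_metadata, write_tracks

BASE_SEED = 20101
COHORTS = {"control": 51, "n256s": 40, "wt_overexpression": 50}
OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim"


def main() -> None:
    for offset, (condition, n_movies) in enumerate(COHORTS.items()):
        out_dir = OUT / condition
        out_dir.mkdir(parents=True, exist_ok=True)
        sims = simulate_cohort(get_preset(condition), n_movies,
                               base_seed=BASE_SEED + offset)
        n_tracks = 0
        for sim in sims:
            write_tracks(sim.movie, out_dir / f"{sim.movie.movie_id}.csv")
            write_movie_metadata(sim.movie,
                                 out_dir / f"{sim.movie.movie_id}.meta.json")
            truth = {
                tid: {"primary_direction": tt.primary_direction,
                      "bouts": [vars(b) for b in tt.bouts]}
                for tid, tt in sim.truth.items()
            }
            (out_dir / f"{sim.movie.movie_id}.truth.json").write_text(
                json.dumps(truth, indent=1))
            n_tracks += sim.movie.n_tracks
        print(f"{condition}: {n_movies} movies, {n_tracks} filaments "
              f"-> {out_dir}")


if __name__ == "__main__":
    main()
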