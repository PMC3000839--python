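# nfkin — neurofilament transport kinetics

Neurofilaments, the intermediate filaments of neurons, are shipped along
axons in a rapid, intermittent, bidirectional fashion: short bouts of
directed movement separated by long pauses, with occasional reversals.
Experiments probing this traffic (for example, the effect of the SPG10
hereditary-spastic-paraplegia mutation N256S in the kinesin-1A/KIF5A motor)
quantify it from time-lapse movies of single filaments moving through gaps
in the axonal neurofilament array. `nfkin` implements that quantification
as a tested Python pipeline, together with a calibrated stop-and-go motion
simulator that provides ground truth for every stage.

For a filament tracked at frame interval Δt with axial positions x_t
(anterograde positive), the pipeline computes:

- **Qualification**: analyze objects ≥ 10 px (1.31 μm) long that move a
  total path Σ|Δx| ≥ 50 px (6.55 μm) over ≥ 3 successive frames.
- **Bouts**: maximal runs of same-direction moving intervals
  (|Δx| > ε = 1 px) delimited by pauses, reversals, or the track boundary;
  v_bout = distance/duration; boundary-truncated bouts are excluded from
  bout statistics.
- **Direction class**: anterograde/retrograde if ≥ 70 % of moving time is
  in that direction, else bidirectional ("dual" — counted as separate
  anterograde and retrograde events).
- **Frequency** f_dir = n_dir · 3600/T (filaments/hour) and **flux**
  Φ_dir = Σ d_dir · 3600/T (μm/axon/hour) per movie.
- **Mann–Whitney U** (two-sided; exact for small tie-free samples) for
  between-condition comparisons, and **EB1 comet** regression velocities
  with a polarity census for microtubule orientation.

## Layout

- `src/nfkin/` — the library: `track_core` (data model + CSV I/O),
  `motion_sim` (condition presets + generator), `bout_kinetics`
  (segmentation/classification), `transport_stats` (frequency, flux,
  histograms, rank-sum tests), `kymo_eb1` (kymographs, comet velocimetry),
  `axon_image` (synthetic fluorescence rendering, distal-axon intensity),
  `pipeline` (end-to-end glue).
- `analysis/01…05_*.py` — numbered drivers that simulate the three
  experimental arms, run the pipeline, and write tables under `results/`.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.

## Worked example

```python
from nfkin import get_preset, simulate_movie, analyze_movie

sim = simulate_movie(get_preset("control"), seed=42)
res = analyze_movie(sim.movie)
print(f"{res.summary.n_qualifying_tracks} qualifying filaments")
print(f"freq A/R: {res.summary.freq_antero_per_hr:.1f}/"
      f"{res.summary.freq_retro_per_hr:.1f} per hr")
print(f"flux A/R: {res.summary.flux_antero_um_per_hr:.0f}/"
      f"{res.summary.flux_retro_um_per_hr:.0f} um/axon/hr")
for b in res.bouts[:3]:
    print(f"{b.direction:11s} {b.distance_um:5.2f} um in {b.duration_s:4.0f} s"
          f" -> {b.velocity_um_s:.2f} um/s [{b.truncated}]")
```

prints

```
3 qualifying filaments
freq A/R: 8.0/4.0 per hr
flux A/R: 280/133 um/axon/hr
anterograde  4.09 um in   20 s -> 0.20 um/s [none]
anterograde  4.49 um in   24 s -> 0.19 um/s [none]
anterograde  3.70 um in   24 s -> 0.15 um/s [none]
```

— one 15-minute control movie: three filaments qualified (two anterograde,
one retrograde preferred), and the per-movie frequency (counts × 4/hr) and
directed distance × 4 (flux) follow. Averaged over hundreds of simulated
movies these recover the control preset's 4.5/3.2 filaments/hr and
149/116 μm/axon/hr.

The analysis drivers run in order:

```
python analysis/01_simulate_cohorts.py   # 51/40/50 movies -> scratch/sim/
python analysis/02_segment_bouts.py      # bout & track-class tables
python analysis/03_transport_stats.py    # summaries, histograms, rank-sum tests
python analysis/04_eb1_polarity.py       # comet census + kymograph
python analysis/05_distal_intensity.py   # distal-axon null comparison
```

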