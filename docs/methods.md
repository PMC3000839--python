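# Methods

## The measurement problem

Neurofilaments move along axons in a stop-and-go fashion: brief bouts of
rapid directed movement (tenths of a μm/s) separated by pauses, with
occasional reversals. Live-cell recordings of such motion are summarized by
a small set of kinetic statistics, and this package implements that
summarization as a tested pipeline:

- **Qualification.** An object enters the analysis if it is ≥ 10 pixels
  (1.31 μm) long, moves a total distance of ≥ 50 pixels (6.55 μm), and can
  be tracked through ≥ 3 successive frames. The pixel size of 0.131 μm/px is
  fixed by the two printed pixel↔μm pairs and stored per movie so other
  optics can be used.
- **Bout segmentation.** A bout is a period of uninterrupted movement
  between two pauses, or between a pause and a reversal. Bout velocity is
  bout distance over bout duration. Bouts in progress at the track's first
  or last frame are flagged truncated and excluded from bout statistics
  (their duration is not assessable) but their distance still counts toward
  flux.
- **Direction classification.** A filament moving ≥ 70 % of its *moving*
  time in one direction has a preferred direction; the remainder ("dual")
  are treated as separate anterograde and retrograde moving events.
- **Frequency** = qualifying filaments per direction per movie × 3600/T
  (filaments/hour; dual filaments add one to each direction).
  **Flux** = total directed distance of all qualifying filaments per
  direction × 3600/T (μm/axon/hour; each movie images one axon).
- **Group comparison.** Mann–Whitney U, two-sided, midranks for ties:
  exact enumeration when n₁+n₂ ≤ 12 and tie-free, else normal approximation
  with tie and continuity corrections (scipy.stats.mannwhitneyu supplies
  the distributions; an independent full-enumeration oracle checks the
  exact path in the tests).
- **EB1 comets.** Comet velocity is the least-squares slope of position
  against time over the whole trace (comets do not pause in the model);
  the sign census over many comets reports microtubule polarity.
  Kymographs are built by bilinear resampling of each frame along the axon
  path (rows = time, columns = position).

## Decisions the data definitions leave open

These points are underdetermined by the verbal definitions above; the
package pins them as follows (each is isolated behind `AnalysisConfig`
where configurable):

- **Pause criterion.** No numeric pause threshold is part of the bout
  definition. We call an interval a pause when |Δx| ≤ 1 pixel (0.131 μm,
  i.e. < 0.033 μm/s at 4-s frames): one pixel is the camera's localization
  quantum and sits far below bout velocities of 0.23–0.40 μm/s. The
  boundary case |Δx| = ε is a pause.
- **"Total distance" in the 50-px filter** is path length (Σ|Δx|), not net
  displacement — filaments reverse, and net displacement would disqualify
  genuine out-and-back movers. Pause-interval jitter (≤ ε per interval) is
  excluded from the path sum, which also makes anterograde + retrograde
  directed distance ≡ total path an exact identity.
- **"70 % of their time"** counts moving time only; pauses are excluded
  from the denominator. The boundary (exactly 70 %) is classified as
  having a preferred direction (inclusive ≥).
- **Minimum bout** is a single frame-to-frame interval between delimiters;
  a reversal terminates a bout even without an intervening pause.
- **Missing frames** (e.g. refocusing) leave their spanning interval
  unscored: it is neither a pause nor part of a bout, and it interrupts the
  "successive frames" run used by qualification. Gap detection treats any
  interval > 1.5× the frame interval as a gap.
- **Bout metrics are pooled over bouts** across movies (bout histograms
  count bouts), whereas **frequency and flux are averaged per movie**
  (each movie contributes one value per direction).

## The synthetic-data generator

`motion_sim` generates whole movies (default 15 min at 4-s frames) whose
analyzable kinetics match a `ConditionPreset`. Presets carry per-direction
frequency (filaments/hr), flux (μm/axon/hr), bout-velocity and
bout-duration means, and the three built-ins encode the published arms:

| preset | freq A/R (/hr) | flux A/R (μm/axon/hr) | bout v A/R (μm/s) | bout dur A/R (s) |
|---|---|---|---|---|
| control | 4.5 / 3.2 | 149 / 116 | 0.27 / 0.32 | 19 / 11 |
| n256s | 1.4 / 2.0 | 46 / 90 | 0.24 / 0.40 | 19 / 15 |
| wt_overexpression | 3.7 / 3.1 | 109 / 105 | 0.23 / 0.30 | 15 / 14 |

Structure of one movie:

- Filament counts per direction class are Poisson with mean
  `freq_per_hr × T/3600`.
- Each filament runs an itinerary `pause, bout, pause, …, bout, pause` with
  a Poisson number of bouts whose mean closes the flux identity
  `flux = freq × n_bouts × E[V] × E[D]`
  (`calibrate_bouts_per_filament`); under independent velocity and
  duration draws, bout *distance* is emergent rather than separately
  calibrated (the printed triplets are approximately consistent with
  independence, e.g. 0.32 × 11 ≈ 3.5 vs 3.7 μm).
- Bout velocities and durations are Gamma with CV 0.5 (right-skewed,
  strictly positive; the CV is a preset field); pauses are Exponential with
  mean 20 s — pause statistics are unconstrained by any published number
  and affect no recovery target.
- At each bout boundary the direction flips with probability 0.01. This
  value was calibrated once against the published statistic that ~97 % of
  filaments keep a ≥ 70 % preferred direction: a flip mid-itinerary tends
  to persist, so even small per-boundary probabilities produce substantial
  bidirectional minorities (0.05 would leave only ~89 % preferred).
- Filament lengths are log-normal (σ = 0.75) truncated to the observed
  1.3–44.5 μm range, with the location solved numerically so the truncated
  mean is exactly 8.6 μm.

Two deliberate discretization choices make the analyzer's estimates
unbiased rather than systematically inflated:

1. **Frame-grid quantization.** Bout and pause durations are quantized to
   whole frame intervals by stochastic rounding (floor + Bernoulli on the
   fractional part), which preserves the mean exactly (up to a < 1 %
   clamp-at-one-interval effect). Free-phase events would add on average
   one extra partially-moving interval per bout, inflating measured bout
   duration by ~4 s and deflating velocity correspondingly — a bias far
   larger than the 5 % recovery tolerance used in the tests.
2. **Itineraries fit the movie.** The itinerary is placed uniformly among
   start frames that let it finish before the movie ends (overlong
   itineraries start at frame 0 and are truncated, flagged in the ground
   truth). Together with pause-padding at both ends, a complete bout is
   never flush against a track boundary, so boundary-bout exclusion
   discards only genuinely truncated bouts and the full generated flux is
   observed. Without this, uniformly-born filaments would lose ~15 % of
   their distance off the end of the movie and flux recovery would fail.

What the generator does *not* emulate: localization noise on positions
(pauses are exactly stationary), filaments drifting into or out of the
field of view mid-movie, photobleaching, 2-D curvature of the axon, or any
mechanistic motor model (tug-of-war / coordination force balance).
Parameter-recovery tests passing on these simulations therefore validate
the bookkeeping of the pipeline — filtering, segmentation, classification,
scaling — not its robustness to tracking noise.

Residual design couplings worth knowing: dual-class filaments are counted
in both direction frequencies (as in the published analysis), which
inflates recovered frequencies by ~2–3 % relative to the preset value; and
an anterograde-born filament's reversed bouts contribute retrograde
distance drawn with retrograde kinetics, cross-contaminating fluxes by
~±2 % at reversal probability 0.01. Both effects sit well inside the
Monte-Carlo error of 200-movie experiments.

EB1 comets are simulated as constant-velocity traces (Gamma speeds, CV 0.2,
mean 0.13 μm/s; 2-min recordings at 2-s intervals), retrograde with a small
probability; optional Gaussian localization noise exercises the regression
estimator.

## Synthetic imaging

`axon_image.render_stack` deposits objects conservatively (bilinear
splatting of dense sub-pixel samples), blurs with a Gaussian PSF, and adds
background plus Poisson/Gaussian noise, so integrated above-background
signal is exactly proportional to object intensity — the property the
image-level tests lean on. `distal_intensity` measures the mean intensity
in a ±5 px band along the distal window (default 100 μm) of an axon path,
minus the mean of two flanking bands offset 10–15 px; band widths and the
flanking-band background estimate are package choices, as no published
values constrain them. The distal-content comparison is reproduced only as
a null-behavior property on equal-density synthetic cohorts; real
immunofluorescence data are not modeled.

## Problem sizes and numerics

Recovery experiments use 200 movies per condition (Monte-Carlo standard
errors a factor ≥ 3 below the quantities' scale), 500 comets for velocity
recovery, 1000 random tracks for oracle equivalence, and 20 replicate
50-movie-per-arm experiments for the discrimination property; the analysis
drivers use the published cohort sizes (51/40/50 movies). All randomness
flows through `numpy.random.default_rng` with explicit seeds; simulation
is bit-reproducible under a fixed seed. Floating-point identities
(distance conservation, truth tiling) hold to 1e-8 absolute; CSV
round-trips to 1e-6 μm.

## Known limitations

- The control anterograde bout duration (19 s) is only implicitly
  published (stated as unchanged by the mutant); the control preset adopts
  it.
- Tracks are 1-D by construction; projecting curvilinear 2-D trajectories
  onto the axon axis is upstream and out of scope, as is automated
  filament detection/tracking from images.
- Frequencies are not edge-corrected for filaments entering or leaving the
  imaged gap; the per-hour scaling assumes uniform observability, matching
  the published definition.
- The exact Mann–Whitney mode requires tie-free data; frequency data (small
  integer multiples of 4/hr) are tie-heavy and always take the corrected
  normal approximation, which is anti-conservative below n ≈ 8 per group.
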