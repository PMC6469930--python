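# Methods

This note documents the models, conventions and numerical choices behind
`eodmap`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic tests do and do not establish
about real recordings.

## Coordinate and time conventions

All geometry is in centimetres in a tank-centred frame (x right, y up in
plots); the overhead camera maps onto this frame via `pixel_scale`
(default 0.125 cm/px: a 1200 px image height spanning the 150 cm tank).
Time is in seconds from trial start. The video grid (default 15 Hz) is the
master time base: EOD rate is sampled onto it, spikes are assigned to the
nearest video frame (ties toward the earlier frame), and a trial's
duration is `n_frames × dt`. Headings are body-axis directions wrapped to
(−π, π]; backward swimming means velocity antiparallel to the body axis,
not a heading reversal — the classification is the sign of
v · (cos h, sin h), with frames below the 1 cm/s speed threshold labelled
quiescent. The threshold separates the low-speed quiescence mode of the
speed distribution from active swimming and is exposed in
`AnalysisConfig.speed_threshold_cm_s`.

## Instantaneous EOD rate

The rate at time t is the reciprocal of the inter-pulse interval
containing t — a step function, sampled on the analysis grid, constant-
extrapolated outside the first/last pulse. No smoothing is applied by
default; a Gaussian smoother (σ in seconds) exists for display and for
down-state detection on noisy trains. Because grid samples fall into an
interval with probability proportional to its length, the time average of
this estimator equals spike-count/duration (no inverse-moment bias), which
the tests exploit. Down-states are maximal runs with rate < 50 Hz,
filtered to ≥ 1 s.

Artifact blanking zeroes every sample within ± 2.8 ms of an EOD pulse
(closed interval, union over pulses; idempotent by construction). The
threshold-crossing counter (sample i−1 < θ ≤ sample i) applied to the raw
and the blanked trace bounds the fraction of spikes lost to blanking.

## Triggered averages

stEODr and stSpeed average the covariate in ± 4 s around each spike;
spikes whose window crosses a trial edge are dropped (behavior is not
circular), and units need more than 10 eligible spikes. Sampling density
is computed **per spike** as the elementwise quotient of the EODr and
speed snippets, then averaged — not as a quotient of means. Speeds are
floored at 0.5 cm/s before dividing; spikes rarely occur at lower speeds,
and the floor prevents quotient blow-ups at quiescence edges.

The null ensemble circularly shifts the whole train by a uniform random
time in [30 s, T − 30 s] (100 surrogates), preserving the spike count and
the circular ISI multiset. Mean elevation is tested by Kruskal–Wallis
between observed per-spike window means and the pooled surrogate window
means; because per-spike values of an autocorrelated covariate are not
independent, a group-level permutation p (observed grand mean ranked among
surrogate grand means) is reported alongside. Under the generator's
default conditions both stay calibrated (empirical type-I ≈ α), but on
covariates with much longer correlation times the KW variant should be
expected to be anticonservative — prefer the permutation p there.

Peak significance follows a two-step recipe: locate the extremum of the
*mean* trace, then sign-rank the per-spike value at that lag against the
per-spike window mean (one-sided). Per-spike timing takes the global
maximum (peaks) or the **smallest interior local minimum** (dips), with
plateaus resolved to their centre sample and ties broken toward lag 0;
snippets with no interior minimum are excluded and counted.

A caveat the synthetic batteries make explicit: the per-spike
deepest-local-minimum time is a biased, high-variance estimator. Even
with a strongly coupled pre-spike slowdown at −0.5 s, chance minima
elsewhere in the 8 s window shrink the median per-spike dip time toward
zero (typically −0.1 to −0.4 s), while the dip of the mean trace recovers
−0.5 s within one grid step and the pooled per-spike distribution is
robustly shifted negative (sign test). Interpret per-spike timing
medians accordingly.

## Spatial analysis

The occupancy grid anchors 16 cm square bins at the corner of the tank's
bounding box; the circular wall clips the outer bins. A visit increments
only when the head enters a bin it was not in on the previous frame; bins
with fewer than five visits in the trial are excluded (threshold
configurable — the inclusive ≥ 5 reading is used). Occupancy
probabilities p_i are time-in-bin renormalised over *included* bins so
that Σp_i = 1 and r_m = Σ p_i r_i is the occupancy-weighted mean rate the
information formula assumes.

Place information I = Σ p_i (r_i/r_m) log2(r_i/r_m) (zero-rate bins
contribute 0; undefined when r_m = 0). Significance uses 1000 surrogates:
the `shift` method circularly shifts the whole train (conserving relative
timing — conservative, because within-trial rate clumps survive shifting),
the `shuffle` method redraws spike times uniformly (liberal). A unit is
significant when observed information exceeds the 95th percentile of the
surrogate distribution; a one-sample t-test p of the surrogate
distribution against the observed value is reported as well, without
reconciling the redundancy of the two criteria. The validation battery
checks the ordering property (shuffle flags ≥ shift on the same units)
with an "epoch" unit that fires only early in the trial.

Rate-map displays are clipped at the 97th percentile of included-bin
rates; the true maximum is reported separately. Landmark-removal effects
average rates over included bins whose centres lie within 10 cm of the
landmark *polygon* (boundary distance, not centroid), normalise the
before/after pair by the larger, and test pooled pairs by Kruskal–Wallis.

## Egocentric landmark analysis

The landmark raster marks 10 × 10 px blocks (≈ 1.25 cm) whose footprint
intersects any landmark polygon or the tank-boundary circle — 160 × 120
elements for a 1600 × 1200 video. The egocentric transform resamples this
binary raster by nearest neighbour (no interpolation, preserving {0,1})
after rotating/translating so the fish sits at the centre element, head
north; elements mapping outside the raster are invalid. STLM accumulates
the transform at spike poses, PTLM at every 20th frame (1.33 s at 15 Hz).
Their quotient is masked where PTLM is at or below its lower 10th
percentile (locations essentially never occupied by a landmark), cropped
to a rectangular ± 10 cm window — 10 cm being a conservative upper range
for electrosensory object detection — and normalised to its maximum.

Preference indices use region maxima of that probability map: left/right
of the body midline and anterior/posterior of the boundary at one third of
the body length (default 15 cm) behind the head, which defines the zero of
the AP axis. Signs follow the interpretation "positive = right /
anterior", i.e. lr = (max_R − max_L)/(max_R + max_L) and analogously for
AP. The midline column and the AP-boundary row belong to neither side.

## Synthetic sessions

The generator emulates the study conditions rather than any particular
fish: 30–60 min trials, 15 Hz tracking in a 1.5 m tank with a home
structure and acrylic landmarks.

*Movement* is a correlated random walk on heading steered by excursion
goals renewed every ~12 s, half of them placed 1.5–4 cm beside a random
object — this produces full-tank coverage with wall/landmark-biased
occupancy (the fraction of time within 3 cm of objects exceeds the
area-proportional fraction several-fold). Speed follows an AR(1) process
(mean 8 cm/s, τ = 2 s) whose target drops to 45 % within 6 cm of objects,
so the fish decelerates smoothly when closing in. Backward episodes
(default 0.03 s⁻¹, mean 1.5 s) set velocity antiparallel to the body axis;
quiescent episodes (mean 30 s, every ~4 min) freeze the fish up to a small
drift. Positions get 0.03 cm of Gaussian tracking jitter, the magnitude a
sub-pixel video tracker would leave. Collisions steer the movement
direction toward the tank centre; landmark interiors (except the enterable
home) are never entered. B-scan kinematics are not quantified in the
literature at this resolution; the backward-episode parameters are free
choices, not claims.

*EOD train*: an inhomogeneous gamma-renewal process via time rescaling.
ISI shape defaults to 25 (CV ≈ 0.2, quasi-regular as real EOD trains are;
shape 1 recovers Poisson for tests). The driving rate is 70 Hz when
active, 40 Hz during quiescent down-states (< 50 Hz, matching the
down-state criterion), plus a 30 Hz transient decaying with distance to
the nearest object (length constant 4 cm).

*Spikes*: an inhomogeneous Poisson process on the frame grid, intensity =
baseline (0.5 Hz) × place gain (Gaussian bumps, σ = radius/2, peak gain
10) × direction gain (backward frames) × covariate couplings ×
egocentric-landmark drive, and ×0 during ground-truth quiescence unless
disabled. Covariate couplings multiply by exp(g·z) where z is the
z-scored covariate at t + lag, clipped at |z| ≤ 2.5 so the modulation
saturates, and normalised to unit mean; a peak injected at lag ℓ appears
at lag ℓ of the spike-triggered average. The landmark drive multiplies
intensity when the nearest landmark point is within 12 cm and in the
chosen body sector. All stages draw from one seeded generator; identical
seeds give bit-identical sessions.

**What the synthetic tests show — and what they don't.** Passing
calibration and recovery means the *pipeline* is correct and its tests are
calibrated under plausible statistics: it says nothing about spike
sorting, tracking errors beyond small jitter, electrode drift,
non-stationary behavior across landmark reconfigurations, or real
EODr–speed cross-correlations beyond those the movement model induces.
The generator's effects are multiplicative and stationary; real units need
not be either.

## Numerical and degenerate-input choices

Blanking windows are closed intervals with a 1 ns guard against float
rounding at the edges. Constant series make the KW and Wilcoxon tests
degenerate; they return p = 1 with a warning rather than failing. Units
with ≤ 10 eligible spikes are skipped with a logged reason and reported as
skipped in session output; zero time in a swim state, zero mean rate, or a
fully masked egocentric region raise `UndefinedResultError`. Session
reports are deterministic given (bundle, config): the config seed spawns
one RNG stream per unit in sorted-name order, and report JSON is written
with sorted keys so reruns are byte-identical.

## Validation batteries

`eodmap.validation` runs 30-min sessions (the short end of the study's
trial range, chosen to keep the batteries minutes-scale):

* **Calibration** — 40 sessions whose single unit has every coupling off
  (uniform Poisson through down-states too). Each significance procedure
  (mean-elevation KW, peak Wilcoxon, shift-null place information,
  stationarity KW) must fire in ≤ 2α of sessions at α = 0.05.
* **Recovery** — 20 sessions × six single-effect units: place field,
  backward gain, posterior landmark drive, pre-spike EODr rise (−0.3 s),
  post-spike speed rise (+0.5 s), pre-spike speed dip (−0.5 s), each
  recovered by its downstream statistic in ≥ 90 % of sessions with timing
  medians within ±0.2 s (the dip via its mean-trace lag, see the caveat
  above).
* **Ordering** — place/uniform/epoch units; shuffle-null detections must
  be ≥ shift-null detections.

`scripts/acceptance.py` re-runs all three batteries plus the closed-form
checks and an end-to-end session, writing every quantity to JSON.
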