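# eodmap

Analysis pipeline linking **sparse pallial spiking** in freely swimming
pulse-type electric fish (*Gymnotus* sp.) to **active electrosensory
sampling**, swim kinematics, allocentric spatial firing, and the egocentric
position of landmarks — together with a synthetic-session generator that
makes every stage of the analysis testable by parameter recovery.

Pulse-type electric fish probe their surroundings with discrete electric
organ discharges (EODs); each pulse is one electrosensory sample, so the
instantaneous EOD rate (EODr) is a sensory sampling rate and
EODr / swim-speed is a **sampling density** (pulses emitted per cm
traveled, a proxy for electrosensory attention). Hippocampus-like pallial
neurons in these fish fire extremely sparsely (≲ 1 Hz). This package
implements the complete desk analysis for such recordings: given tracked
head position and heading (15 Hz video), EOD pulse times, and sorted spike
times per unit, it quantifies how spikes relate to sampling behavior, to
place, and to where landmarks sit relative to the fish's body. It is
aimed at systems-neuroscience labs analysing freely moving electric-fish
(or, with minor adaptation, any sparse-spiking navigation) data.

## What it computes

**Spike-triggered behavior** (`eodmap.triggered`) — stEODr, stSpeed and
stSmpD: mean ± SEM of EOD rate, swim speed and sampling density in a ±4 s
window around every spike, with per-spike snippets retained. Significance
comes from 100 surrogates in which the whole spike train is circularly
shifted by a random time ≥ 30 s (Kruskal–Wallis on per-spike window means),
a Wilcoxon sign-rank test of the per-spike value at the mean-trace peak
against the per-spike window mean, and per-spike peak/dip timing histograms
with a sign test of the median against 0.

**Spatial firing** (`eodmap.spatial`) — occupancy in 16 cm bins with the
visit rule (a visit counts once per entry; bins with < 5 visits excluded),
firing-rate maps (display clipped at the 97th percentile), and Skaggs place
information

$$I = \sum_i p_i \,\frac{r_i}{r_m}\,\log_2\frac{r_i}{r_m}\quad\text{[bits/spike]},$$

tested against 1000 circular time-shifts of the train (conserving relative
spike timing; conservative) and against uniformly shuffled spike times
(liberal), each at the 95th percentile. Also: within/across-trial
stationarity checks and the firing-rate effect of removing a landmark
(bins within 10 cm of the landmark polygon, normalised rates, KW test).

**Swim direction & egocentric landmarks** (`eodmap.kinematics`,
`eodmap.egocentric`) — forward/backward labels from the sign of the
velocity projection onto the body axis (these fish swim backward routinely;
turns pool with the swim state of the same sign), the direction preference
index DPI = (FR_fwd − FR_bwd)/(FR_fwd + FR_bwd), and the spike-/position-
triggered landmark matrices: a 160 × 120 binary raster of landmarks and
tank wall is rotated/translated so the fish is centred and heading north,
summed at spike times (STLM) and every 1.33 s (PTLM); STLM/PTLM, masked
below the lower 10th PTLM percentile and cropped to a 10 cm window, is the
landmark-presence probability around the fish, summarised by left–right
and anterior–posterior preference indices (positive = right / anterior;
the AP boundary sits at the anterior third of the body).

**EOD processing** (`eodmap.eod`) — instantaneous EODr as the reciprocal
of the containing inter-pulse interval sampled on the video time base,
artifact blanking (trace zeroed ± 2.8 ms around every EOD pulse), and the
threshold-crossing counter used to bound blanking spike loss. Down-states
are maximal intervals with EODr < 50 Hz.

**Synthetic sessions** (`eodmap.synthetic`) — 30–60 min trials in a 1.5 m
circular tank with landmark polygons: goal-directed correlated random walk
(landmark-biased occupancy, backward-swim episodes, quiescent down-states),
a quasi-regular gamma-renewal EOD train (< 50 Hz in down-states, transients
near objects), and inhomogeneous-Poisson spike trains with configurable
place fields, direction gain, EODr/speed couplings and egocentric landmark
drive — all recoverable downstream, all seeded.

## Worked example

```sh
$ eodmap simulate demo --duration 1800 --seed 1
wrote synthetic trial to demo (27000 frames, 145753 EOD pulses)
$ eodmap preprocess demo
49 down-state interval(s); derived.csv written
$ eodmap placemap demo --unit u0
I_place = 0.137 bits/spike (95th pct of shift null = 0.071, significant = True, max FR/bin = 2.81 Hz)
$ eodmap report demo
analysed 2 unit(s), skipped 0; report.json written
```

The simulated trial holds two units: `u0` carries a place field (gain 10,
radius 15 cm) and `u1` a ×3 backward-swim gain. `placemap` recovers the
field: 0.137 bits/spike against a shift-null 95th percentile of 0.071 —
significant place information. In `report.json`, `u1` shows a direction
preference index of −0.50 (3 Hz backward vs 1 Hz forward firing gives
(1−3)/(1+3) = −0.5), while `u0` sits near 0 — each unit expresses exactly
the effect that was injected. A trial directory is plain CSV/JSON
(`trajectory.csv`, `eod_pulses.csv`, `spikes_<unit>.csv`, `arena.json`),
so real recordings in the same dialect run through the identical commands;
`eodmap sta` and `eodmap egocentric` expose the remaining stages, and
everything is callable as a library (see `eodmap.session.run_session`).

## Layout

```
src/eodmap/
  arena.py        tank + landmark geometry (shapely)
  synthetic.py    trajectory / EOD / spike generators with ground truth
  eod.py          EOD rate, artifact blanking, pulse detection
  kinematics.py   speed, forward/backward labels, down-states
  triggered.py    stEODr/stSpeed/stSmpD, circular-shift nulls, timing stats
  spatial.py      occupancy, rate maps, Skaggs information, landmark effects
  egocentric.py   DPI, STLM/PTLM, AP/LR preference vectors
  validation.py   calibration / recovery batteries
  io.py, config.py, session.py, cli.py, plots.py
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
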