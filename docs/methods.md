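# Methods

## Data model and time conventions

An *episode* is one labour's recording: FHR in bpm on a uniform 2 Hz grid
(0.5 s ticks) plus sparse, intermittent MHR points, both referenced to
the time of birth at t = 0 (negative seconds before birth). Missing
samples are NaN in memory and empty fields (or 0, the device's
no-measurement code) on disk. Grid position n of a time t relative to an
analysis origin t0 seconds before birth is n = 2(t + t0).

Analysis windows are half-open [start, start + Δ), so a partition of the
last t0 seconds assigns every tick to exactly one window; window index
p = (t + t0)/Δ. Defaults follow the reference analysis: t0 = 9000 s
(150 min), Δ ∈ {300, 600} s for trends and {600, 1800} s for densities.

Monitor clocks can drift by up to ±30 min. Episodes with measured FHR
after the recorded birth time are corrected by shifting all times so the
last measured sample sits at t = 0 (the shift is stored on the episode).
Drift in the other direction is unobservable from the signal and is left
uncorrected; it blurs, but does not bias, windowed statistics.

## Cleaning (FhrClean)

Three artefact patterns matter: short spikes far outside physiology,
longer non-physiological stretches, and missing data. Without beat-level
ground truth only the first is safely removable, so cleaning removes
*only* segments shorter than 30 s bounded by physiologically impossible
changes:

1. Gaps are filled by forward replication (backward at the head). Fills
   exist solely so the change detector sees a gap-free signal; they are
   flagged and revert to missing afterwards — every downstream statistic
   uses measured samples only.
2. A candidate excursion starts at a tick whose absolute first
   difference exceeds the jump threshold (default 25 bpm per 0.5 s tick —
   an order of magnitude above real beat-to-beat change; configurable).
   The excursion is followed, possibly through further opposite-signed
   jumps (a spike overshooting on its way back), until the signal
   returns to within the threshold of the last trusted pre-jump level.
   Chains that never return within 30 s, or whose total length reaches
   30 s, are retained wholesale: they are "long" deviations whose truth
   status is unknown.
3. Removal applies only to measured ticks, so replication artefacts are
   never counted as removed data.

Following excursions to a trusted return level (rather than stopping at
the first opposite jump) is what makes cleaning idempotent: re-cleaning a
cleaned episode removes nothing, and no removed run can reach 60 ticks.
The exact boundary rule of the original procedure is not published; this
rule reproduces its described behaviour (short impossible excursions
removed, long ones kept) but is not guaranteed identical to it.

Degenerate inputs: an all-missing episode raises an error; a constant
trace is untouched; with the threshold at infinity nothing is removed.

## Ambiguity

A Doppler sensor can lock onto the maternal pulse. Where both channels
are measured, the pair is ambiguous when |fhr − mhr| ≤ T_mhr (boundary
inclusive); T_mhr defaults to 5 bpm, the threshold used in the clinical
CTG literature. Because the channels run at different rates, each MHR
point is matched to the nearest cleaned FHR tick within 0.25 s (half a
tick; configurable), each tick used at most once. The cohort rate pools
all pairs, weighting episodes by their pair counts. An empty pair set has
*undefined* ambiguity — the code raises rather than returning 0.
Ambiguity is computed on cleaned FHR by default (cleaning precedes all
group analyses); a flag supports the raw signal instead.

## Trend estimation and tests

mFHR(p) is the median of all measured samples of all of a group's
episodes within window p — samples are pooled, not averaged per episode,
so episodes contribute proportionally to their measured data. Quartiles
use linear interpolation between order statistics. Windows without
measured data are flagged absent (never zero); windows supported by
fewer than 5 episodes are flagged low-support.

The shift between two windows is tested with the Wilcoxon signed-rank
test on per-episode window medians, restricted to episodes with data in
both windows; groups are compared per window with Kruskal–Wallis on
per-episode medians. The episode — not the sample — is the independent
observation unit, since samples within an episode are strongly
autocorrelated. Both exact and normal-approximation p-values are
available (`method=`); the approximation is the default at the cohort
sizes used here. All-zero differences return p = 1 (no detectable
shift). Fewer than 2 complete pairs, or any group with fewer than 2
episodes, raises an insufficient-data error.

## Densities

Per window, measured samples are counted into integer bins l = 50…200
bpm; bin l covers [l − 0.5, l + 0.5) (the device logs integer rates, so
edges only matter for synthetic data). Samples outside [49.5, 200.5) go
to an overflow tally and are excluded from N. Episode histograms are
summed over the group and divided by the total count N, so merging
cohorts equals a count-weighted density mixture. σ²_PDF is the variance
of the bin-center random variable under h̄ and equals the plain variance
of the pooled binned samples. A window with N = 0 has no defined pdf and
is reported absent. The 10-min pdf surface is exported long-format with
a per-window sidecar (N, episode count, σ²_PDF).

## Synthetic cohort

The generator emulates the observable structure of the restricted
clinical recordings; defaults are the study conditions used by the tests
and the acceptance script.

* **Composition** 200 normal / 20 NCU / 6 VEND / 4 FSB (perinatal
  mortality = VEND ∪ FSB = 10), scaled from the reference cohort's
  proportions to a size a laptop regenerates in seconds.
* **Baseline profiles** (minutes before birth, bpm), linearly
  interpolated, clamped earlier than the first knot: normal runs
  134 → 137 (at −90) → 135 (at −40) → 112, giving a first 10-min-window
  median of ≈134 bpm, a last-window median of ≈119 bpm and a mid-labour
  density peak in the 135–145 bpm band; NCU sits 1–2 bpm lower; the
  perinatal profile starts its large decline at −40 min and ends near
  98 bpm, shifting its final-half-hour peak near 110 bpm.
* **Variability** per-episode baseline offset ~ N(0, 8 bpm); stationary
  AR(1) wander (lag-1 = 0.9) with sd 6 bpm ramping linearly to ×2 by
  birth — labour intensifies, and this ramp is what produces the growing
  σ²_PDF toward birth; smooth half-cosine decelerations (2/h, ~15 bpm,
  ~60 s) that cleaning must *not* remove.
* **Dropout** per-episode missing fraction ~ N(0.30, 0.15) clipped to
  [0.02, 0.85], realized as alternating exponential measured/gap runs
  (mean gap 45 s).
* **Spike noise** 1.8% of measured ticks in runs of ~5 s (< 25 s), offset
  ±50–80 bpm from the signal — at least twice the jump threshold, mostly
  landing outside the 110–160 bpm band.
* **MHR** present in 30.5% of episodes, covering ~0.4% of the duration in
  60 s blocks sampled at 1 Hz, maternal baseline ~ N(85, 10) with slow
  wander. With probability 0.045 a block is *ambiguous*: the fetal
  channel records the maternal series exactly. Blocks are 60 s ≥ 30 s on
  purpose, so cleaning (which only removes sub-30 s segments) keeps
  them, as maternal pickup survives cleaning in reality. The injected
  rate calibrates the pooled synthetic ambiguity to the few-percent
  magnitude reported for Doppler devices; because joint coverage is so
  sparse (~1 h per cohort), the realized rate varies by a couple of
  percentage points across seeds — matching how thin this statistic's
  data base is in practice.
* **Spans** recording starts uniform between −10 h and −3 h; 30% of
  episodes stop up to 30 min before birth, reproducing the falling
  episode-support curve near birth. Optional clock drift uniform on
  ±drift_max (default off, max ±30 min).

Everything is a deterministic function of (config, seed); each episode
draws from its own child of the seed sequence.

What the generator does **not** emulate: true beat-to-beat dynamics,
accelerations/decelerations with CTG-guideline morphology, gestational-
age or delivery-mode covariates, MHR/FHR harmonic interference, or any
mechanistic fetal physiology. Passing recovery tests therefore shows the
*estimators* are correct under realistic missingness, noise and episode
heterogeneity — not that the clinical findings themselves are
reproduced on real data, which remain access-restricted.

## Numerical and scale choices

* Percentiles: numpy linear interpolation; even-count medians average
  the central pair.
* Density normalization asserted to 1 ± 1e-9; σ²_PDF cross-checked
  against the pooled-sample variance oracle in the tests.
* Type-I-error calibration of both tests runs on i.i.d. per-episode
  medians (the tests' actual observation unit), 1000 replicates × 50
  episodes/group — the exact null of the procedure at a cost of seconds.
* Problem sizes (230-episode default cohort, 100-episode cleaning
  audits) keep the full test suite under a minute while leaving
  Monte-Carlo error far below every asserted tolerance.
* Reports are plain CSV; every pipeline output directory carries a run
  manifest with the package version and a configuration hash, and
  identical (config, seed) runs are byte-identical.

## Known limitations

* The cleaning boundary rule approximates an unpublished procedure; its
  false-negative behaviour on artefacts that drift slowly (< 25 bpm per
  tick) is untested and likely poor — such artefacts are explicitly out
  of scope of the "<30 s impossible change" rule.
* Cohort-level ambiguity on the defaults rests on a few thousand matched
  pairs; per-seed scatter is large (see above).
* The perinatal-mortality group is tiny by construction (10 episodes),
  so its trend and density outputs are qualitative, with the same
  low-support caveats the reference analysis makes.
* MHR values are consumed as given; maternal ECG processing and
  accelerometer-based contraction detection are out of scope.
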