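# Methods

## Pipeline model

The package treats a session as a `(frames × height × width)` luminance
stack with two metadata scalars: frame duration (default 0.249 s, ~4 fps)
and pixel size (default 1.183 µm/px). The analysis assumes somata are
laterally stable up to rigid in-plane translation, that a fixed 5-px-radius
disk around each manually selected center captures the soma across the
session, and that calcium transients are positive-going excursions of ΔF/F
about a slowly varying baseline summarized by the session median.

### Motion correction

Per-frame translation is estimated by cross-correlation in the Fourier
domain against a fixed template (mean of the first 100 frames), with
subpixel refinement to 0.1 px (upsampled cross-correlation) and plain
(unnormalized) spectra, which is robust for these low-texture images.
Estimated shift components are capped at a configurable maximum (default
20 px). Correction translates each frame by the negated shift using linear
interpolation; pixels entering from outside the field are filled with the
frame median so edge ROIs are not biased toward zero. Integer shifts are
reproduced exactly in the overlap region. Non-rigid deformation and z-drift
are out of scope.

### ROI extraction and ΔF/F

A disk ROI contains every integer pixel whose center lies within the radius
of the selected point (squared-distance arithmetic; 81 pixels at radius 5).
Masks are clipped at image borders with a warning. The pooling statistic is
the **mean** over the disk (the convention for soma ROIs; sum would differ
only by a constant factor, which ΔF/F removes). ΔF/F uses the per-cell
session **median** as F₀; cells with non-positive median are excluded and
reported. The per-cell SD that scales the detection threshold and the
baseline gate is computed on the **raw, unsmoothed, full-session** ΔF/F,
events included — the simplest reading of "SD of the ΔF/F of each cell",
with no exclusion rule.

### Event detection and validation

Detection operates on the 5-frame centered moving average of ΔF/F (edges
truncated, length preserved). Candidates are upward crossings of
1.96 × SD_i with hysteresis: while the smoothed trace stays above threshold
no new onset is admitted, so a single transient is never double-counted.
Two crossings whose excursions trace back to the same departure from
baseline are merged into one event.

Validation anchors at the **apparent onset**: from each crossing, the trace
is walked back to the first frame of the contiguous run above 1 × SD_i.
This matters because a centered moving average spreads a transient backward
by half its window; anchoring at the crossing frame itself would put the
transient's own rising shoulder inside the baseline window and reject the
vast majority of genuine events. The event is kept iff

1. all 8 smoothed frames (~2 s) before the apparent onset lie within
   ±1 × SD_i of zero (flat baseline);
2. the mean of the smoothed trace over the response window — 3 s, i.e.
   `round(3/frame_duration)` = 12 frames — differs from the baseline mean
   with p < 0.05 under a **Welch two-sample two-tailed t-test** (chosen over
   the pooled-variance t because the response window contains the transient's
   deterministic shape and has very different variance from the baseline);
3. the response mean exceeds the baseline mean (transients are
   positive-going; this bars validating dips).

Validated events are assigned to consecutive half-open 300-s windows by
apparent-onset time; events past the last complete window are dropped and
reported. Event amplitude and duration are deliberately not analyzed — the
readout is counts.

Known behavior of this parameter set: 5-frame smoothing at 0.249 s/frame
attenuates a fast indicator transient (0.4-s decay) by ~2.4×, so the
smoothed peak is ~0.42 × amplitude. Consequently the detector's effective
limit is amplitude ≈ 7–8 × noise SD; at amplitude 5 × noise SD recall drops
to ~0.45. At the generator's default conditions (amplitude 10 × noise SD)
F1 ≈ 0.94 without drift and ≈ 0.88 with the default drift, the residual
misses being transients that arrive during a drift peak or within a few
seconds of a previous transient — both rejected by the flat-baseline rule by
design. The strict baseline gate is also why false positives are nearly
absent (≪ 0.5 per cell per window on pure noise).

### Statistics

Two-group comparisons are gated: Shapiro–Wilk on each sample (α = 0.05);
both normal and variances compatible under a two-sided F-test → Student t;
both normal, variances different → Welch t; otherwise Mann–Whitney U. Effect
sizes: Cohen's d with pooled SD for the t family, rank-biserial
r = 2U/(n₁n₂) − 1 for the rank test. For ≥3 groups, tie-corrected
Kruskal–Wallis H with η²_H = (H − k + 1)/(N − k); because rank tests are
sometimes summarized with F-style statistics, a Welch one-way ANOVA F on the
same data is reported alongside, with the design's (k − 1, N − k) df echoed
— the two are distinct statistics and neither is derived from the other.

The event-count comparison is a mixed (split-plot) two-way ANOVA with cells
as subjects: group between subjects — df (g − 1, N − g) — and 5-min window
within subjects, uncorrected for sphericity. The fit is delegated to
`pingouin.mixed_anova` and cross-checked in the test suite against an
explicit sums-of-squares decomposition. Partial η² is
SS_effect/(SS_effect + SS_error-for-that-effect) per effect. Raw p-values
are reported; no multiple-comparison correction is applied, matching the
one-model-per-population design. Percent change is
100 · (mean_treated − mean_control)/mean_control per window.

Cumulative dose for the titrated seizure-susceptibility test sums the
initial dose plus boosters through the Grade V-evoking injection; the
standard schedule is 40 mg/kg, then 5 mg/kg at +10 and +20 min, then
10 mg/kg every 5 min (30 mg/kg start for the reduced arm).

## Synthetic data generator

The generator emulates what the analysis assumes, no more:

- **Transient kernel**: difference of exponentials, rise 0.05 s, decay
  0.4 s (fast-indicator kinetics), discretized at the frame duration and
  unit-peak normalized. Bursts sum linearly.
- **Event timing**: homogeneous Poisson within each 300-s window with a
  per-window rate, so a windowed rate profile (e.g. a peak in window 3) is
  exactly representable. Default control rate 3 events/cell/window — a
  moderately active cortical population under a subthreshold convulsant.
- **Trace**: F₀ + drift + amplitude·F₀·(events ⊛ kernel) + Gaussian noise,
  with F₀ = 100, amplitude 0.5 ΔF/F (a strong burst-driven transient),
  noise 5 luminance units (0.05 ΔF/F, a typical shot-noise floor; SNR 10),
  and drift a one-cycle-per-session sinusoid of amplitude 3 with random
  phase per cell.
- **Movie**: each cell an isotropic Gaussian of SD 3 px truncated at 3 SD,
  peak luminance following the cell's trace, on a constant background;
  rigid per-frame jitter drawn i.i.d. Gaussian and applied analytically
  (cells rendered at displaced positions), so ground-truth shifts are
  exact; output quantized to 16 bit.
- **Seeding**: one master seed spawns an independent stream per cell plus
  one for the jitter; equal seeds give bit-identical output.

Not modeled (hence not demonstrated by passing tests): spike-to-calcium
nonlinearity, bleaching, neuropil contamination, z-motion, correlated
(shared) noise across cells, and non-sinusoidal baseline dynamics. Results
on real data will degrade to the extent these matter; in particular the
flat-baseline gate interacts with real baseline dynamics more harshly than
with the sinusoidal drift simulated here.

## Numerical and design choices

- Disk membership, window assignment, and counting use exact integer/float
  comparisons with half-open intervals; ties at the threshold (`>` not
  `>=`) never create an onset.
- Smoothing at trace edges truncates the window rather than padding, so
  edge values are means of fewer samples.
- The number of 5-min windows defaults to the number of *complete* windows
  in the session (4 in the simulated 20-min design); sessions shorter than
  one window are rejected rather than silently scaled.
- A session's partial final window, if explicitly requested, receives a
  proportionally scaled Poisson rate in the generator.
- Degenerate inputs: constant movies yield zero shifts with a warning;
  zero-variance traces yield no candidates with a warning; all-tied samples
  in the rank test return p = 1 with a warning.
- Problem sizes in the test and acceptance runs (e.g. 50 replicate seeds at
  100 cells/group for ratio recovery, 200 replicates for the type-I check,
  96-px movie fields) were chosen so each check has enough resolution to
  detect the failure mode it targets while the whole suite stays quick to
  iterate on.
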