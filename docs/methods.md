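# Methods

## Generative model (simgen)

One simulated recording is a single axon of length *L* (default 40–80 µm)
imaged for *T* frames at interval Δt with pixel size *p*. Two acquisition
presets mirror common protocols: in vivo (196.6 µm / 1024 px ⇒
*p* = 0.192 µm, 1.06 Hz, 636 frames ≈ 10 min; a legacy variant at 0.87
frames/s is also provided) and acute slice (0.18 µm, 1.96 Hz). A small CI
preset (120 frames, ≤256 px wide) keeps unit tests fast.

**Kinetics.** Each organelle has a fixed main direction, anterograde with
probability `p_anterograde`, and alternates between run and pause states.
Transitions are evaluated per frame with probability 1 − exp(−rate·Δt),
exact for exponential waiting times at frame resolution. A speed is drawn
once per run bout from a direction-specific normal truncated at zero and
held for the bout (producing the straight kymograph segments seen in real
data); the sign never flips within a bout, and the model contains no
reversal process — direction changes in real axons exist but are not needed
for any quantity tested here. Paused organelles have exactly zero
frame-to-frame displacement. Default marker kinetics are the study
conditions: NPY 1.518/1.073 µm/s (antero/retro), p_antero 0.61; LAMP1
2.371/1.476, 0.54; RAB7 2.344/1.370, 0.51. Published sources give means
only; the speed SDs (0.30–0.40 µm/s) are realistic spreads chosen once.
Pause entry/exit rates (0.03 and 0.20 s⁻¹ for NPY/LAMP1; 0.019 s⁻¹ entry
for RAB7) reproduce the reported stationary pause fractions
(entry/(entry+exit) ≈ 0.13 and 0.085).

**Synapse coupling.** Synapse centers are either given or drawn as a
Poisson process along the axon. Inside intervals of `synapse_radius_um`
(default 1.0 µm) around centers, the pause-entry rate is multiplied by
`synapse_pause_multiplier` (1 = no coupling). A hard-edged multiplier over
a 1 µm coupling radius makes the enrichment factor decrease strictly across
the standard mask bands (0.5 µm disk → 0.5–1.5 µm → 1.5–2.5 µm annulus),
the qualitative radius dependence the analysis must detect.

**Calcium activity.** Activity bouts form a Poisson process (rate
`calcium_bout_rate`) with exponential durations; the defaults
(0.021 s⁻¹ × 5 s) give ≈10% active time. During a bout (plus an optional
lag window) run speeds are multiplied by `active_speed_multiplier`. The
calcium channel renders as a uniform tube along the axon whose intensity
follows the bout state; `calcium_raw_trace` gives the equivalent 1-D
fluorescence series.

**Rendering.** Each particle is an isotropic Gaussian of σ =
`psf_sigma_um` (0.25 µm) and amplitude 5 over a uniform background of 1;
Poisson photon noise is applied at `photon_scale` photons per intensity
unit (0 disables noise; peak SNR ≈ 5·√photon_scale), then an optional
per-frame integer drift shifts the frame. Setting the seed reproduces
movies and truth byte-identically.

**Boundaries.** Organelles crossing an end of the axon are removed
(recorded as exits) and, by default, replaced by a new particle entering at
the opposite end at a uniform fractional-frame offset, keeping the standing
density stationary. Entrants necessarily arrive running, which depletes
pause density within about one relaxation length v/(λ_entry+λ_exit)
(≈6 µm) of the ends — a property of open-boundary transport, not an
artifact; uniformity of pause positions is therefore asserted on the axon
interior (3 µm margins), while the enrichment null calibration is global
and unbiased (mean factor 1.01 ± 0.02 over 200 axons).

**What the generator does not emulate:** photobleaching, axon branching or
z-drift, diffusive (non-motor) motion, within-bout speed fluctuations,
direction reversals, non-uniform backgrounds, and detector artifacts beyond
shot noise. Passing tests therefore demonstrate correctness of the analysis
given this model, not robustness to every property of real movies.

## Image processing (imgproc)

Registration is translation-only with integer shifts maximising phase
cross-correlation against a reference frame; sub-pixel registration is
deliberately avoided so exactness is testable. Background is the per-pixel
20th temporal percentile (subtracted, clipped at 0) followed by a per-frame
median filter (radius 1 px). Kymographs resample the axon polyline at
≈1 px arc-length steps, symmetric in the path ends (so reversing the path
flips columns exactly), and reduce perpendicular to the path by the
**maximum** over a 5 px width, preserving punctum peaks on curved axons.

## Tracking

The tracer works in two passes. Pass 1: per-row peak detection (rows
Gaussian-smoothed by 0.7 px — below the PSF width so nearby puncta stay
resolvable; threshold = median + 5 robust σ of the smoothed kymograph;
3-point parabolic sub-pixel refinement) followed by conservative
frame-to-frame linking — a velocity-confirmed segment accepts a detection
only within 3 px of its constant-velocity prediction, assignments solved
jointly per frame, so segments break at pauses, speed changes and
crossings. Pass 2 joins segment ends to later segment starts globally under
three hypotheses — the earlier segment kept moving, the later one was
already moving, or the particle paused through the gap (the pause
hypothesis carries a penalty so a consistent constant-velocity continuation
always outbids it at a pause-crossing). A join may bridge up to 4 missing
frames (occlusions from crossing or co-pausing puncta routinely last
several frames; purely stationary bridges may span longer) and is accepted
when the best hypothesis lands within 5 px (+1 px per bridged frame).
Assignments are one-to-one with an explicit per-end "no join" option priced
at the join radius, so a bad join is never forced merely to raise the
matching count; a final relaxed pass applies the same logic to whole
chains, and single-vertex zigzag outliers (contaminated localisations at
near-merges) are pruned. Every link respects the hard speed gate
v_max = 6 µm/s (≈2.5× the fastest mean speed of interest), so no traced
segment exceeds it; tracks shorter than 5 vertices are discarded. The gap
default (4) is larger than a bare missed-detection allowance because
bridging occlusions, not dropped frames, dominates fragmentation.

**Benchmark fixture.** Real single-axon recordings contain ~1–4 visible
moving organelles at a time (hundreds of tracks accumulate only over
minutes). The default benchmark is an 80 µm axon, 150 frames, 6 concurrent
organelles with turnover (≈20 distinct particles per recording) at peak
SNR ≈ 7; pooled over six such axons the tracer achieves recall ≥ 0.9 with
per-segment speed RMSE ≤ 0.15 µm/s. RMSE compares each traced vertex-pair
velocity with the truth displacement over the same frames: the tracer
asserts no positions inside bridged gaps, so bridged intervals are scored
on their average velocity.

## Metrics conventions

Moving ⇔ |net displacement| ≥ 2 µm (declared default). Orientation comes
from the modal direction of plus-end comet tracks when a comet channel
exists, else from the faster-mean-speed convention; with only ~8 tracks per
axon the faster-side heuristic occasionally flips, so simulations that need
reliable per-axon orientation include a comet channel. Mean moving speed
excludes paused segments (threshold 0.1 µm/s ≈ sub-quantization motion) by
default; an include-pauses mode exists because published conventions are
not always explicit. The pause-definition sweep {0, <0.2, <0.5, <1 µm/s}
is exposed for enrichment analyses. Relative flux counts tracks, not
unique organelles: with particle turnover the anterograde track fraction
exceeds the per-particle anterograde probability by the speed ratio
(faster particles produce more tracks per unit time); parameter-recovery
tests therefore disable re-injection so each particle yields one track.

## Synapse and activity context

Masks are 1-D along arc length (a kymograph analysis is intrinsically 1-D,
so "mask area fraction" collapses to length fraction). Annuli are (union of
outer disks) − (union of inner disks). Enrichment = (pauses in mask /
total pauses) / mask fraction, pauses located at segment midpoints. ΔF/F
uses a 20th-percentile baseline (mean of frames at or below it); the
half-max threshold is taken on a 3-frame median-smoothed trace over the
full recording — per-recording, not per-bout. Active runs are extended
forward by the configured window (+5 s / +30 s), merged when overlapping;
extension nesting A(0) ⊆ A(5) ⊆ A(30) holds by construction. Samples are
labelled by their time midpoints, bout starts closed on the left.

## Statistics

Distribution comparisons: two-sided KS (asymptotic p) and Wilcoxon
signed-rank for paired per-axon means. Condition effects on segment speeds
use a linear mixed model with nested random intercepts
(mouse ⊃ dataset ⊃ track) fitted by **ML** (not REML — the compared models
differ in fixed effects), and a likelihood-ratio χ² test with
(levels − 1) df. The statsmodels optimizer reliably stops short of the ML
optimum near variance-component boundaries, so fits are polished with
repeated derivative-free (Powell) restarts until the likelihood is
stationary; with this, the LR statistic is calibrated (type-I ≈ 0.05 on
null simulations). Because few top-level clusters (2–5 mice) make
asymptotic LRTs anti-conservative in general, a within-track permutation
oracle is provided; only the full model is refitted per permutation
(the null model's likelihood is permutation-invariant). Levels with a
single group are dropped with a warning; non-convergence withholds the
p-value. Stars follow the usual convention (\*, \*\*, \*\*\*, \*\*\*\*).

## Problem sizes in the shipped checks

Unit tests run on the CI preset. The acceptance-style checks use: 6
benchmark axons for the tracker; 25 axons × 3 markers (8 particles each,
no re-injection) for parameter recovery; 200 null and 120 coupled axons
(kinetics only) for enrichment; 10 traces + 100 replicate recordings for
the activity machinery; 1000 replicates each for KS/Wilcoxon and 500 for
the LRT type-I, with permutation agreement on 8 null datasets × 100
permutations. `scripts/acceptance.py` uses slightly smaller counts (20
axons per marker, 150/100 enrichment axons, 200 LRT replicates) to stay
well inside a desktop run; all sizes are the package's own choices and are
stated here so they can be scaled up.

## Known limitations

- The tracer's identity model is position/velocity only; co-pausing puncta
  under one diffraction-limited peak cannot be disentangled, and a small
  fraction of crossing events still swap identities.
- The LMM assumes Gaussian residuals; real speed distributions are skewed
  (the permutation oracle is the robust fallback).
- The simulator's hard-edged synapse coupling and constant bout speeds are
  idealisations; effect-size estimates on real data should not be read off
  simulation calibrations.
- Manual kymograph tracks are supported as CSV polylines, but no GUI editor
  is included.
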