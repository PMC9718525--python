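# axotrack

Quantification of axonal organelle trafficking from two-photon time-lapse
movies, built around kymograph analysis: automated track tracing, transport
speeds, directionality, flux, pausing, synapse-proximity pause enrichment,
and calcium-activity correlation — together with a synthetic movie generator
that makes every stage verifiable against exact ground truth.

## Who this is for

Labs imaging fluorescently tagged organelles (dense core vesicles via NPY
fusions, endo-lysosomal compartments via LAMP1 or RAB7, plus-end comets,
synapse markers, axonal calcium sensors) in single axons, in vivo or in
slices, who want a scriptable, tested alternative to manual ImageJ kymograph
workflows — and a simulator to validate parameter choices before trusting
numbers from real recordings.

## The analysis in brief

A recording is a calibrated stack *I(t, y, x)* (pixel size ~0.19 µm, frame
rate ~1 Hz). Along a traced axon polyline, the movie is resampled into a
kymograph *K(t, s)* (time × arc length); a punctum moving at velocity *v*
appears as a line of slope *v*. The tracer detects sub-pixel intensity peaks
per frame and links them into tracks *x_i(t)* using velocity continuity, from
which per-segment signed velocities *v = Δx/Δt* (anterograde positive, after
orientation assignment via a plus-end comet channel or the faster-direction
convention) feed the trafficking statistics:

- **mean moving speed** — time-weighted mean |v| over segments above the
  pause threshold;
- **pause fraction** — time-weighted fraction of segments with |v| below it;
- **relative flux** — fraction of moving tracks (net displacement ≥ 2 µm)
  whose main vector is anterograde;
- **absolute flux** — moving organelles per µm axon per minute;
- **pause enrichment** — observed pauses inside a synapse mask of radius *r*
  versus the count expected under spatial uniformity
  (total pauses × mask length fraction); a factor of 1 means no coupling;
- **activity correlation** — segment speeds split by a calcium ΔF/F
  half-maximum active state (optionally extended +5 s / +30 s past each
  bout), compared with a hierarchical linear model
  (speed ~ condition, nested random intercepts mouse ⊃ dataset ⊃ track,
  ML fit, likelihood-ratio test) plus a within-track permutation oracle.

The simulator (`axotrack.simgen`) generates movies with the same acquisition
geometry and a two-state run/pause kinetic model (direction-specific
truncated-normal speeds, exponential pause switching, optional
synapse-coupled pausing and activity-modulated speeds) and returns the exact
latent state, so tracking and statistics can be scored by parameter
recovery.

## Worked example

```python
import pandas as pd
from axotrack import simgen, imgproc, tracking, metrics

tables = []
for seed in range(5):                                # five 80 µm axons
    cfg = simgen.tracking_benchmark_preset(seed=seed)
    movies, truth = simgen.simulate_axon_movie(cfg)  # npy channel + truth
    kymo = imgproc.build_kymograph(movies["npy"], simgen.make_path(cfg))
    ts = metrics.assign_direction(tracking.trace_kymograph(kymo))
    tables.append(metrics.summarize_tracks(ts))
moving = pd.concat(tables).query("moving")
print(moving.groupby("direction")["mean_moving_speed_um_s"].mean().round(3))
print(f"{len(moving)} moving tracks, "
      f"mean pause fraction {moving['pause_fraction'].mean():.3f}")
```

prints

```
direction
antero    1.424
retro     1.081
Name: mean_moving_speed_um_s, dtype: float64
68 moving tracks, mean pause fraction 0.102
```

i.e. from rendered noisy movies alone, the tracer and metrics recover the
generator's anterograde/retrograde speed means (1.518 / 1.073 µm/s) to
within a few percent on 68 tracks; the pause fraction is slightly below the
stationary 0.13 because segment-level pauses shorter than a frame are
invisible at 1 Hz.

The same stages are available from a shell:

```bash
axotrack simulate --out sim/ --seed 7 --preset ci
axotrack kymo --movie sim/npy.tif --path sim/axon_path.csv --out kymo.tif
axotrack track --kymo kymo.tif --out tracks.csv
axotrack metrics --tracks tracks.csv --axon-length 40 --duration-min 1.9 --out metrics.csv
axotrack run --out run/ --seed 7      # whole pipeline + manifest
```

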