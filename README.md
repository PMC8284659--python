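# cometkit

Quantification of axonal microtubule (MT) plus-end dynamics and bundle
disorganisation from fluorescence microscopy.

Axons are supported by parallel bundles of microtubules. Growing MT
plus-ends recruit end-binding proteins (Eb1/EB3, or live markers such as
MACF43::GFP), which appear as comet-shaped puncta that move along the
axon in time-lapse movies and as bright spots in fixed stainings. When
plus-end regulation fails, axonal MTs buckle into intertwined, curled
bundles. `cometkit` implements the measurements used to quantify both
phenomena, validated end-to-end on synthetic movies with known ground
truth:

- **Comet amount** — per-comet length and background-subtracted mean
  intensity along the traced axon; the comet amount is their product,
  `amount = mean_intensity x length`.
- **Kymograph dynamics** — position-vs-time reslices along a traced axon
  (band-averaged, bilinear), automatic ridge tracking, and per-neuron
  median comet velocity and lifetime.
- **2D plus-end tracking** — sub-pixel comet detection and
  frame-to-frame linking with gap closing under an explicit parameter
  semantics (maximum gap 8 frames, minimum track 3 frames, search radius
  5-12 px, forward cone 50 deg, backward cone 10 deg, shrinkage factor
  0.8, fluctuation radius 2.5 px, 2 s frame interval by default).
- **MT disorganisation index (MDI)** — the summed area of curled MT
  regions divided by (axon length x 0.5 um reference axon diameter):
  `MDI = sum(A_curl) / (L_axon * 0.5 um)`, plus axonal swelling counts.
- **Statistics** — normalisation to parallel (same-repeat) controls,
  tie-corrected Kruskal-Wallis with Dunn's post-hoc z-tests (raw and
  Holm-adjusted p), Mann-Whitney rank-sum (exact enumeration for small
  untied samples), tie-corrected Spearman correlation, and superplot-style
  repeat summaries with percentile-bootstrap confidence intervals.
- **Synthetic data** — a generator for stills and movies of simulated
  axons: Poisson comet nucleation, constant-velocity motion, exponential
  lifetimes, Gaussian-front/exponential-tail comet profiles convolved
  with the PSF, lattice fluorescence, Poisson + Gaussian camera noise —
  with full ground truth (tracks, curl polygons, trace).

## Worked example

Simulate a 50 um axon carrying one 10 um^2 curled region and a minute of
comet traffic at 0.2 um/s, then quantify it:

```python
import cometkit as ck

cfg = ck.SimConfig(axon_length_um=50.0, comet_velocity_um_s=0.2, rng_seed=42)
trace, curls = ck.simulate_axon_trace(cfg, curl_specs=[(25.0, 10.0)])
stack, truth = ck.simulate_comet_movie(trace, cfg)

kymo = ck.build_kymograph(stack, trace)
summary = ck.comet_dynamics_summary(ck.extract_tracks(kymo))
print(f"tracks: {summary.n_tracks}")
print(f"median velocity: {summary.median_velocity_um_s:.3f} um/s")
print(f"median lifetime: {summary.median_lifetime_s:.1f} s")

polys = [ck.PolygonROI(c.polygon_px, "curl") for c in curls]
res = ck.mdi(polys, trace)
print(f"axon length: {res.axon_length_um:.1f} um")
print(f"curl area:   {res.curl_area_um2:.2f} um^2")
print(f"MDI:         {res.mdi:.3f}")
```

prints

```
tracks: 33
median velocity: 0.199 um/s
median lifetime: 3.0 s
axon length: 50.0 um
curl area:   9.99 um^2
MDI:         0.400
```

The extracted median velocity recovers the simulated 0.2 um/s within
0.5%; the MDI equals the ground-truth 10 / (50 x 0.5) = 0.4. The median
lifetime is shorter than the simulated mean lifetime (8 s) because
lifetimes are exponentially distributed, comets leaving the axon are
truncated, and tracks shorter than three frames are not scored.

A command-line interface wraps the same pipeline for TIFF + ROI inputs:

```sh
cometkit simulate --config cfg.json --out sim/
cometkit comets   --image still.tif --rois rois.json --out comets.csv
cometkit kymo     --movie movie.tif --rois rois.json --out kymo.tif --tracks tracks.csv
cometkit track    --movie movie.tif --out tracks.csv
cometkit mdi      --rois rois.json --out mdi.csv
cometkit stats    --table measurements.csv --metric comet_amount --out report.csv
```

Movies and stills are multi-page/single-page TIFF with a sidecar JSON
(`<name>.tif.json`) holding `pixel_size_um` and `frame_interval_s`;
annotations are a JSON/CSV ROI dialect (documented in
`cometkit.io`), with read-only import of ImageJ `.roi`/`.zip` polylines
and freehand polygons.

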