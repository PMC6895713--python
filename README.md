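# sstmorph

3D morphometry of blind-ended epithelial tubules (avian sperm storage
tubules) from light-sheet image volumes and paired side traces: averaged
luminal centerlines, arc-length sampling, oblique cross-sections, major/minor
axis diameters, and mixed-effects models of the diameter profile and
cross-sectional circularity. A synthetic-data generator renders tubule
volumes with known geometry so every stage is verifiable without the
original microscopy data.

## Pipeline

1. **synthgen** — synthetic SPIM-like volumes: a curved tube whose wall
   carries punctate Gaussian granules around a dark lumen, plus simulated
   side traces and per-bird measurement tables with a known generating
   model (quadratic diameter profile, bird random intercepts).
2. **tracegeom** — polyline arc length, equidistant resampling, averaging
   of two side traces into a luminal centerline, local tangents; 10
   equidistant sample loci per tubule by default.
3. **obliqueslice** — trilinear extraction of 2D sections on planes normal
   to the local tube direction, with a deterministic in-plane frame and a
   validity mask for out-of-volume pixels.
4. **morphometry** — per-section measurement: smooth, threshold (`otsu`,
   `halfmax`, or `fixed:<v>`), fill the dark lumen, take the component at
   the slice center, and report moment-equivalent-ellipse axis diameters
   d1 ≥ d2, circularity d1/d2 and mean diameter (d1+d2)/2. Note: on
   granular ring sections Otsu thresholds low and inflates diameters by
   ~2 px; `halfmax` (FWHM-style) is unbiased to < 1 voxel.
5. **ssstats** — REML random-intercept mixed models (own fitter,
   cross-checked against statsmodels): mean diameter ~ distance +
   distance² + total length, and circularity ~ length + (d1+d2) +
   distance + interaction; Satterthwaite dfs, Nakagawa–Schielzeth
   marginal/conditional r²; OLS lumen-vs-outer-diameter scaling with
   prediction.

## CLI

```sh
sstmorph simulate --seed 1 --out-dir out/          # volume.tif + traces + table
sstmorph measure out/volume.tif out/trace_a.swc out/trace_b.swc --out-dir out/
sstmorph stats out/measurements.csv --out-dir out/ # mixed-model report
sstmorph all --config config.yaml --out-dir out/   # the whole chain
```

All knobs live in a YAML config (`--config`); every run writes a
`manifest.json` (config, seeds, input hashes, version) sufficient to
reproduce its outputs. Volumes are ImageJ-style TIFF with a YAML spacing
sidecar; traces are 7-column SWC or x,y,z CSV; tables are plain CSV with
the shared schema `bird_id, sst_id, point_index, s_um, d1_um, d2_um,
circularity, mean_diameter_um, total_length_um`.

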