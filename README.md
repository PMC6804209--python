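# ramanpipe

Label-free Raman microspectroscopy analysis for tissue diagnostics, built
as a reusable, fully tested pipeline:

- **Synthetic data** (`ramanpipe.synth`) — labeled Raman spectra and
  hyperspectral cubes for seven tissue classes (pituitary gland, five
  adenoma subtypes, periosteal layer) with pseudo-Voigt bands at twelve
  reference positions (590, 658, 874, 939, 1004, 1093, 1254, 1331, 1445,
  1663, 2873, 2945 cm⁻¹), class-specific absent bands (all adenomas lack
  1004 cm⁻¹; gonadotroph also lacks 1093 cm⁻¹; periosteal lacks 590, 658,
  1004 and 1093 cm⁻¹), a smooth autofluorescence background, additive
  noise, optional cosmic spikes, and per-band spatial concentration maps.
- **Preprocessing** (`ramanpipe.preprocess`) — axis calibration from a
  reference peak table, transmission correction, iterative degree-9
  polynomial baseline removal (fit → point-wise minimum → refit),
  Savitzky–Golay smoothing (window 21, order 3), fingerprint/CH-region
  cropping, per-spectrum 0–1 normalization.
- **Chemometrics** (`ramanpipe.chemometrics`) — PCA with
  explained-variance component selection (default 95%), stratified or
  biopsy-grouped 25% holdout, 1-nearest-neighbor classification
  (Euclidean, equal weights, lowest-index tie rule), confusion-matrix
  reports with per-class recall and overall accuracy.
- **Cube imaging** (`ramanpipe.cube`) — per-pixel preprocessing of
  hyperspectral cubes, band-image extraction around peak positions, and
  two-band magenta/green overlays.
- **Texture analysis** (`ramanpipe.texture`) — grey-level co-occurrence
  matrices at the four one-pixel offsets (0°/45°/90°/135°), the four
  Haralick statistics (contrast, correlation, energy, homogeneity),
  per-(class, band) medians, and 2-D correlation coefficients between
  class band-images.

## CLI

```sh
ramanpipe simulate --n-per-class 100 --seed 1 -o spectra.csv
ramanpipe preprocess -i spectra.csv -o preprocessed.csv \
    --baseline-degree 9 --sg-window 21 --sg-order 3
ramanpipe classify -i preprocessed.csv --variance 0.95 --holdout 0.25 \
    --split-level spectrum --seed 1 -o report.json
ramanpipe band-image --cube cube.h5 --center 1004 --half-window 5 -o band.tiff
ramanpipe texture --cube cube_gland.h5 --cube cube_null_cell.h5 \
    --bands 590,658,874,939,1004,1093,1254,1331,1445,1663,2873,2945 \
    --levels 8 --outdir texture_out
ramanpipe run-all --outdir run1 --seed 1            # full synthetic run
ramanpipe fixture --kind cube --preset small --seed 1 --outdir fixtures
```

`run-all` accepts a YAML config (`--config run.yaml`) mirroring the CLI
flags; explicit flags win, and the effective config is written into the
output directory alongside the classification report, confusion matrix,
texture tables, correlation matrix and figures.

## File formats

- Labeled spectrum sets: CSV with row 1 = class labels, optional
  `#biopsy` row, column 1 = wavenumber (cm⁻¹), one intensity column per
  spectrum.
- Hyperspectral cubes: HDF5 with `/cube` (line × step × wavenumber),
  `/wavenumber`, and pitch attributes (5 µm along the line, 10 µm per
  scan step by default — a 100 µm × 500 µm field at 20 × 50 pixels).
- Band images: 32-bit TIFF plus PNG render.

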