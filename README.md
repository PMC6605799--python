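# exoquant

Quantification of secretion hotspots near focal adhesions (FAs) in
fluorescence microscopy. The package reimplements, as a tested and seeded
pipeline, the image-quantification procedures used to show that post-Golgi
cargo is secreted preferentially next to FAs:

- **`exoquant.synthetic`** — seeded generator of two-channel scenes
  (elongated peripheral FA blobs + cargo spots placed FA-proximally,
  uniformly, or on-FA) and vesicle movies (emitters moving along polylines
  at programmed speed), rendered with a Gaussian PSF, Poisson shot noise
  and Gaussian read noise, with full ground truth.
- **`exoquant.detection`** — ROI rasterization, Gaussian-filter +
  threshold segmentation (Otsu over ROI by default, provenance recorded),
  prominence-based spot detection with deterministic tie-breaking, object
  counting, spot density per cell / per µm², normalized spot intensity.
- **`exoquant.proximity`** — exact Euclidean distance-to-FA map, binned
  cargo-vs-baseline distance distributions and the enrichment ratio R(b),
  plus a scalar enrichment-within-d summary.
- **`exoquant.dynamics`** — greedy nearest-neighbor linking with a hard
  displacement cutoff, per-track speed and covered distance, kymographs
  along polylines (bilinear sampling, odd line width), temporal max /
  argmax projection.
- **`exoquant.quant_stats`** — object-based colocalization (one-to-one
  greedy centroid matching), Pearson correlation over an ROI, secreted
  fraction `sup / (sup + lys)`, pooled-variance Student's t test (Welch
  optional) with mean ± SEM summaries.
- **`exoquant.pipeline` / `exoquant.cli`** — end-to-end orchestration with
  a JSON/YAML config, stable CSV/TIFF/JSON file contracts, MANIFEST with
  full parameters, and byte-identical outputs for identical config + seed.

## CLI

One entry point with subcommands; all randomness is behind `--seed`:

```sh
exoquant simulate sim.json --seed 7 --out simdir        # scene + ground truth
exoquant simulate sim.json --movie --out movdir         # vesicle movie
exoquant segment img.tif roi.json --pixel-size 0.1 --json
exoquant enrich cargo.tif fa.tif roi.json --pixel-size 0.1 \
    --out profile.csv --plot profile.png
exoquant track movie.tif --pixel-size 0.1 --frame-interval 0.2 --json
exoquant kymo movie.tif path.json --pixel-size 0.1 --frame-interval 0.2
exoquant project movie.tif --pixel-size 0.1 --frame-interval 0.2
exoquant coloc spots_a.csv spots_b.csv --radius 3 --json
exoquant pearson a.tif b.tif roi.json --json
exoquant sunset lanes.csv --out secreted_fraction.csv
exoquant run analysis.yaml --seed 11 --json             # full pipeline
```

ROIs are JSON polygons (`{"polygon": [[row, col], ...]}`; ImageJ `.roi`
rectangles/polygons are also readable). Scenes are `(C, Y, X)` TIFFs,
movies `(T, C, Y, X)`; tables are CSV with unit-suffixed headers.

## Conventions

Pixel coordinates are 0-based `(row, col)` with pixel centers at integer
positions; distances are reported in µm, speeds in µm/s. Identical config
and seed give bit-identical images, ground truth and CSV outputs.
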