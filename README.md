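# spavg

Single-particle averaging of two-color 3D fluorescence volumes of
diffraction-limited particles. The package re-implements, as a reusable
library and CLI, a post-processing chain for reconstructed
structured-illumination z-stacks:

1. **Detection** — sum-project a channel, blur (σ = 1 px), greedily accept
   local maxima above 15% of the image maximum with a 30 px minimum mutual
   distance, and eliminate particles whose Gaussian-fitted axial profile
   peaks in the first or last slice.
2. **Fitting** — constrained dual 3D Gaussian fits (shared lateral/axial
   widths, constant background) by box-constrained trust-region nonlinear
   least squares; lateral centers held to ±2 px of the seeds, axial centers
   to ±2 slices of the brightest 3×3 z-profile slice. Parameter errors via
   residual-noise Monte Carlo (100 replicates).
3. **Alignment & averaging** — assign the mother spot (fiducial proximity or
   brightness), resample each particle onto a common plane through both
   centers and the optical axis (trilinear, 4× finer pixels), orient
   (mother left, query mass up), and sum into dual-color probability maps;
   maps can be co-registered vertically by their fiducial peak.
4. **Quantification** — multi-Gaussian axis-profile fits with optional broad
   background component and end trimming, FWHM = 2√(2 ln 2)·σ ≈ 2.35σ and
   95%-integral ≈ 1.7×FWHM conversions, 3D distances, bend angles,
   75%-threshold contour outlines (independent per distribution), display
   rendering, and an F-test one-vs-two-foci classifier.
5. **Synthetic scenes** — ground-truthed generators (`pair`, `bent_triplet`,
   `line_bridge`, `single`) with anisotropic Gaussian PSF, point/line
   emitters, additive Gaussian noise, and jittered "manual click" seeds, so
   every stage is testable without external data.

## CLI

```sh
# generate ground-truthed synthetic scenes (OME-TIFFs + seeds.csv + truth.json)
spavg simulate --preset pair --n 17 --seed 42 --noise-sd 2.0 --out scenes/

# detection on projection images
spavg detect scenes/*.ome.tiff --channel 0 --threshold 0.15 --min-distance 30 --out candidates.csv

# constrained dual 3D Gaussian fits with Monte Carlo errors
spavg fit scenes/*.ome.tiff --seeds scenes/seeds.csv --mc 100 --mc-seed 17 --out fits.json

# align, orient, and average into a dual-color probability map
spavg align scenes/*.ome.tiff --seeds scenes/seeds.csv --out map.tiff

# profile fits and contour outlines of the map
spavg profile --map map.tiff --channel 0 --axis x --components 2 --out profile.json
spavg contour map.tiff --threshold 0.75 --out contours.geojson

# full pipeline from a YAML config
spavg run --config run.yaml
```

A minimal `run.yaml`:

```yaml
simulate_preset: pair
n_particles: 17
simulate_params: {noise_sd: 2.0}
rng_seed: 42
out_dir: out/
```

File-based runs replace `simulate_preset` with `volume_paths` (TIFF z-stacks
with OME/ImageJ voxel metadata, or `voxel_size_override: [dz, dy, dx]` in nm)
plus `seeds_path` (CSV with columns `image_id, fit_channel,
reference_channel, mother_x, mother_y, distal_x, distal_y`).

## Layout

- `src/spavg/io_volumes.py` — Volume/SeedPair types, OME/ImageJ TIFF and CSV I/O
- `src/spavg/detection.py` — projection, greedy maxima, z-edge filter
- `src/spavg/fit3d.py` — constrained single/dual 3D Gaussian fits, Monte Carlo errors
- `src/spavg/alignment.py` — mother assignment, plane resampling, orientation, maps
- `src/spavg/mapstats.py` — profiles, conversions, geometry, contours, classifier
- `src/spavg/synthetic.py` — ground-truthed scene generators
- `src/spavg/pipeline.py` — YAML-configured end-to-end runs with provenance
- `src/spavg/cli.py` — `spavg` command group
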