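# aosize

Acoustic–optical fish sizing. The package detects fish traces in split-beam
echograms, fits a deformable ventral silhouette model to video frames,
verifies the spatio-temporal correspondence between the two channels, and
produces metric snout–fork length (SFL) and maximum width (W) estimates with
tilt-based quality filtering. A first-class synthetic module generates paired
echogram + video scenes with full ground truth so every stage is testable
without recordings.

## Layout

- `aosize.synthetic` — paired scene generator (echogram, lazy frame
  sequence, ground truth, calibration), deterministic under a fixed seed.
- `aosize.echogram` — Otsu binarization, morphological cleanup, trace
  extraction/characterization (area, solidity, TS, range, ping count),
  time-and-space isolation filter, swimming tilt indicator (STI: slope of
  the per-ping max-backscatter range line).
- `aosize.vision` — local-threshold segmentation, blob filtering, contour
  tracing, eight-parameter silhouette model fitting (deterministic
  Nelder–Mead from a principal-axis initialization with head/tail
  multi-start), fitting error index (FEI), greedy overlap tracking.
- `aosize.fusion` — beam projection onto the image, spatial/temporal
  correspondence, pinhole conversion `Y = y·Z/f`, symmetric trimmed mean
  over tracked measurements, ML→SFL linear relation
  (`SFL = 1.0312·ML + 0.065641`).
- `aosize.tiltfilter` — STI interval classifier (pluggable interface) and
  confusion reporting.
- `aosize.stats` — relative errors, error-by-tilt percentile summaries,
  population statistics, frequency histograms.
- `aosize.pipeline` / `aosize.cli` — end-to-end orchestration with
  per-stage sample accounting; vision runs only on frames inside the
  1000 ms acoustic trigger windows (provably equivalent to processing all
  frames).

## CLI

```sh
# generate a synthetic paired scene
aosize simulate --seed 7 --out scene/

# run the sizing pipeline (writes results.csv, traces.csv, counts.json)
aosize size --scene scene/ --out out/

# summary statistics, histograms, error-by-tilt table
aosize report --results out/results.csv --truth scene/truth.csv --out report/
```

Scene configuration is a YAML file with a `scene:` section mirroring
`aosize.synthetic.SceneConfig` (`aosize simulate --config cfg.yaml`).

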