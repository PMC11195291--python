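# logprf

Population receptive field (pRF) mapping with a log-eccentricity-warped
drifting-bar stimulus, implemented end to end:

- **Stimulus generation** (`logprf.stimulus`) — fixed-width drifting-bar
  aperture movies (2° bar, 0.4°/s, 16° circular aperture; 2 s blank +
  eight 45 s sweeps + 4 s blank = 366 s per run), the logarithmic
  eccentricity warp `r' = c·ln(1 + k·r)` with `c = rmax/ln(1 + k·rmax)`
  (default `k = 5`, `rmax = 8°`) that turns the fixed bar into a "log bar"
  moving at roughly constant speed on a log-magnified cortex, and the
  preprocessing used before fitting (binarize, 540×540 → 108×108 spatial and
  → 366-frame temporal linear downsampling).
- **Hemodynamics** (`logprf.hemodynamics`) — six-parameter double-gamma HRF
  (difference of gamma densities; SPM-canonical defaults) and causal
  convolution.
- **Forward model** (`logprf.forward_model`) — isotropic 2-D Gaussian pRF
  (unit peak) and predicted BOLD as the per-frame stimulus/Gaussian dot
  product convolved with the HRF.
- **Fitting** (`logprf.fitting`) — correlation objective; exhaustive coarse
  grid search (centers −8…8° in 20 steps per axis, σ 1…5° in 20 steps);
  Nelder-Mead refinement with σ in log space; alternating 6-parameter HRF
  estimation on the top-VE subset (median across units, 3 iterations);
  retention filters (ecc < 8°, σ > 0.05°, VE > 10%).
- **Simulation** (`logprf.simulation`) — ground-truth grids (24 polar angles
  × 200 log-spaced eccentricities = 4800 pRFs, σ = 0.15·ecc + 0.1), noisy
  synthetic BOLD replicates, and recovery analysis showing that the fixed
  bar overestimates small foveal pRF sizes while the log bar tracks truth.
- **Metrics** (`logprf.metrics`) — variance explained, Fisher z, Spearman and
  circular (Fisher–Lee) reliability, behavioral performance.

## Tests

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`; its recovery criterion runs
the full fast-profile simulation (two stimulus types × 400 pRFs × 10 noisy
replicates) and takes ~10 minutes on one CPU. Everything else finishes in a
few minutes.

## CLI

```bash
# generate a stimulus movie (NIfTI + JSON sidecar)
logprf stimulus --mode log --k 5 --rmax 8 --bar-width 2 --speed 0.4 \
    --seed 1 --out movie.nii.gz

# parameter-recovery simulation (fast or full profile)
logprf simulate --profile fast --seed 1 --out simdir/

# fit pRFs to a time-course matrix (TSV or 2-D NIfTI)
logprf fit --stim movie.nii.gz --data tc.tsv --config fit.yaml --out fits.tsv

# session-to-session reliability of two fit tables
logprf report --fits-a session1.tsv --fits-b session2.tsv --out report.tsv

# full configured experiment with manifest
logprf run --write-default-config config.yaml
logprf run --config config.yaml --out outdir/
```

## Conventions

- Visual-field degrees; x rightward, y upward, origin at fixation; polar
  angle counter-clockwise from +x; pixel centers at half-integer offsets.
- Natural logarithm in the warp (any base change is absorbed by `c`).
- The Gaussian pRF is unit-peak and predictions are unscaled: the Pearson
  objective is invariant to affine scaling, so no amplitude/baseline is fit.
- Movies are stored as X×Y×1×T NIfTI with degree and frame-duration zooms
  plus a JSON sidecar; fits and reports are TSV.
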