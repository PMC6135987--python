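# acsat

Automated cell segmentation by adaptive thresholding for large-scale
calcium-imaging recordings — plus a synthetic ground-truth simulator and the
ROI-matching evaluation used to benchmark it.

## What it does

Given a fluorescence movie (multipage TIFF) or a pre-collapsed 2-D image,
the pipeline:

1. **Collapses time**: each pixel becomes max(t) − mean(t); active neurons
   stand out, static background goes to ~0.
2. **Searches for the threshold** τ\* that maximizes the number of valid
   cell-shaped regions (area within [A_min, A_max], centroid inside the
   mask, convex-hull/area ratio ≤ the golden ratio), by recursively
   narrowing the intensity search range instead of sweeping it.
3. **Splits merged cells**: every candidate region is re-thresholded inside
   its own dilated footprint, recursively, until it no longer separates.
4. **Iterates**: segmented cells are blanked out (with a dilated margin) and
   the search repeats at a naturally lower threshold, picking up dimmer
   cells, until the global threshold converges:
   |τ\_{n+1}\* − τ_n\*| / τ_1\* < δ (default 10%).

The output is the union of all iterations' ROIs, each tagged with the
iteration that found it. Because thresholds are chosen from the data, the
same defaults work across preparations with very different brightness and
illumination. See `docs/methods.md` for the full model and its assumptions.

The package also ships a simulator that generates time-collapsed images from
the additive model I₀ = E + A∘C (positively skewed collapse noise E,
bivariate-Gaussian cell bodies A, smooth illumination field C) at a
requested SNR and cell count, with exact ground-truth masks — so
segmentation quality can be measured as recall/precision under controlled
conditions.

## Worked example

```python
from acsat import (AcsatConfig, SimulationConfig, match_roi_sets,
                   run_acsat, simulate_dataset)

truth = simulate_dataset(SimulationConfig(
    height=256, width=256, n_rois=40, target_snr_db=26.0, seed=3))
seg = run_acsat(truth.image, AcsatConfig())
m = match_roi_sets(seg.rois, truth.true_rois)
print(f"{len(seg.rois)} ROIs in {seg.n_iterations} iterations, "
      f"taus {[round(t, 2) for t in seg.tau_trace]}")
print(f"recall {m.recall:.3f}  precision {m.precision:.3f}")
```

prints

```
38 ROIs in 2 iterations, taus [5.09, 4.48]
recall 0.950  precision 1.000
```

Forty cells were simulated at 26 dB; the first iteration segments the
bright majority at threshold 5.09, the second picks up dimmer cells at
4.48, and matching against the true masks (centroids < 50 px apart, mutual
overlap > 60%) scores 38/40 found with no false positives — the two misses
are overlapping cells that threshold as one region.

The same flow from the shell:

```
acsat simulate -o sim --n-rois 40 --snr 26 --size 256 --seed 3
acsat run sim/I0.tif -o out            # labels.tif, rois.csv, run.json
acsat eval --pred out/labels.tif --truth sim/truth_labels.tif -o report.json
acsat collapse movie.tif -o I0.tif     # for real multipage recordings
acsat bench -o bench --snr 24 --snr 27 --n-rois 40 --reps 2 --seed 0
```

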