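# motionprf

Population receptive field (pRF) mapping with motion-defined bar stimuli,
as a tested, fully synthetic-data-capable pipeline.

Retinotopic maps are usually measured by sweeping a high-contrast bar across
the visual field while recording BOLD fMRI, then fitting each cortical
vertex with a 2D-Gaussian pRF. When the bar is defined not by luminance but
by *motion* — a patch of coherently moving dots against a background of
opposing, incoherent, or locally-paired dots — the estimated pRF properties
(responsivity, goodness of fit, pRF size) change dramatically across the
visual hierarchy (V1 … MT+). A key interpretive question is whether those
changes reflect genuine pRF differences or the *selective dropout* of
vertices whose bar-locked signal drowns in the background response. This
package implements the full analysis chain needed to study that question on
synthetic cortex with known ground truth:

* **`sweep_design`** — the bar-sweep protocol (2.4°-wide bar, 25 steps of
  0.7° and 1 s, 8 sweep directions plus 2 null trials → 250 volumes at
  TR = 1 s) and its binary per-volume apertures.
* **`dot_kinematics`** — the five dot-field conditions (`bar_only`,
  `kinetic`, `global`, `transparent`, `size_defined`): 2000 dots in a
  16 × 16° square, 180° direction reversals every 0.5 s, wraparound,
  bar-membership rules.
* **`prf_core`** — the forward model. For pRF parameters
  (x₀, y₀, σ, β, b), neural drive d(t) = Σₚ w(p)·aperture_t(p) with
  w(p) = exp(−((pₓ−x₀)² + (p_y−y₀)²)/2σ²), prediction
  ŷ(t) = b + β·(d ∗ h)(t) with a canonical double-gamma HRF h; plus run
  preprocessing (discard, linear detrend, z-standardise, average).
* **`prf_fit`** — two-stage estimation: exhaustive coarse grid search
  maximising Pearson r, then per-vertex Nelder–Mead refinement of
  (x₀, y₀, σ) with amplitude/baseline by least squares. Goodness of fit is
  R² = r²; the responsivity criterion is R² > 0.05, which for 250 volumes
  corresponds to p = 0.000367.
* **`synthetic_cortex`** — populations of vertices across V1, V2, V3, V3A,
  V3B and MT+ with eccentricity-scaled pRF sizes, per-condition bar and
  background response gains (the "neural visibility" account), and AR(1)
  BOLD-like noise.
* **`map_metrics`** — responsivity/size/fit summaries per area, polar-angle
  circular correlations (Jammalamadaka–SenGupta, Fisher-z group averaging),
  the selection-control analysis, pRF size vs eccentricity fits, gaze-MAD
  stability, and 4AFC bar-localisation scoring.
* **`pipeline` / `motionprf` CLI** — config-driven simulate → fit → report
  runs with manifests and tidy TSV outputs.

## Worked example

```python
import numpy as np
from motionprf import (PRFParams, build_sweep_design, render_apertures,
                       predict_timeseries, build_grid, grid_fit, fine_fit,
                       r2_to_pvalue)
from motionprf.prf_core import detrend_zscore

design = build_sweep_design()                  # 10 trials, nulls at 5 and 10
stack = render_apertures(design, grid_pixels=100)   # 250 binary apertures

truth = PRFParams(x0=2.0, y0=-1.0, sigma=1.5)
clean = detrend_zscore(predict_timeseries(truth, stack).values)
observed = clean + np.random.default_rng(0).normal(0, 1.0, clean.size)

grid = build_grid(None, stack)                 # 15 x 15 x 12 search grid
coarse = grid_fit(observed, grid)
fine = fine_fit(observed, coarse, engine=grid.engine)
print(f"coarse: x0={coarse.params.x0:+.2f} y0={coarse.params.y0:+.2f} "
      f"sigma={coarse.params.sigma:.2f} R2={coarse.r2:.3f}")
print(f"fine:   x0={fine.params.x0:+.2f} y0={fine.params.y0:+.2f} "
      f"sigma={fine.params.sigma:.2f} R2={fine.r2:.3f}")
print(f"p-value of the R2 > 0.05 threshold at T=250: {r2_to_pvalue(0.05, 250):.6f}")
```

prints

```
coarse: x0=+1.21 y0=-1.21 sigma=1.63 R2=0.557
fine:   x0=+1.79 y0=-1.20 sigma=1.83 R2=0.571
p-value of the R2 > 0.05 threshold at T=250: 0.000367
```

At a signal-to-noise ratio of 1 the coarse stage lands on the nearest grid
point; the simplex refinement moves the centre to within ~0.2° of the true
(2.0, −1.0) and improves R². The last line is the two-tailed p-value of the
default responsivity threshold given 250 observations.

An end-to-end synthetic experiment from the shell:

```bash
motionprf all --seed 1 --out runs/demo
```

writes a dataset bundle (truth table + per-run series), per-condition fit
tables, and report tables (area summaries, polar-angle correlation matrix,
selection-control analysis, parameter-recovery errors vs ground truth).

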