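# multifrac

Scale-dependent multifractal analysis of 2-D grayscale and binary
images.

Real images — histology sections, renderings of mathematical fractals,
any natural texture — are never true fractals: their scaling behaviour
changes with the scale at which you look.  Rather than forcing a single
fractal dimension through a log–log fit, `multifrac` treats the
generalized dimension as a *function of scale*,

    D_alpha(eps) = - dH_alpha / d log(eps),

where `H_alpha(eps)` is the order-`alpha` Rényi entropy of the box
measures at box side `eps`:

    mu_i     = (intensity in box i) / (total intensity),
    H_alpha  = 1/(1 - alpha) * log( sum_i mu_i^alpha )      [nats].

`alpha = 0` gives the box-counting dimension, `alpha = 1` the
information (Shannon) dimension, `alpha = 2` the correlation dimension.
Two ingredients make dense scale sweeps practical and stable:

* **Integral images (summed-area tables).**  After one cumulative pass
  over the pixels, the intensity in any `eps x eps` box is a four-corner
  lookup, so the measures at *all* scales cost `O(area * pi^2/6)` rather
  than `O(area * n_scales)`.
* **LOWESS differentiation.**  `H_alpha` vs `log(eps)` is differentiated
  by a locally weighted quadratic fit with Gaussian weights
  `exp(-((x - x0)/sigma)^2)`, which is far more robust to the
  stair-stepping of discrete box counts than finite differences.

The package also ships seeded generators of validation fractals with
known Hausdorff dimensions (Koch snowflake, quadric Koch island,
Sierpinski carpet, Pascal's triangle mod 3, chaos-game Sierpinski
triangle, fractional Brownian surfaces and their level-set outlines)
and a histology-style pipeline: threshold optimisation on a physical
scale band, 1-px outline extraction, per-subject core selection, and
Kruskal–Wallis group comparison with a rank-based multiple comparison.
It is aimed at quantitative-pathology and image-analysis researchers
who need morphological complexity measures tied to explicit physical
scales (micrometres), not a single unqualified "fractal dimension".

## Worked example

Estimate the box-counting dimension curve of an exact 2187 × 2187
Sierpinski carpet and average it over the 20–50 px plateau:

```python
import numpy as np
import multifrac as mf

carpet = mf.sierpinski_carpet(7)                  # 3^7 x 3^7, binary
H = mf.entropy_spectrum(carpet.to_intensity(),
                        scales=np.arange(2, 301), alphas=(0, 1, 2))
D = mf.dimension_curve(H, sigma=0.5)              # quadratic LOWESS
band = (D.scales >= 20) & (D.scales <= 50)
print(round(float(D.column(0.0)[band].mean()), 3))
```

This prints `1.869`, against the carpet's exact Hausdorff dimension
log 8 / log 3 ≈ 1.893: the estimate sits within 0.03 of truth on the
plateau, and stays within 0.1 of it across the whole 10–250 px range.
The same pipeline from the shell, via TIFF and tidy CSV:

```bash
multifrac generate sierpinski-carpet --iterations 7 --out carpet.tiff
multifrac analyze carpet.tiff --scales 2:300 --alphas 0 --out-dir out/
multifrac validate deterministic        # full fixture-vs-theory check
```

`analyze` writes `carpet_entropy.csv` and `carpet_dimension.csv`
(columns `image_id, eps_px, eps_um, alpha, D, sigma, degree,
edge_flag`) plus a `manifest.json` that records the exact configuration
for reproduction.  For tissue cohorts, `multifrac histology-run
manifest.csv --pixel-size 0.47` runs thresholding, outlining, core
selection and the grade comparison in one step.

## Layout

| module | contents |
| --- | --- |
| `multifrac.sat` | intensity/integral-image types, block sums, coarse-graining, TIFF/PNG reading |
| `multifrac.renyi` | natural measures, Rényi entropies, entropy spectra over scale grids |
| `multifrac.dimension` | Gaussian-weighted LOWESS fits and dimension curves |
| `multifrac.fractals` | seeded fractal generators with exact dimension metadata |
| `multifrac.histology` | thresholding, outlines, band means, core selection, group comparison |
| `multifrac.cli` | `multifrac generate / analyze / validate / histology-run` |

See `docs/methods.md` for the estimator's assumptions, parameter
choices and known limitations.
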