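# Methods

## Problem and approach

Soil-disinfestation trials (steam vs. chloropicrin fumigation vs. untreated
control) are traditionally scored by plant size and yield, which are slow to
measure and sensitive to camera geometry. `leafgreen` instead quantifies
*how dark green* the canopy is from ordinary RGB photographs: darker leaves
reflect higher chlorophyll/nutrient status, and the degree of greenness
within the green-leaf area does not depend on plant size or camera distance.

The pipeline is:

1. **Quantization.** Each photograph is reduced to a coarse palette and
   histogrammed into a *color table* — distinct RGB codes with pixel counts.
2. **Green profile.** Codes are classified green iff `G > R and G > B`
   (strict; equality is non-green). Among greens, the darkness index
   `(R + B) / G` orders codes from dark (near 0) to light. Pixel weights
   are `W_i = A_i / Σ A_j` over the retained green codes.
3. **Weighted statistics.** Five summaries per profile:
   `ΣW_i R_i`, `ΣW_i G_i`, `ΣW_i B_i`, `ΣW_i R_i/G_i`, `ΣW_i B_i/G_i`.
   The ratio means are means of per-code ratios, *not* ratios of channel
   means — the two differ whenever the greens are heterogeneous.
4. **Bootstrap.** Sampling distributions are approximated by resampling
   codes from Categorical(W); percentile intervals give 95% CIs for group
   means and pairwise treatment differences.
5. **Dark:light ratio model.** The ratio of dark-code to light-code area
   (defaults `(0,43,0)` and `(102,128,102)`; ratio > 1 means a darker,
   healthier canopy) is log-transformed and modelled across treatments and
   months with a random intercept per plot; cumulative yield (g/plant) is
   regressed on the May ratio by OLS.

## Quantization choices

Median-cut quantization (Pillow) with dithering disabled: dithering would
scatter pixel counts across fabricated intermediate codes and corrupt the
histogram. An image already holding no more colors than the palette size is
returned unchanged, so quantization is idempotent and always conserves the
pixel count. Because the exact palette used by any particular GIF converter
is tool-specific, a user-supplied fixed palette is also supported
(nearest-neighbor in Euclidean RGB, ties to the lowest palette index); that
path makes render → quantize an exact round trip and lets a known code list
be forced. 8-bit sRGB is assumed throughout; alpha is dropped and grayscale
promoted.

## Ordering caveat

The five common strawberry-canopy greens are exposed as
`COMMON_GREEN_CODES` in their conventional dark-to-light listing. That
listing is not monotone in `(R+B)/G` for the middle pair — `(51,85,51)` has
index 1.2 but `(51,85,0)` has 0.6 — and no standard darkness metric
reproduces it, so the package's canonical ordering is the index itself and
the fixed listing is available as a constant.

A related subtlety: moving pixel mass from a lighter to a darker code (by
the index) is guaranteed to not increase the *sum* `mean R/G + mean B/G`,
which equals the weighted darkness index exactly; it can increase one of the
two ratios individually when codes are not componentwise ordered. Property
tests therefore check the sum.

## Bootstrap

Defaults: `n_rep = 2000` replicates, `α = 0.05`, percentile intervals
(empirical α/2 and 1−α/2 quantiles, linear-interpolation definition —
`numpy.quantile(..., method="linear")`). Percentile rather than BCa/normal
intervals: it is the simplest construction consistent with resampling-based
CIs, and it is swappable. `n_draw` — the number of codes drawn per
replicate — is not a settled convention; the default resamples the
profile's own green-pixel population at its own size (capped at 1e5 for
tractability), the standard nonparametric bootstrap. CI width shrinks
roughly as `1/sqrt(n_draw)`, so the choice matters for interval width and is
configurable and reported on every result. Treatment differences resample
the two groups independently (independent field plots) and difference
replicates pairwise by index; a degenerate single-code profile yields a
zero-width interval at the exact value.

## Mixed model

`log_ratio ~ treatment * month (+ year)` with a random intercept per plot,
REML (statsmodels `MixedLM`). Month enters as categorical; year is added
additively when more than one year is present. The natural log is used.
Planned treatment contrasts are averaged over months and tested by Wald
t-statistics with **containment degrees of freedom**
`df = n_plots − n_treatments`, the between-unit df of a replicated block
design — at 12 plots and 3 treatments, df = 9. This is the small-sample
correction: with so few experimental units a normal reference would be
anti-conservative (Kenward–Roger/Satterthwaite are not available in
statsmodels). In the balanced one-observation-per-plot case this reproduces
the classic pooled two-sample t-test exactly (unit-tested).

Residual normality is checked by Shapiro–Wilk on marginal residuals
(response minus fixed-effect fit). Records with a zero dark or light count
have an undefined ratio; they are flagged, excluded with a warning, and a
Haldane-style +0.5 correction is available but off by default (it biases the
log ratio and is rarely needed at realistic pixel counts). A design with
fewer than two plots in some treatment is rejected: the plot intercept would
be confounded with the treatment effect. When REML profiling is singular
(e.g. noise-free data with zero residual variance) the fit falls back to OLS
with zero random-intercept variance, with which the mixed estimator
coincides at that boundary.

The yield regression is OLS of grams/plant on the untransformed May ratio,
matched by plot (and year); it requires at least three matched plots and
non-constant ratios.

## Synthetic trials

No photographs are distributed with the underlying field study, so the
`synth` module generates trials with the statistical structure the analysis
assumes: 2 years × 3 treatments × 4 plots × 3 months (May–July), one color
table per plot-month of 1e5 pixels (70% green over the five common codes,
30% non-green background: soil, fruit, mulch codes).

Treatments are parameterised by a shift on the *dark-code logit* of a shared
base mixture. Because renormalization cancels in a log-weight difference,
the latent log dark:light ratio of an image is exactly

    base + delta_treatment + b_plot + e_image,
    b_plot ~ N(0, plot_random_sd²),  e_image ~ N(0, residual_logratio_sd²)

— i.e. the generator's latent scale *is* the linear random-intercept model
the analysis fits, up to multinomial counting error (SD ≈ 0.014 on the log
ratio at the default pixel count, negligible against the residual SD).
Defaults: base log ratio −0.4 (control canopy lighter than dark, ratio
≈ 0.67), dark-shift 1.0 for both steam and chloropicrin (treated canopies
darker, ratio ≈ 1.82, and equivalent to each other), `plot_random_sd = 0.2`,
`residual_logratio_sd = 0.3`. These place the treatment effect well clear of
the noise at 4 plots per treatment while keeping single-trial inference
non-trivial, a realistic regime for a replicated block field trial. An
optional Dirichlet jitter (`within_image_noise`) perturbs the whole mixture
for heavier-tailed noise; it is off by default so the latent model stays
exact. Yields follow `800 + 400·(May log ratio) + N(0, 150)` g/plant,
putting control plots near 640 g/plant and treated plots near 1040 — the
right order of magnitude for strawberry.

Under these defaults the sampling SD of a treated-vs-control contrast
estimate from one simulated year is `sqrt(2·(0.2²/4 + 0.3²/12)) ≈ 0.19`, so
roughly 72% of single-trial estimates fall within ±0.2 of the true effect;
recovering the effect to ±0.2 with 90% reliability would need about twice
the plot replication. The test suite measures and documents exactly this.

`simulate_ratio_records` draws ratio records directly from the latent linear
model (same defaults) for fast estimator-calibration studies;
`simulate_trial` runs the full pixel route. `render_image` places a table's
pixels in seeded random arrangement so the image path (render → quantize →
profile) can be exercised losslessly under a fixed palette.

What the generator does *not* emulate: spatial structure within a canopy,
illumination gradients, camera noise, quantizer idiosyncrasies of any
particular GIF tool, plant loss, or month-by-treatment interaction (month
effects default to zero). Passing tests therefore demonstrate correctness of
the statistical machinery on palette-coded data, not robustness to raw field
photography.

## Numerical conventions

- Weights renormalize after every construction, truncation and pooling;
  `ΣW_i = 1` is enforced to 1e-12 in tests.
- `top_k` selection ties break by pixel count desc, then darkness index
  asc, then lexicographic RGB — fully deterministic.
- All randomness flows through `numpy.random.Generator`; every simulating
  function accepts a seed or a Generator and is bit-reproducible.
- Percentile intervals on a constant replicate vector are the zero-width
  interval at that constant, not an error.
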