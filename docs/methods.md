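# Methods

## The comparison model

Two co-registered rasters `a` and `b` on an `n_rows x n_cols` grid with a
shared validity mask are compared at window radii (scales) `s = 1..20`.
The window at scale `s` is the Euclidean disc of integer offsets
`{(dr, dc) : dr^2 + dc^2 <= s^2}` — 5 cells at scale 1, 13 at scale 2, up
to 1257 at scale 20. On a 10-arcmin grid the scale-1 window's bounding
box spans `(2*1+1)/6 = 0.5` degrees, and windows grow to continental
extent by scale 20, so the profile reads as agreement-by-spatial-scale.

At each valid centre cell the window is intersected with the grid and the
mask (no padding — padding would fabricate data) and one of three indices
is computed over the surviving cell pairs:

- **kappa**: Cohen's kappa `(p_o - p_e) / (1 - p_e)` from the window's
  2x2 contingency table of two binary maps. When both window samples are
  constant, `p_e = 1` and the ratio is 0/0; we define the value as 1 when
  the samples are identical and 0 otherwise. This happens routinely in
  small windows deep inside a range or far outside it, and a finite value
  there keeps profile averages meaningful; note the "0 otherwise" branch
  coincides with the formula's limit, since constant-but-different
  samples give `p_o = p_e`.
- **D**: mean absolute difference of two `[0, 1]`-standardized maps.
- **CC**: Pearson correlation of the paired window values; undefined when
  either sample has zero variance (there is no direction of variation to
  correlate) or fewer than 3 cells.

A centre is undefined at a scale when fewer than 50% of the full disc (and
never fewer than 3 cells) are valid — near coasts and corners small valid
samples would otherwise make the indices erratic. The fraction is a
parameter (`min_valid_fraction`) on every windowed operation.

The per-scale **profile** averages the monoscale map over its *defined*
centres only (undefined centres are excluded, not counted as zero); the
**multiscale map** averages each pixel over the scales where it is
defined, masking pixels defined nowhere. "Monoscale 0" — the pixel-by-pixel
statistic over all valid cells jointly — is reported separately as
`global_0` and is not part of the profile mean: a radius-0 window cannot
support kappa or a correlation, so the `*_mean` summaries cover scales
1..20 exactly.

### Numerical route

Windowed counts and sums are convolutions with the disc stencil, computed
by `scipy.signal.convolve` (FFT-backed for large grids, direct for small
ones). Counts of 0/1 fields are rounded back to exact integers, so the
kappa path is bit-for-bit the brute-force result; for D and CC the
convolution route agrees with explicit window enumeration to ~1e-13, and
the test suite pins both routes together at 1e-12 on random grids. CC's
zero-variance test uses the guard `n*Sxx - Sx^2 > 1e-9 * n^2` so that
convolution round-off in a truly constant window cannot manufacture a
spurious correlation. All accumulation is double precision; iteration
order is fixed, so every result is reproducible byte for byte.

## Validation model

Scores are min–max standardized over valid cells (`standardize`); a
constant map maps to all zeros — a flat score carries no discrimination
and zero keeps its dichotomisation conservative. The ROC enumerates every
distinct valid score as a candidate threshold (plus a sentinel above the
maximum) with the inclusive rule "score >= threshold means presence", so
the chosen threshold itself classifies as presence. AUC is the
trapezoidal area, identical to Mann–Whitney concordance with ties at 1/2,
and is reported raw even below 0.5. The SPT maximises Youden's
J = TPR − FPR — the ROC point farthest from the 1:1 line — with ties
broken toward the smallest (most inclusive) threshold. Kappa requires
both classes among the observations; a single-class observation raises
rather than returning a degenerate curve.

## Synthetic study conditions

The generator emulates the statistical structure of a mid-latitude
10-arcmin climate grid, not any real dataset:

- grid: 100 x 120 cells at 1/6 degree, ~25% masked as sea in contiguous
  blobs (a smoothed-noise field thresholded at the sea-fraction quantile);
- `t_cold` (coldest-month minimum temperature): linear south–north
  gradient from +8 to −22 °C plus Gaussian-correlated noise, sd 2 °C,
  correlation length 5 cells — CMP is only informative on spatially
  structured fields, so the noise is smoothed, not white;
- `gdd5` (degree-days above 5 °C): 3500 down to 200 poleward, noise
  sd 250, floored at 0;
- `moisture`: west–east index 0.15–0.85, noise sd 0.15, clipped to [0, 1].

Three toy models give the three structural classes of SDM output:

1. **envelope**: product of trapezoidal responses — zero outside each hard
   limit, linear ramp inside (ramp widths 4 °C, 400 degree-days, 0.15
   moisture), one in the core. Sharply bounded, like a fitted climate
   envelope.
2. **hybrid**: logistic growth in GDD5 (midpoint 900, scale 350) times
   logistic growth in moisture (0.3, 0.1), gated by four bioclimatic
   limits — minimum GDD5 for establishment, minimum coldest-month
   temperature for survival and (stricter) establishment, maximum
   coldest-month temperature for establishment. The gates define nested
   zones establishment ⊆ survival ⊆ {growth > 0} *by construction*; the
   nesting test asserts the construction is intact, not an empirical
   discovery.
3. **fitness**: probability of surviving frost (logistic in `t_cold`)
   times drought survival (logistic in moisture) times the probability of
   ripening seed (logistic in the heat sum beyond a requirement). Smooth
   everywhere.

Three species presets (boreal-, temperate- and drought-limited-like)
displace the limits along the gradients so the models produce genuinely
different ranges. Observations are the standardized envelope truth
thresholded at 0.5 with 10% independent label flips — a stand-in for
atlas data with detection/registration error. What passing tests show is
that the *methodology* behaves correctly on fields with realistic spatial
structure; the toys say nothing about the skill of any real SDM, and the
generator omits real-data features such as anisotropic climate, spatially
correlated observation error, dispersal limitation and elevation.

Every generator takes an explicit seed; nothing reads global random
state, so any study configuration reproduces byte-identical reports.

## Null baseline

`null_baseline` draws replicate pairs of independent Bernoulli(p = 0.5)
maps on a fully valid grid and runs the kappa CMP on each. Chance
agreement centres the profile on ~0; with 10 replicates of 200 x 200 the
grand mean over scales 3–20 is of order 1e-3, comfortably inside the
~0.01 floor quoted for unstructured patterns. This is the reference
against which a real profile's broad-scale values are read.

## Anomaly profiles

For model profiles `k_m(s)` the cross-model mean is `mean(s)` and the
anomaly of model m is `(k_m(s) - mean(s)) / mean(s)`, undefined where the
mean is zero. This relative-to-mean form makes anomalies sum to zero
across models at every scale; it is one natural reading of a
"relative anomaly" and is recorded here as this package's definition.

## Problem sizes and defaults

The default study (3 species x 3 models, scales 1..20, 100 x 120 grid,
5-replicate null) runs in a few seconds; the acceptance experiment
(10 replicates, 200 x 200) in under a minute. Test grids are 10–50 cells
a side with scales <= 6, which is where brute-force oracles remain
exact and fast while still exercising border clipping, masks and
degenerate windows.

## Known limitations

- No reprojection or resampling: inputs must already be co-registered,
  and masks must be *identical* (the intersection is never taken
  silently; a mismatch is an error by design).
- The disc membership rule is fixed at `d^2 <= s^2`; other software may
  use a slightly different rounding of the circle.
- Only isotropic circular windows; no FFT-sized performance tuning beyond
  scipy's automatic method choice.
- GeoTIFF support covers single-band float rasters with the basic GDAL
  geo-tags; multi-band imagery, CRS handling and compressed tiles are out
  of scope.
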