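# Methods

This note records the models, parameter choices and numerical decisions
behind `tidemark`, and what the synthetic benchmark does and does not
establish about real imagery.

## Radiometric chain

The calibration chain is the classic Landsat TM/ETM+ recipe. DN → radiance
uses the per-band linear rescale with gain `(L_max − L_min)/(Q_max −
Q_min)` and bias `L_min − G·Q_min`, so the DN endpoints map to the
published radiance endpoints exactly (this identity is asserted in tests).
Radiance → TOA reflectance is `ρ = πLd²/(E0 cos θ_s)`; reflectance is
deliberately *not* clipped at 1 at this stage, since specular cells can
legitimately exceed it and clipping would bias later statistics.

**DOS1.** The path-radiance estimate is

    L_p = L_min + (L_max − L_min)/255 · DN_min − 0.01·(E0·cosθ_s·T_z + E_down)·T_v/π

with `T_v = T_z = 1`, `E_down = 0`. Two things deserve flags:

* The haze term divides by the fixed constant 255 rather than by
  `Q_max − Q_min`, and carries no `d²` term. This is the formula as used in
  the originating workflow and is implemented verbatim; it equals the DN
  gain only when `Q_max − Q_min = 255`. The consequence is that `L_p` can
  come out negative for dark scenes — the implementation applies it as-is
  (radiance increases) and emits a warning. The exact haze-shift
  cancellation property therefore holds only for calibrations with a DN
  span of 255, and the test asserting it to 1e−9 uses `Q_min = 0,
  Q_max = 255`.
* `DN_min` uses the histogram method: the smallest DN whose frequency
  reaches `dark_fraction` of the valid pixels (default 0.0001). The default
  makes the estimate robust to isolated dead-dark pixels while still
  finding the dark-object population; a uniform raster trivially returns
  its single DN. If no bin reaches the cut the absolute darkest pixel is
  used.

Corrected radiance is floored at zero *after* subtraction. Classification
consumes floating-point reflectance; the 8-bit export (`clip to [0,1]`,
scale by 255, round half up) exists for interoperability only, avoiding a
second quantisation loss in the analysis path.

MTL-style metadata accepts either `SUN_ZENITH` or `SUN_ELEVATION` (zenith
= 90° − elevation), since archives store one or the other.

## Spectral separability

The Jeffries–Matusita distance is computed per band from univariate class
sample moments (unbiased n−1 variance):

    B  = (μ₁−μ₂)² / (4(σ₁²+σ₂²)) + ½·ln[(σ₁²+σ₂²)/(2σ₁σ₂)]
    JM = 2(1 − e^(−B))

The univariate-Gaussian form is used because the selection operates on one
band at a time and produces the per-band scalar a separability table needs;
a full-covariance multivariate J–M is out of scope. Multi-sensor series are
handled by *pooling* samples across scenes before taking moments (rather
than averaging per-scene distances): pooling answers the operational
question — how separable are the classes in the combined training pool the
classifier will actually see. Selection drops bands with JM < 1.0 and keeps
the top `n_keep = 3` by JM descending, breaking ties by the fixed order
SWIR1, NIR, Red, SWIR2, Green, Blue, Thermal (the field's prior on
mangrove discrimination power). Zero-variance classes are an error, not a
silent JM = 2.

## Classification

The classifier is a soft-margin RBF-kernel SVM, defaults `g = 0.091`,
`C = 100`, on the three selected bands. The dual optimisation is delegated
to scikit-learn's SVC; the package owns and tests everything that defines
the method's behaviour: the kernel formula, the deterministic per-class
sampling (uniform without replacement, ≥400 pixels per class, seeded), the
two-class decision rule (decision function > 0 → non-mangrove, ≤ 0 →
mangrove, invalid pixels → nodata), and a serialization
(support vectors + dual coefficients + bias in one `.npz`) from which the
decision function is reproduced bit-for-bit with the package's own kernel —
a test cross-checks it against SVC's `decision_function` to 1e−10. No
feature scaling is applied by default because reflectance features already
live in [0, 1]; a `standardize` switch exists for users feeding other
units. A cross-validated grid-search utility is provided but the defaults
are fixed, not retuned per scene.

Two contracts only hold in the hard-margin (separable) regime and are
tested there: duplicating every training point leaves the decision surface
unchanged, and swapping labels flips its sign — with bounded dual
coefficients (`α = C`) both can fail for overlapping data, which is
expected behaviour, not a bug.

## Accuracy assessment

Confusion matrices are always oriented rows = reference, columns =
predicted, and every output says so; producer's vs user's accuracy is
meaningless without that statement. Kappa is Cohen's unweighted form.
Classes with an empty row or column yield NaN for the affected metric —
reported as missing rather than zero, so downstream averaging cannot be
silently biased.

## Change statistics and the Markov model

Areas are pixel counts × `pixel_area_ha` (0.09 ha at 30 m). Percent change
is the signed `(S_j − S_i)/S_i × 100`; gain/loss markers are formatting
derived from the sign.

Transition estimation cross-tabulates jointly classified pixels and
normalises rows. A class with zero pixels at date 1 receives an identity
(persistence) row with a warning — the alternative (NaN row) would
propagate through every projection.

**Orientation.** The projection uses the row-vector convention
`v_{t2}ᵀ = v_{t1}ᵀ·M` with row-stochastic `M`. The column convention
`v_{t2} = M·v_{t1}` does not conserve total area for a row-stochastic
matrix; conservation (proportions summing to 1, areas summing to the fixed
study area) is asserted for every horizon.

**Fractional horizons.** Horizons that are not whole multiples of the
estimation interval (e.g. 10 years on a 7-year matrix) use
`fractional_matrix_power`, then clip any small negative entries to 0 and
renormalise rows — the standard annualisation repair in land-change
software. Integer ratios always use exact repeated multiplication, and the
fractional path is pinned by tests: at `h = interval` it reproduces `M` to
1e−9, at `h = 2·interval` it reproduces `M²`. Non-diagonalizable or
complex-contaminated cases fall back to the nearest integer power with a
warning.

**Validation.** Pearson's `χ² = Σ(O−E)²/E` compares projected and observed
per-class areas, with `(q−1)²` degrees of freedom (1 for the two-class
case, critical value 3.841 at α = 0.05, taken from `scipy.stats.chi2`).
Note `(q−1)²` is the transition-matrix convention for this workflow; a
plain one-way goodness-of-fit would use `q−1` — identical for `q = 2`.

## Synthetic benchmark

The generator emulates a multi-decadal archive over a mangrove coastline:

* **Dynamics.** Epoch 0 thresholds a smoothed Gaussian random field at the
  target mangrove fraction (default 0.5), giving spatially coherent
  patches. Later epochs apply independent per-pixel transitions with the
  generating matrix `M* = [[0.9, 0.1], [0.2, 0.8]]` per 5-year step —
  sticky classes with net mangrove gain towards the 2:1 stationary mix,
  the kind of slow decadal turnover coastal land-cover series show.
  Transitions are deliberately aspatial because the Markov model under
  test is aspatial; optional majority smoothing adds visual realism but is
  off in statistical tests since it biases transition recovery.
* **Rendering.** Per class and band, reflectance is Gaussian (defaults:
  mangrove dark in SWIR1 at 0.10 vs 0.30, bright in NIR at 0.45 vs 0.30,
  sd 0.02, clipped to [0, 1]), inverted through the TOA equation and the
  linear calibration to 8-bit DN. The default calibration sets each band's
  `L_max` to the radiance of unit reflectance, so the DN range spans
  reflectance 0–1. With zero noise every class renders to a single DN per
  band, making exact-recovery tests meaningful; the quantisation error
  bound (one DN step, converted to reflectance) is asserted.
* **Benchmark size.** 256×256 pixels, five epochs: large enough that
  binomial standard errors on `p_ij` are ~0.2–0.4 percentage points and
  3σ recovery bands are tight, small enough that the full chain runs in
  seconds.

What passing these tests shows: the chain is internally consistent — the
calibration inverts the rendering, the classifier recovers designed
signatures, transition estimation is unbiased under the generator's own
assumptions. What it does not show: performance under mixed pixels, tidal
inundation, atmospheric variability beyond additive haze, spatially
correlated class noise, sensor cross-calibration drift, or reference-map
error — all present in real archives. Real-imagery accuracies will be
lower than the benchmark's.

## Published-area arithmetic

`tidemark.published` ships a small CSV of published regional mangrove
area estimates for Palawan (1988–2020) with projected 2030/2050 extents,
used as inputs to the percent-change arithmetic (driver 08 and the
acceptance script). The table reproduces the source numbers as printed;
minor internal inconsistencies in that record (sub-hectare rounding
between a printed delta and the difference of the printed areas) are left
as printed, and the percent changes are always recomputed from the areas.

## Known limitations

* GeoTIFF I/O writes/reads the core georeferencing tags (pixel scale,
  tiepoint, minimal GeoKey directory, GDAL nodata) via `tifffile`; CRS
  handling is an identifier string, with no reprojection or datum logic.
* Two classes only; the confusion/transition machinery is q-class but the
  generator, classifier and CLI assume mangrove vs non-mangrove.
* No spatial allocation of projected change (no cellular-automata stage):
  projections are proportion vectors, not maps.
* Cloud masks are consumed, never detected; mask provenance is the user's
  problem.
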