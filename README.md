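# tidemark

Multi-temporal mangrove change detection and Markov-chain projection from
calibrated satellite imagery.

`tidemark` is for coastal remote-sensing practitioners and land-change
modellers who map mangrove extent from Landsat-class imagery and want a
single, testable chain from raw digital numbers to projected future extent.
The package implements every stage — sensor calibration, spectral band
selection, supervised classification, accuracy assessment, change
statistics, and Markov projection with chi-squared validation — and ships a
synthetic-scene generator with known ground truth so the whole chain can be
exercised and scored without any satellite downloads.

## The model

**Calibration.** Digital numbers become at-sensor radiance through the
linear rescale `L = G·DN + B` with `G = (L_max − L_min)/(Q_max − Q_min)`,
`B = L_min − G·Q_min`, then top-of-atmosphere reflectance
`ρ = π·L·d² / (E0·cos θ_s)` (Earth–sun distance `d` in AU, solar zenith
`θ_s`). Path radiance is removed by dark-object subtraction (DOS1), which
assumes true dark objects reflect 1% and estimates the haze signal from the
darkest populated DN of the scene histogram.

**Band selection.** Per-band Jeffries–Matusita distance between the
mangrove and non-mangrove sample distributions,
`JM = 2(1 − e^{−B})` with the Gaussian Bhattacharyya distance `B`, scored
in [0, 2]; bands under 1.0 are dropped and the top three survivors are kept
— characteristically SWIR1–NIR–Red, because mangrove canopies are
distinctively dark in the short-wave infrared.

**Classification.** A soft-margin SVM with the RBF kernel
`K(x,x′) = exp(−g‖x−x′‖²)`, defaults `g = 0.091`, `C = 100`, trained on
≥400 random pixels per class. Maps are scored with confusion-matrix
statistics: overall, producer's and user's accuracy, and Cohen's kappa
`κ = (p_o − p_e)/(1 − p_e)`.

**Change and projection.** Class areas are pixel counts × 0.09 ha (30 m
grid); change between dates is the signed percent
`(S_j − S_i)/S_i × 100`. Cross-tabulating two dates gives transition counts
`n_ij` and the row-stochastic Markov matrix `p_ij = n_ij/n_i`; future
proportions follow `v_{t+h}ᵀ = v_tᵀ Mʰ` with `h = horizon/interval`
(fractional powers by eigendecomposition, repaired to row-stochastic form).
Projections are validated against observations with Pearson's
`χ² = Σ(O−E)²/E` at `(q−1)²` degrees of freedom — critical value 3.841 for
two classes at α = 0.05.

## Worked example

The numbered drivers under `analysis/` run the whole chain on the
benchmark synthetic landscape (256×256 pixels at 30 m ≈ 5900 ha, five
epochs on a 5-year step, generating matrix `[[0.9, 0.1], [0.2, 0.8]]`,
seed 42). Equivalently from the shell: `tidemark all --seed 42 --out run/`.

```bash
cd analysis
python 01_simulate_landscape.py   # ... 07_markov_projection.py
```

Band selection (03) ranks the bands exactly as designed:

```
   band       jm  selected
  SWIR1 1.999992         1
    NIR 1.997754         1
    Red 1.840717         1
  SWIR2 1.338955         0
  Green 0.486523         0
   Blue 0.233952         0
Thermal 0.066651         0
```

Change statistics (06) recover the simulated mangrove expansion — the
landscape relaxes towards the chain's 2:1 stationary mix, so gains shrink
each period — and the first-interval transition matrix lands within
sampling error of the generating `[[0.9, 0.1], [0.2, 0.8]]`:

```
 from   to  area_initial_ha  area_final_ha  delta_ha  percent direction
 1988 1993          2949.12        3233.61    284.49 9.646606      gain
 1993 1998          3233.61        3447.00    213.39 6.599126      gain
 1998 2003          3447.00        3582.27    135.27 3.924282      gain
 2003 2008          3582.27        3675.87     93.60 2.612868      gain

            to_1      to_2
from_1  0.898987  0.101013
from_2  0.197479  0.802521
```

Projection (07) carries the 2008 map 10 and 30 years forward (fractional
matrix powers for the 2-interval and 6-interval horizons) and the
chi-squared back-validation accepts the model:

```
chi-squared validation: statistic 0.014 vs critical 3.841 (df=1, alpha=0.05)
-> agreement not rejected
```

Driver 08 applies the same percent-change arithmetic to the bundled record
of published Palawan regional mangrove areas (1988–2020, plus projected
2030/2050 extents), e.g. Puerto Princesa City 1988–1998: 2876.3 →
5634.2 ha, +95.88%.

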