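# Methods

`eggfresh` calibrates egg freshness — the Haugh unit (HU) — against
visible/short-wave-NIR semi-transmittance spectra.  The pipeline is: spectral
pretreatment, equal-width interval division of the wavelength axis, one PLS1
model per interval ("member" models), and a Lasso regression over the
members' cross-validated outputs that simultaneously selects informative
intervals and fuses the survivors into the final predictor.  This note
records the model, the knobs that matter, and the design choices that were
genuinely open.

## Freshness indicators

The Haugh unit combines thick-albumen height `H` (mm) and egg weight `W` (g):

    HU = 100 · log10(H − 1.7 · W^0.37 + 7.57)

`log` is taken base-10 (the standard form of the formula).  Supporting
indicators are the weight loss rate (percent of arrival weight lost during
storage), the yolk coefficient (yolk height / diameter) and the egg shape
index (long / short axis).  HU grade boundaries (AA/A) are deliberately not
encoded; grading is out of scope.

## Sample handling

* Replicate scans (three per egg, taken at 120° rotations in the emulated
  design) are arithmetically averaged per egg *before* outlier screening and
  splitting.
* Outlier screening at significance level α (default 0.05) is two-sided:
  spectral outliers by Mahalanobis distance of PCA scores — components
  retained until ≥ 99 % of variance — against a χ²(k) quantile at 1 − α;
  reference outliers by a two-sided z test on HU.  The specific statistic is
  a standard chemometric choice, not a reconstruction of any particular
  instrument software; both thresholds are configurable.  Note that the
  99 %-variance rule presumes smooth, low-rank spectra; on full-rank white
  noise it degenerates to near-uniform leverage and flags nothing.
* The calibration/prediction split is a seeded uniform shuffle at ratio 2:1
  with the calibration share rounded half-up (103 samples → 69 + 34).

## Pretreatments

SNV (row-standardisation, sample SD with n − 1), MSC (per-row OLS against a
reference spectrum, default the calibration mean, then inversion) and a
Savitzky–Golay first derivative (5 points, degree 2, per index, edges
handled by evaluating the boundary polynomial so the column count is
preserved).  The derivative treats the axis as evenly spaced; a per-nm
rescale would only multiply every value by a constant and cannot change any
downstream model.  The working pretreatment for the interval sweep defaults
to `none`: on both the emulated data and the kind of study this mirrors,
scatter correction buys little because the informative variation is already
band-shaped, while differentiation amplifies channel noise.

## PLS1 members

Mean-centred NIPALS PLS1 (no variance scaling — standard for spectra).  The
latent-variable count is chosen per model by k-fold cross-validation
(default 5 folds, venetian-blind assignment after one seeded shuffle, the
same scheme reused for every stage so fold structure is shared) at the
minimum RMSECV, ties to the smaller count, capped at
min(20, columns, training rows − 2).  One deflation pass per training fold
serves every candidate count, so LV selection costs one fit per fold.  The
regression vector B = W(PᵀW)⁻¹q reproduces the deflation recursion to
1e−8; if X deflates to numerical zero the remaining components contribute
nothing rather than erroring, which keeps cross-validation defined at any
requested complexity.

## Interval division and member diagnostics

`p` variables split into `n` contiguous intervals of width floor(p/n), the
first `p mod n` intervals taking one extra variable (2041 in 6 → 341 + 5×340).
Intervals are reported 1-based as "k/n".  Per interval the member's LV count
is selected once on the full calibration CV; the fold refits that produce
the member's out-of-fold predictions reuse that count (cheaper and more
stable than per-fold reselection; the alternative is available via the
library API by calling `cross_validate_lv` per fold).  Those out-of-fold
predictions — never in-sample fits — are the fusion inputs, which avoids
leaking training fit into the stacking stage.

## Lasso fusion

With member-output matrix Z (calibration samples × n members) the fusion
solves

    min_{β0, β}  (1/2N) Σᵢ (yᵢ − β0 − Σⱼ z_ij βⱼ)² + λ Σⱼ |βⱼ|

by cyclic coordinate descent on centred, unit-variance-scaled columns,
intercept unpenalised, coefficients reported back on the HU scale;
convergence when the largest coefficient change in a sweep is below 1e−7.
The same optimum under a plain residual-sum-of-squares objective corresponds
to λ_ssr = 2N·λ.  The inner kernel works on the Gram matrix (O(m) per
coordinate update) and is numba-jitted; adjacent-interval members correlate
above 0.99, which makes the small-λ end of the path genuinely slow to
converge, so the sweep cap is generous (2×10⁶).

λ is chosen on a 100-point log grid from λ_max (smallest all-zero penalty)
down to λ_max·10⁻⁴ by 5-fold cross-validated MSE, minimum rule, ties to the
larger (sparser) penalty, warm-starting each grid point from the previous
one.  Members with coefficient exactly zero (or below 1e−10 after
back-scaling) are discarded; the survivors are the selected intervals.

A 1-way division has a single member — the full-spectrum PLS — and the
fusion passes it through unchanged (identity coefficients), so the n = 1
fusion *is* the plain PLS model, bit for bit.

## Division sweep and model choice

The sweep fits the fusion for every division count 1..n_max (default 40).
Reported RMSECV applies the final Lasso to the member cv-outputs; because
the λ search and the final fit both consume those same cv-outputs, this
RMSECV is optimistic for large n — the Lasso stage can overfit many noisy
members, and on simulated studies RMSECV keeps drifting down with n while
RMSEP rises.  That is a property of the method itself, so model choice does
not trust RMSECV alone: `best_n` minimises prediction-set RMSEP among the
divisions whose RMSECV lies within a configurable margin (default 5 %
relative) of the global minimum.

Two stacked comparators frame the fusion: **PLS-s1**, a single PLS on the
concatenated columns of the fusion-selected intervals (a synergy-interval
PLS without the combinatorial search), and **PLS-s2**, an unpenalised
least-squares stack of all n members (minimum-norm solution with a warning
if rank-deficient).  One naming caveat: published descriptions of these two
comparators are not always consistent between running text and table
footnotes; here s1 is always "PLS on the selected spectra" and s2 the
"unpenalised stack of all members".  With a single member PLS-s2 reduces to
an affine recalibration of the plain PLS output (its prediction-stage
correlation is identical; its in-sample RMSE can only be lower, by OLS
optimality) rather than to the PLS model verbatim.

## Synthetic data generator

No public egg-spectra set exists for this design, so the generator is a
first-class module with a *known* HU → spectrum link:

* **Cohort** (default 105 eggs over storage days 1–13, 15 per sampling day):
  arrival weights from a truncated normal whose truncated mean is 57.53 g
  (SD 4.095 g, bounds 49.1–69.5 g; the location parameter is solved so the
  asymmetric truncation does not bias the mean); a population HU trajectory
  piecewise-linear through (day 1, 85), (7, 79), (9, 70), (13, 64) — a gentle
  early decline with a drop after the first week — plus persistent egg-level
  offsets (SD 3) and measurement-day scatter (SD 1.5), clipped to [56, 91];
  weight loss accumulating ≈ 0.55 %/day; yolk coefficient declining with day;
  shape index normal around 1.273 (SD 0.037).  Albumen height is back-solved
  from the Haugh formula, so the indicator module reproduces the assigned HU
  exactly.
* **Spectra** (550–985 nm, 2041 points): a smooth transmittance hump minus
  Gaussian absorption valleys at 645/770/880/970 nm.  Valley depths are
  affine in HU *and* in storage day (a Beer–Lambert-style surrogate; the
  day term emulates water-loss absorption changes that are only partly
  coupled to HU), the overall level declines with day, and each egg carries
  broad nuisance structure and valley-depth noise uncorrelated with HU.
  Replicates get multiplicative lognormal scatter, additive offsets and
  white noise.  The per-egg valley-depth noise (default SD 2.0 %T) is the
  knob that sets the attainable accuracy; the default puts plain-PLS RMSEP
  near 5 HU for a ~65-egg calibration set — the error scale typical of
  SW-NIR egg-freshness calibrations — which makes the generator a realistic
  test bed, not a claim about any particular instrument.
* **Planted-interval oracle** (`plant_interval_signal`): iid-normal columns
  with y a unit-variance combination of each signal interval's columns under
  a smooth band-shaped weight profile plus noise.  Band-shaped, because an
  absorption feature spans contiguous channels; a handful of isolated signal
  columns inside a 300-column interval is a regime where PLS provably cannot
  concentrate its first weight vector, and an oracle built that way probes
  identifiability, not selection logic.

What passing tests on this generator do **not** show: robustness to
instrument drift, eggshell-colour effects, nonlinear HU–absorbance links, or
any physically calibrated %T magnitudes (the baseline level is arbitrary).

## Problem sizes and numerical choices

The test suite runs planted-signal recovery at full spectral width
(p = 2041, 100 calibration samples, 6- and 26-way divisions, 20 seeds) and
the paired fusion-vs-member comparison on 10 simulated studies of 150 eggs;
the acceptance script runs the complete protocol (105 eggs, divisions 1–40)
in a few minutes on one core.  Support-recovery simulations use the
26-interval division: at coarser divisions with only two signal-bearing
intervals, each member's accessible R² is below 0.5 and a ~200-column
interval at n = 100 leaves member models statistically indistinguishable
from the null (verified against an independent PLS implementation), so
selection cannot be probed there.

Degenerate inputs fail loudly and early: constant rows in SNV/MSC,
non-positive Haugh arguments, zero-variance y, empty interval selections,
mismatched wavelength axes.  Ties are deterministic everywhere (smallest LV,
largest λ, first minimum).  Fixed seeds make every dataset, split, fold
assignment and therefore every fitted model bit-reproducible.
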