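# Methods

This note documents the models and numerical conventions implemented in
nircal, the choices made where conventions are genuinely open, and what the
synthetic-data generator does and does not establish.

## Spectral containers and the wavelength grid

Spectra are stored as log(1/R) apparent absorbance on a uniform grid. The
standard Vis/NIR instrument grid is declared as **400–2498 nm inclusive at
2 nm steps (1050 channels)**. An inclusive 400–2500 nm grid at 2 nm would
contain 1051 points; the 1050-point count is the fixed convention here, so
the last channel sits at 2498 nm. Duplicate scans are averaged
arithmetically per sample before any modelling.

## Pre-treatments

A math treatment is the tuple `(derivative order, gap, smooth1, smooth2)`
plus a scatter mode in {none, snv, dt, snv-dt}; tuple units are data points
(2 nm each). Scatter correction is applied **before** derivation, SNV
before detrend. Which order a closed-source instrument package uses
internally is unpublished; the scatter-first convention is fixed here and
recorded in model metadata.

- **SNV** standardises each spectrum to mean 0, SD 1 (n−1 denominator),
  removing multiplicative scale and additive offset exactly. Constant
  spectra raise an error naming the sample.
- **Detrend** subtracts the least-squares polynomial in wavelength, degree
  2 by default (the Barnes SNV-DT convention), computed against an
  orthonormalised Vandermonde basis for conditioning.
- **Gap–segment derivative** follows the Norris convention: boxcar mean of
  width `smooth1`, then segment differences across `gap` points
  (first order: x̄[i+g] − x̄[i−g]; second order: x̄[i−g] − 2x̄[i] + x̄[i+g]),
  then a second boxcar of width `smooth2`. Smoothing widths are forced odd
  (even inputs rounded up) so windows stay centred. Edge channels whose
  full window does not fit are filled with the nearest valid value and
  flagged False in a column mask; masked channels keep the grid length but
  are excluded from PCA and regression. The implementation is
  parameter-compatible with, not bit-identical to, closed commercial
  filters, whose exact algorithm is unpublished.

## Modified PLS

`MPLSRegression` implements single-response NIPALS PLS. In `pls1` mode it
is the textbook algorithm on centred data (verified in tests against an
independent PLS implementation to 1e-6 relative). In `mpls` mode
(Shenk–Westerhaus "modified" PLS), after each factor is extracted and
deflated, every spectral residual column and the reference residual are
divided by their current standard deviations before the next factor is
extracted. Centring uses calibration means only; no autoscaling occurs
before factor 1, which is what distinguishes MPLS from column-autoscaled
PLS. The two modes coincide exactly at one factor.

All scalings are composed into an accumulated coefficient vector per
factor count, maintained by propagating the linear map from original
centred spectra into the current residual space; prediction is then a
single dot product and reproduces the sequential factor path to machine
precision (asserted in tests at 1e-8). Residual-SD divisors are floored at
1e-12 × the largest column SD (exhausted columns divide by 1), and factor
extraction truncates with a warning when the residual rank is exhausted.
Loading and weight vectors are exposed per factor, sign-normalised so the
largest-magnitude element is positive. Note that in NIPALS PLS1 the
*weight* vectors are orthonormal; loading vectors are generally not.

## Population structure (CENTER) and the split

PCA is run on the pre-treated spectra (default treatment 2,5,5,2 SNV-DT,
shared with calibration; the choice is recorded with the split). The
smallest number of components explaining ≥ 99 % of variance is retained.
GH is the squared Mahalanobis distance in score space — diagonal
covariance given by the PCA eigenvalues (n−1 denominator) — divided by the
number of retained components, so E[GH] ≈ 1 for a Gaussian population and
the conventional cutoff GH > 3 is meaningful at any dimensionality.

Non-outliers are ranked by ascending GH (ties broken by sample id) and
every *n*-th rank (default 5) becomes validation; taking the *n*-th rather
than the 1st keeps boundary samples in calibration. 156 non-outliers at
1-in-5 yield a 31/125 split; a 30/126 split arises only if an extra sample
is removed first, so the split size is a parameter, not a constant.

## Cross-validation and statistics

Folds (default 4 groups) are assigned round-robin over the GH ranking —
deterministic and spectrally balanced; a seeded random assignment is
optional. SECV(k) is the root mean squared held-out residual pooled over
folds; the selected factor count k* minimises it, and `groups = N` equals
brute-force leave-one-out exactly (tested at 1e-9).

External validation reports bias = mean(ŷ−y), SEP = √(Σe²/(N−1)),
SEP(C) = √(Σ(e−bias)²/(N−1)), and R² as the squared Pearson correlation
(the WinISI RSQ convention, not 1 − SSE/SST; differences are second
order). **RPD = SD/SEP(C)** and **RER = range/SEP(C)**: a printed-formula
variant with an N−K−1 denominator (K = model factors) is available via
`denominator="n-k-1"`, but the default matches the arithmetic by which
published tables are actually computed. Perfect predictions report RPD and
RER as +inf sentinels.

Classification bands are right-closed so edge values land in the lower
band (0.90 → "good", not "excellent"): R² < 0.26 very-low, 0.26–0.50 low,
0.50–0.65 discriminate-high-low, 0.65–0.82 rough-prediction, 0.82–0.90
good, > 0.90 excellent; RPD < 1.5 unusable, 1.5–2.5 screening, 2.5–3
acceptable, > 3 excellent; RER ≥ 10 good-precision else screening.

## The synthetic world

Defaults state the published concentration moments for rocket-leaf
analytes: GRA (mean 9.11, SD 6.41, range 0.13–27.85 μmol·g⁻¹ dw), GLSAT
(9.66, 3.92, 0.25–18.61), GER (1.45, 1.60, 0.14–8.01), TPC (8.73, 1.99,
2.30–12.30 mg·GAE·g⁻¹ dw) and TGLs (23.56, 4.86–44.65), with pairwise
correlations GRA–GLSAT 0.48, GRA–GER −0.53, GER–TPC 0.33 (non-significant
pairs set to 0).

Concentrations are multivariate Gaussian, clipped to the ranges. Clipping
is a documented bias source: GER's lower bound sits only 0.8 SD below its
mean, so ~20 % of GER draws are clipped and the realised GER–GRA
correlation attenuates from −0.53 to ≈ −0.50 (still within the ±0.05
sampling band asserted in tests). TGLs is generated as
GRA + GLSAT + GER + an independent non-negative "other glucosinolates"
remainder whose SD (≈ 2.86) is solved analytically so corr(TGLs, GRA) =
0.83 in the latent model. A jointly consistent covariance honouring every
published pairwise correlation together with the sum structure does not
exist (the variance of the three-component sum alone exceeds the published
TGLs variance), so corr(TGLs, GLSAT) realises ≈ 0.78 (vs 0.70) and
corr(TGLs, GER) ≈ −0.17 (vs −0.37). The published tables also disagree
internally on the TGLs mean (15.6 in text vs 23.56 in the table) and the
GER mean (1.45 calibration vs 3.20 validation); the calibration-table
values are used throughout.

Spectra are additive Beer–Lambert mixtures: each constituent contributes
concentration × a sum of Gaussian bands. Band centres follow the standard
NIR assignments (glucosinolates: S–H 1696 nm, amide N–H 2054/2084 nm,
methylene C–H 2310/2324 nm; phenolics: 1415–1512 and 1650–2035 nm O–H/
aromatic C–H regions; matrix: water 1432/1920 nm, cellulose 2270 nm,
chlorophyll 670 nm, carotenoid 470 nm). Widths (12–40 nm) and amplitudes
are free parameters fixed once so constituent signals are a few
hundredths of an absorbance unit — realistic for these concentrations.
Artefacts are the minimal model SNV-DT is designed to remove:
observed = exp(0.05·z) · clean + offset (SD 0.02 au) + slope
(SD 2×10⁻⁵ au/nm, pivot 1450 nm) · (λ−1450) + white noise (SD 0.002 au).
All randomness derives from one seed through per-stage spawned streams, so
stages regenerate independently and runs are bit-reproducible.

What a green end-to-end test establishes: the pipeline recovers known
linear structure through realistic scatter artefacts at stated noise. What
it does not establish: performance on real leaves, where reference-assay
error, non-Gaussian band shapes, instrument line-shape, moisture/particle
interactions and biological covariance all reduce accuracy — which is why
the synthetic study's R²VAL (~0.99) far exceeds what real external
validations print (0.59–0.84).

One caveat found while validating the scatter-correction rationale: under
second-derivative treatments the SNV-DT vs raw SECV ordering is not
guaranteed, because the derivative itself removes additive baselines and
SNV's division by the row SD introduces a small ratio nonlinearity. The
ordering is asserted at the no-derivative treatment (0,0,1,1), the regime
scatter correction exists for, where SNV-DT wins decisively for all five
analytes.

## Numerical conventions and degenerate inputs

- All SDs use the n−1 denominator.
- SECV ties between factor counts resolve to the smaller k.
- GH ties in ranking resolve by sample id.
- Constant reference values, constant spectra under SNV, grids that do not
  match a model, derivative windows exceeding the grid, and correlation
  matrices that cannot be repaired to positive semidefinite by eigenvalue
  clipping (entry shift > 0.05) all raise typed errors rather than
  degrading silently.
- Validation fixtures are affine rescalings of a fixed base sequence, so
  prescribed SD, range, bias and SEP(C) hold to floating precision.

## Known limitations

- MPLS follows the published Shenk–Westerhaus description; commercial
  implementations may add iterative calibration-outlier elimination
  between cross-validation passes, which is not implemented and can make
  printed SEC/SECV values from such software slightly optimistic relative
  to this package on the same data.
- No Savitzky–Golay filters, MSC, wavelength-subset selection, PLS2, or
  prediction uncertainty intervals.
- The generator models ground, freeze-dried leaf tissue; intact-tissue
  (fresh leaf) spectra, radiative-transfer and Kubelka–Munk physics are
  out of scope.
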