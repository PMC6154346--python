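# nircal

Chemometric calibration of visible/near-infrared (Vis/NIR) reflectance
spectra for quantifying plant secondary metabolites — glucosinolates
(μmol·g⁻¹ dw) and total phenolics (mg·GAE·g⁻¹ dw) in ground leaf tissue.
It is aimed at NIRS lab analysts and plant-breeding screeners who need
cheap, rapid surrogate assays for expensive wet-chemistry references
(LC-UV desulfo-glucosinolate assays, Folin–Ciocalteu phenolics).

The package implements the classical WinISI-style calibration workflow as
an open, tested pipeline:

- **Pre-treatment** — standard normal variate (SNV), polynomial detrend
  (DT) and Norris **gap–segment derivatives**, written as the four-number
  tuple `(derivative, gap, smooth1, smooth2)`, e.g. `2,5,5,2`.
- **Modified partial least squares (MPLS)** — NIPALS PLS1 in which the
  spectral and reference residuals are standardised after each factor
  (Shenk–Westerhaus); plain `pls1` mode is kept as a verifiable oracle.
- **Population structuring (CENTER)** — PCA on pre-treated spectra,
  standardised Mahalanobis distances GH = D²/k, outliers at GH > 3, and a
  1-in-*n* calibration/validation split over the GH ranking.
- **Validation statistics** — SEC, SECV with cross-validated factor
  selection, SEP and bias-corrected SEP(C), R² as squared Pearson
  correlation, and the quality ratios

  RPD = SD / SEP(C)  RER = (y_max − y_min) / SEP(C)

  with the conventional categorical bands (RPD > 3 excellent,
  1.5–2.5 screening; RER ≥ 10 good precision; R² bands from < 0.26 up to
  > 0.90).
- **Synthetic data** — a generator producing correlated reference
  concentrations and matching leaf-like absorbance spectra (Gaussian
  constituent bands, water/cellulose/pigment matrix, multiplicative
  scatter + baseline artefacts), so the whole pipeline is testable without
  instrument data.

Everything is exposed both as scikit-learn-style estimators
(`SNV`, `Detrend`, `GapSegmentDerivative`, `MPLSRegression`,
`PopulationModel`) and as thin functions over the `SpectraSet` /
`ReferenceTable` containers.

## Worked example

```python
import nircal as nc

cfg = nc.PipelineConfig(synthetic=nc.default_config(seed=1, n_samples=156))
study = nc.run_pipeline(cfg)
print(study.report_table[["analyte", "treatment", "K", "R2CV", "SECV",
                          "R2VAL", "SEP_C", "RPD", "RER", "r2_class"]]
      .round(3).to_string(index=False))
```

prints

```text
analyte        treatment  K  R2CV  SECV  R2VAL  SEP_C    RPD     RER  r2_class
   TGLs   0,0,1,1 snv-dt  4 0.999 0.263  0.999  0.222 35.779 167.174 excellent
    GRA 2,20,20,2 snv-dt  8 0.996 0.365  0.997  0.368 16.617  75.289 excellent
  GLSAT 2,20,20,2 snv-dt 11 0.993 0.321  0.997  0.225 17.871  65.901 excellent
    GER 1,10,10,1 snv-dt 10 0.995 0.090  0.998  0.071 22.306  68.181 excellent
    TPC 1,10,10,1 snv-dt  5 0.998 0.070  0.998  0.069 23.758 102.704 excellent
```

One row per analyte: the winning math treatment and factor count `K`
(minimum SECV over the treatment grid on the calibration set only), the
cross-validation statistics (R²CV, SECV), and the external-validation
statistics on the held-out GH-ranked validation samples (R²VAL, bias-
corrected SEP(C), RPD, RER and the derived quality class). On this clean
synthetic world the equations are near-perfect; real leaf spectra carry
reference-assay error and biological matrix variation that the generator
deliberately does not emulate, so real-world R²VAL values are lower.

The same study runs from a shell:

```sh
nircal run --seed 1 --n 156 --out results/
nircal simulate --n 156 --seed 1 --spectra spectra.csv --reference reference.csv
nircal center --spectra spectra.csv --treatment 2,5,5,2 --scatter snv-dt --out split.csv
nircal calibrate --spectra spectra.csv --reference reference.csv --analyte TPC --out model.json
nircal predict --model model.json --spectra spectra.csv --out pred.csv
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time, the
package's headline quantities: the external-validation ratio identities
(RPD and RER produced by the validation-statistics code on constructed
reference/predicted fixtures with prescribed SD, range and SEP(C)) and
the sample correlation between simulated glucoerucin and glucoraphanin
concentrations under the default generator parameterisation.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/nircal/io.py` — `SpectraSet`/`ReferenceTable`, delimited-text
  readers/writers, duplicate-scan averaging.
- `src/nircal/preprocessing.py` — SNV, detrend, gap–segment derivatives,
  `MathTreatment`.
- `src/nircal/mpls.py` — `MPLSRegression`, model fitting/prediction,
  loading spectra, model serialization.
- `src/nircal/center.py` — PCA/GH population structure and the ranked
  split.
- `src/nircal/validation.py` — cross-validation, external-validation
  statistics, quality classification, Pearson matrices.
- `src/nircal/synthetic.py` — the synthetic-world generator.
- `src/nircal/pipeline.py`, `src/nircal/cli.py` — study orchestration and
  the `nircal` command.

See `docs/methods.md` for the model details, parameter choices and known
limitations.
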