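"""End-to-end study orchestration: simulate or load data, CENTER split,
treatment grid search by cross-validation, external validation, reporting.

"Best-fitting" is defined as minimum SECV over the treatment x factor-count
grid, selected per analyte on the calibration set only; the validation set
never influences model selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .center import population_structure, rank_and_split, SplitPlan
from .errors import ConfigurationError
from .io import (ReferenceTable, SpectraSet, align_by_ids, read_reference,
                 read_spectra, write_reference, write_spectra)
from .mpls import MplsModel, fit_mpls, loading_spectrum, predict, save_model
from .preprocessing import MathTreatment, PAPER_TREATMENTS, apply_treatment
from .synthetic import SyntheticConfig, draw_concentrations, simulate_spectra
from .validation import (ValidationReport, classify, cross_validate,
                         external_validation, report_from_pairs)

log = logging.getLogger("nircal")

__all__ = ["PipelineConfig", "AnalyteResult", "StudyResult", "run_pipeline"]

REPORT_COLUMNS = [
    "analyte", "unit", "treatment", "N_cal", "N_val", "K",
    "cal_range_low", "cal_range_high", "cal_mean", "cal_SD",
    "R2C", "SEC", "R2CV", "SECV", "RPDcv",
    "range_low", "range_high", "mean", "SD",
    "R2VAL", "SEP", "SEP_C", "bias", "RPD", "RER",
    "r2_class", "rpd_class", "rer_class",
]


@dataclass
class PipelineConfig:
    """Everything a study run needs; one seed drives all randomness."""

    synthetic: SyntheticConfig | None = None
    spectra_path: str | None = None
    reference_path: str | None = None
    treatments: tuple[MathTreatment, ...] = PAPER_TREATMENTS
    analytes: tuple[str, ...] | None = None
    center_treatment: MathTreatment = MathTreatment(2, 5, 5, 2, "snv-dt")
    split_every: int = 5
    gh_threshold: float = 3.0
    variance_kept: float = 0.99
    cv_groups: int = 4
    max_factors: int = 16
    mode: str = "mpls"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and (self.spectra_path is None
                                       or self.reference_path is None):
            raise ConfigurationError(
                "either a synthetic config or spectra+reference paths are required"
            )
        if not self.treatments:
            raise ConfigurationError("at least one treatment is required")


@dataclass
class AnalyteResult:
    analyte: tuple[str, str]
    treatment: MathTreatment
    k_best: int
    model: MplsModel
    report: ValidationReport
    loadings: np.ndarray            # factors 1..3 (rows) over the grid
    predictions: pd.DataFrame       # validation reference vs predicted
    secv_grid: dict[str, float]     # SECV of the winning k per treatment


@dataclass
class StudyResult:
    split: SplitPlan
    results: dict[str, AnalyteResult]
    report_table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for res in self.results.values():
            r = res.report
            rows.append({
                "analyte": r.analyte[0], "unit": r.analyte[1],
                "treatment": str(res.treatment), "N_cal": r.extras["N_cal"],
                "N_val": r.N, "K": r.K,
                "cal_range_low": r.extras["cal_range_low"],
                "cal_range_high": r.extras["cal_range_high"],
                "cal_mean": r.extras["cal_mean"], "cal_SD": r.extras["cal_SD"],
                "R2C": r.R2C, "SEC": r.SEC, "R2CV": r.R2CV, "SECV": r.SECV,
                "RPDcv": r.extras["RPDcv"],
                "range_low": r.range_low, "range_high": r.range_high,
                "mean": r.mean, "SD": r.SD,
                "R2VAL": r.R2VAL, "SEP": r.SEP, "SEP_C": r.SEP_C,
                "bias": r.bias, "RPD": r.RPD, "RER": r.RER,
                "r2_class": r.r2_class, "rpd_class": r.rpd_class,
                "rer_class": r.rer_class,
            })
        self.report_table = pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _load_data(config: PipelineConfig) -> tuple[SpectraSet, ReferenceTable]:
    if config.synthetic is not None:
        refs = draw_concentrations(config.synthetic)
        spectra = simulate_spectra(refs, config.synthetic)
        return spectra, refs
    spectra = read_spectra(config.spectra_path)
    refs = read_reference(config.reference_path)
    spectra, refs, unmatched = align_by_ids(spectra, refs)
    if unmatched:
        log.warning("unmatched sample ids dropped from the join: %s", unmatched)
    return spectra, refs


def run_pipeline(config: PipelineConfig) -> StudyResult:
    """Run the full study and (optionally) write its output files."""
    spectra, refs = _load_data(config)
    log.info("data: %d samples, %d channels, %d analytes",
             spectra.n_samples, spectra.grid.n_points, len(refs.analytes))

    pre = apply_treatment(spectra, config.center_treatment)
    pop = population_structure(pre, config.variance_kept, config.gh_threshold)
    split = rank_and_split(pop, config.split_every)
    log.info("center: %d components, %d outliers, %d cal / %d val",
             pop.n_components, len(split.outlier_ids),
             len(split.calibration_ids), len(split.validation_ids))

    X_cal = spectra.subset(split.calibration_ids)
    X_val = spectra.subset(split.validation_ids)
    refs_cal = refs.subset(split.calibration_ids)
    refs_val = refs.subset(split.validation_ids)

    names = list(config.analytes) if config.analytes else refs.names
    results: dict[str, AnalyteResult] = {}
    for name in names:
        y_cal = refs_cal.column(name)
        best = None
        secv_grid: dict[str, float] = {}
        for t in config.treatments:
            cv = cross_validate(X_cal, y_cal, t, groups=config.cv_groups,
                                max_factors=config.max_factors, mode=config.mode)
            secv_grid[str(t)] = cv.SECV
            if best is None or cv.SECV < best[1].SECV:
                best = (t, cv)
        t_best, cv_best = best
        model = fit_mpls(X_cal, y_cal, treatment=t_best,
                         max_factors=config.max_factors, mode=config.mode,
                         analyte=(name, refs.unit(name)))
        k = min(cv_best.k_best, model.n_factors)

        yhat_cal = predict(model, X_cal, k=k)
        resid = yhat_cal - y_cal
        n_cal = len(y_cal)
        sec = float(np.sqrt(np.sum(resid ** 2) / max(n_cal - k - 1, 1)))
        r2c = float(np.corrcoef(y_cal, yhat_cal)[0, 1] ** 2)

        y_val = refs_val.column(name)
        report = external_validation(model, X_val, y_val, k=k)
        report.SEC, report.R2C = sec, r2c
        report.SECV, report.R2CV = cv_best.SECV, cv_best.R2CV
        cal_sd = float(np.std(y_cal, ddof=1))
        report.extras.update({
            "N_cal": n_cal,
            "cal_mean": float(y_cal.mean()),
            "cal_SD": cal_sd,
            "cal_range_low": float(y_cal.min()),
            "cal_range_high": float(y_cal.max()),
            "RPDcv": cal_sd / cv_best.SECV if cv_best.SECV > 0 else float("inf"),
        })
        classify(report)

        loadings = np.vstack([
            loading_spectrum(model, f) for f in range(1, min(3, model.n_factors) + 1)
        ])
        preds = pd.DataFrame({
            "sample_id": split.validation_ids,
            "reference": y_val,
            "predicted": predict(model, X_val, k=k),
        })
        results[name] = AnalyteResult(
            analyte=(name, refs.unit(name)), treatment=t_best, k_best=k,
            model=model, report=report, loadings=loadings,
            predictions=preds, secv_grid=secv_grid,
        )
        log.info("%s: treatment %s, k=%d, SECV=%.4g, R2VAL=%.3f (%s)",
                 name, t_best, k, cv_best.SECV, report.R2VAL, report.r2_class)

    study = StudyResult(split=split, results=results)
    if config.out_dir is not None:
        _write_outputs(study, spectra, config)
    return study


def _write_outputs(study: StudyResult, spectra: SpectraSet,
                   config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.report_table.to_csv(out / "report.csv", index=False,
                              float_format="%.6g")
    with open(out / "report.json", "w") as fh:
        json.dump({n: r.report.to_dict() for n, r in study.results.items()},
                  fh, indent=2, default=str)
    rows = ([(i, "cal") for i in study.split.calibration_ids]
            + [(i, "val") for i in study.split.validation_ids]
            + [(i, "outlier") for i in study.split.outlier_ids])
    pd.DataFrame(rows, columns=["sample_id", "role"]).to_csv(
        out / "split.csv", index=False)
    wl = spectra.grid.wavelengths
    for name, res in study.results.items():
        df = pd.DataFrame(res.loadings.T, columns=[
            f"factor_{i + 1}" for i in range(res.loadings.shape[0])])
        df.insert(0, "wavelength_nm", wl)
        df.to_csv(out / f"loadings_{name}.csv", index=False, float_format="%.6g")
        res.predictions.to_csv(out / f"predictions_{name}.csv", index=False,
                               float_format="%.6g")
        save_model(res.model, out / f"model_{name}.json")
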