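"""End-to-end calibration experiment orchestration.

One config drives the whole workflow: (optional) outlier screening,
Kennard-Stone partitioning, a pretreatment sweep on the full-spectrum
model, the three selection strategies (none / UVE / CARS), PLS fitting
with RMSECV-selected component counts, and evaluation into a comparison
table.

Information-leakage guards are structural: the MSC reference, every
cross-validation loop and both selection algorithms see calibration rows
only; prediction-set concentrations enter at evaluation time and never
before.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .containers import SpectraSet, ValidationError, align_references
from .evaluation import EvaluationReport, compare_models, evaluate_model, render_comparison
from .pls import CVResult, cv_rmsecv, pls_fit
from .preprocessing import PretreatmentSpec
from .sampling import OutlierReport, PartitionResult, kennard_stone, mahalanobis_screen
from .selection import CARSResult, UVEResult, cars_select, uve_select
from .synthetic import SyntheticConfig, generate

DEFAULT_SWEEP = tuple(
    PretreatmentSpec(method=m) for m in
    ("raw", "smooth", "d1_sg", "d2_sg", "msc", "snv")
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one experiment needs; see field comments for defaults."""

    synthetic: SyntheticConfig | None = None
    spectra_path: str | None = None
    references_path: str | None = None
    analytes: tuple[str, ...] | None = None    # None = every reference column
    pretreatments: tuple[PretreatmentSpec, ...] = DEFAULT_SWEEP
    n_calibration: int | None = None           # None = round(0.8 * n)
    screen_outliers: bool = True
    outlier_k_components: int = 5
    outlier_sd_multiplier: float = 3.0
    selection_methods: tuple[str, ...] = ("full", "uve", "cars")
    a_max: int = 18
    cv_folds: int | None = None                 # None = leave-one-out
    cars_runs: int = 100
    cars_mc_fraction: float = 0.8
    cars_cv_folds: int | None = None
    uve_folds: int | None = None
    uve_noise_amplitude: float | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.spectra_path is not None and self.references_path is not None
        if self.synthetic is None and not has_files:
            raise ValidationError(
                "provide either a synthetic config or spectra/references paths")
        if self.synthetic is not None and has_files:
            raise ValidationError("synthetic config and input paths are exclusive")
        unknown = set(self.selection_methods) - {"full", "uve", "cars"}
        if unknown:
            raise ValidationError(f"unknown selection methods: {sorted(unknown)}")
        if "full" not in self.selection_methods:
            raise ValidationError("'full' must be among selection_methods "
                                  "(it is the benchmark model)")


@dataclass
class AnalyteResult:
    analyte: str
    pretreatment: PretreatmentSpec
    outliers: OutlierReport | None
    partition: PartitionResult
    sweep_table: pd.DataFrame
    reports: dict[str, EvaluationReport]
    uve: UVEResult | None = None
    cars: CARSResult | None = None
    cv_curves: dict[str, CVResult] = field(default_factory=dict)


@dataclass
class ExperimentResult:
    comparison: pd.DataFrame
    per_analyte: dict[str, AnalyteResult]
    manifest: dict

    def render(self) -> str:
        return render_comparison(self.comparison)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        ds = generate(config.synthetic)
        return ds.spectra, ds.references, ds
    spectra = nio.read_spectra(config.spectra_path)
    references = nio.read_references(config.references_path)
    return spectra, references, None


def _derive_seeds(seed: int, analytes: list[str]) -> dict[str, dict[str, int]]:
    rng = np.random.default_rng(seed)
    return {
        a: {"uve": int(rng.integers(2 ** 31)),
            "cars": int(rng.integers(2 ** 31))}
        for a in analytes
    }


def _fit_evaluate(analyte: str, model_name: str,
                  cal: SpectraSet, pred: SpectraSet,
                  y_cal: np.ndarray, y_pred: np.ndarray,
                  subset: np.ndarray | None, a_max: int,
                  cv_folds: int | None):
    """Fit PLS on a channel subset with RMSECV-optimal components; evaluate."""
    Xc = cal.absorbance if subset is None else cal.absorbance[:, subset]
    Xp = pred.absorbance if subset is None else pred.absorbance[:, subset]
    cv = cv_rmsecv(Xc, y_cal, min(a_max, Xc.shape[1]), folds=cv_folds)
    a = cv.optimal_components
    model = pls_fit(Xc, y_cal, a, wavelength_subset=subset)
    report = evaluate_model(
        analyte, model_name, n_components=a, n_variables=Xc.shape[1],
        rmsecv=cv.min_rmsecv,
        y_cal=y_cal, yhat_cal=model.predict(Xc),
        y_pred=y_pred, yhat_pred=model.predict(Xp),
    )
    return model, report, cv


def run_pretreatment_sweep(config: PipelineConfig,
                           analyte: str | None = None) -> dict[str, dict]:
    """Fit a full-spectrum model per pretreatment and pick a winner.

    The winner per analyte is the pretreatment with the highest
    prediction-set R_p^2 (ties broken by lower RMSEP).  Returns, per
    analyte, the winning spec and a sweep grid with R_c^2, R_p^2, RMSEC
    and RMSEP per candidate.
    """
    spectra, references, _ = _load_inputs(config)
    analytes = [analyte] if analyte else list(
        config.analytes or references.columns)
    out: dict[str, dict] = {}
    for name in analytes:
        out[name] = _sweep_one(config, spectra, references, name)
    return out


def _sweep_one(config: PipelineConfig, spectra: SpectraSet,
               references: pd.DataFrame, analyte: str) -> dict:
    if not config.pretreatments:
        raise ValidationError("pretreatment sweep list is empty")
    retained, outliers = _screen(config, spectra)
    partition = _partition(config, retained)
    cal_raw = retained.select_samples(partition.calibration_ids)
    pred_raw = retained.select_samples(partition.prediction_ids)
    y_cal = align_references(cal_raw, references, analyte)
    y_pred = align_references(pred_raw, references, analyte)

    rows = []
    best = None
    for spec in config.pretreatments:
        try:
            cal, pred = spec.fit_apply(cal_raw, pred_raw)
            _, report, _ = _fit_evaluate(
                analyte, spec.method, cal, pred, y_cal, y_pred,
                subset=None, a_max=config.a_max, cv_folds=config.cv_folds)
        except ValidationError as exc:
            raise ValidationError(
                f"pretreatment {spec.method!r} failed for analyte "
                f"{analyte!r}: {exc}") from exc
        rows.append({"pretreatment": spec.method, "R_c^2": report.r2_c,
                     "R_p^2": report.r2_p, "RMSEC": report.rmsec,
                     "RMSEP": report.rmsep})
        key = (report.r2_p, -report.rmsep)
        if best is None or key > best[0]:
            best = (key, spec, report)
    table = pd.DataFrame(rows)
    return {"best": best[1], "table": table, "outliers": outliers,
            "partition": partition}


def _screen(config: PipelineConfig, spectra: SpectraSet):
    if not config.screen_outliers:
        return spectra, None
    report = mahalanobis_screen(
        spectra, k_components=config.outlier_k_components,
        sd_multiplier=config.outlier_sd_multiplier)
    if report.flagged_ids:
        spectra = spectra.select_samples(report.retained_ids)
    return spectra, report


def _partition(config: PipelineConfig, spectra: SpectraSet) -> PartitionResult:
    n = spectra.n_samples
    n_cal = config.n_calibration or int(round(0.8 * n))
    n_cal = min(n_cal, n)
    return kennard_stone(spectra, n_cal)


def run_full_experiment(config: PipelineConfig) -> ExperimentResult:
    """Screen -> split -> pretreat -> {full, UVE, CARS} -> evaluate.

    Deterministic under a fixed config seed, including the CARS Monte-Carlo
    draws; rerunning yields a byte-identical rendered comparison table.
    """
    t0 = time.perf_counter()
    spectra, references, _ = _load_inputs(config)
    analytes = list(config.analytes or references.columns)
    for a in analytes:
        if a not in references.columns:
            raise ValidationError(f"analyte {a!r} not in reference table")
    seeds = _derive_seeds(config.seed, analytes)

    reports: list[EvaluationReport] = []
    per_analyte: dict[str, AnalyteResult] = {}
    stages: dict[str, float] = {}
    for analyte in analytes:
        ta = time.perf_counter()
        sweep = _sweep_one(config, spectra, references, analyte)
        best_spec: PretreatmentSpec = sweep["best"]
        partition: PartitionResult = sweep["partition"]
        retained = (spectra if sweep["outliers"] is None
                    else spectra.select_samples(sweep["outliers"].retained_ids))
        cal_raw = retained.select_samples(partition.calibration_ids)
        pred_raw = retained.select_samples(partition.prediction_ids)
        y_cal = align_references(cal_raw, references, analyte)
        y_pred = align_references(pred_raw, references, analyte)
        cal, pred = best_spec.fit_apply(cal_raw, pred_raw)

        result = AnalyteResult(
            analyte=analyte, pretreatment=best_spec,
            outliers=sweep["outliers"], partition=partition,
            sweep_table=sweep["table"], reports={})

        _, full_report, full_cv = _fit_evaluate(
            analyte, "full_pls", cal, pred, y_cal, y_pred,
            subset=None, a_max=config.a_max, cv_folds=config.cv_folds)
        result.reports["full_pls"] = full_report
        result.cv_curves["full_pls"] = full_cv
        reports.append(full_report)

        if "uve" in config.selection_methods:
            uve = uve_select(
                cal.absorbance, y_cal,
                n_components=full_cv.optimal_components,
                noise_amplitude=config.uve_noise_amplitude,
                folds=config.uve_folds, seed=seeds[analyte]["uve"])
            result.uve = uve
            if uve.selected_channels.size >= 2:
                _, rep, cv = _fit_evaluate(
                    analyte, "uve_pls", cal, pred, y_cal, y_pred,
                    subset=uve.selected_channels, a_max=config.a_max,
                    cv_folds=config.cv_folds)
                result.reports["uve_pls"] = rep
                result.cv_curves["uve_pls"] = cv
                reports.append(rep)

        if "cars" in config.selection_methods:
            cars = cars_select(
                cal.absorbance, y_cal, a_max=config.a_max,
                n_runs=config.cars_runs,
                mc_fraction=config.cars_mc_fraction,
                seed=seeds[analyte]["cars"],
                cv_folds=config.cars_cv_folds)
            result.cars = cars
            _, rep, cv = _fit_evaluate(
                analyte, "cars_pls", cal, pred, y_cal, y_pred,
                subset=cars.selected_channels, a_max=config.a_max,
                cv_folds=config.cv_folds)
            result.reports["cars_pls"] = rep
            result.cv_curves["cars_pls"] = cv
            reports.append(rep)

        per_analyte[analyte] = result
        stages[analyte] = time.perf_counter() - ta

    comparison = compare_models(
        reports, require_cars="cars" in config.selection_methods)
    manifest = _build_manifest(config, per_analyte, stages,
                               time.perf_counter() - t0)
    result = ExperimentResult(comparison=comparison,
                              per_analyte=per_analyte, manifest=manifest)
    if config.output_dir:
        _write_artifacts(config, result, spectra, references)
    return result


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    if config.synthetic is not None:
        snap["synthetic"]["components"] = [
            asdict(c) for c in config.synthetic.components]
    snap["pretreatments"] = [asdict(p) for p in config.pretreatments]
    return snap


def _build_manifest(config: PipelineConfig, per_analyte: dict,
                    stages: dict[str, float], elapsed: float) -> dict:
    return {
        "config": _config_snapshot(config),
        "seed": config.seed,
        "analytes": {
            name: {
                "pretreatment": res.pretreatment.method,
                "n_calibration": len(res.partition.calibration_ids),
                "n_prediction": len(res.partition.prediction_ids),
                "n_outliers_removed": (0 if res.outliers is None
                                       else len(res.outliers.flagged_ids)),
                "models": {
                    m: {"n_components": r.n_components,
                        "n_variables": r.n_variables,
                        "rmsep": r.rmsep}
                    for m, r in res.reports.items()
                },
                "wall_clock_s": stages[name],
            }
            for name, res in per_analyte.items()
        },
        "total_wall_clock_s": elapsed,
    }


def _write_artifacts(config: PipelineConfig, result: ExperimentResult,
                     spectra: SpectraSet, references: pd.DataFrame) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    nio.write_spectra(spectra, out / "spectra.csv")
    nio.write_references(references, out / "references.csv")
    result.comparison.to_csv(out / "comparison.csv", index=False)
    (out / "comparison.txt").write_text(result.render() + "\n")
    for name, res in result.per_analyte.items():
        nio.write_partition(res.partition, out / f"partition_{name}.json")
        res.sweep_table.to_csv(out / f"sweep_{name}.csv", index=False)
        if res.cars is not None:
            nio.write_selection(
                res.cars.selected_channels, spectra.wavelengths_nm,
                out / f"selection_cars_{name}.json",
                diagnostics={
                    "rmsecv_history": res.cars.rmsecv_history,
                    "subset_sizes": np.asarray(
                        [s.size for s in res.cars.subset_history]),
                    "best_run": res.cars.best_run,
                })
        if res.uve is not None:
            nio.write_selection(
                res.uve.selected_channels, spectra.wavelengths_nm,
                out / f"selection_uve_{name}.json",
                diagnostics={"stability": res.uve.stability,
                             "threshold": res.uve.threshold})
    # JSON manifest, stripped of non-serializable leftovers via default=str
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str))


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file.

    Keys mirror the dataclass fields; ``synthetic`` nests a
    :class:`~nirquant.synthetic.SyntheticConfig` (with optional
    ``components`` list of component-spec mappings) and ``pretreatments``
    is a list of method names or mappings with parameters.
    """
    from .synthetic import ComponentSpec

    raw = yaml.safe_load(Path(path).read_text())
    kwargs = dict(raw)
    if "synthetic" in kwargs and kwargs["synthetic"] is not None:
        syn = dict(kwargs["synthetic"])
        if "components" in syn:
            syn["components"] = tuple(
                ComponentSpec(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in c.items()})
                for c in syn["components"])
        kwargs["synthetic"] = SyntheticConfig(**syn)
    if "pretreatments" in kwargs:
        specs = []
        for item in kwargs["pretreatments"]:
            if isinstance(item, str):
                specs.append(PretreatmentSpec(method=item))
            else:
                specs.append(PretreatmentSpec(**item))
        kwargs["pretreatments"] = tuple(specs)
    for key in ("analytes", "selection_methods"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return PipelineConfig(**kwargs)
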