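"""Model-quality metrics and the three-way model comparison table.

Metrics follow the NIR calibration reporting conventions: RMSE with an
``n`` (not ``n-1``) divisor; calibration R² centered on the measured mean;
prediction R² centered — as some NIR papers print it — on the *predicted*
mean (the classical measured-mean convention is available); and RPD, the
ratio of the reference-value standard deviation to RMSEP, with the usual
interpretation bands (>2 exceptional, 1.4-2 general, <1.4 poor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError

RPD_BANDS = ((2.0, "exceptional"), (1.4, "general"), (0.0, "poor"))

MODEL_LABELS = {"full_pls": "Full-PLS", "cars_pls": "CARS-PLS",
                "uve_pls": "UVE-PLS"}


def rmse(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Root mean squared error, dividing by the sample count."""
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if predicted.shape != measured.shape or predicted.ndim != 1:
        raise ValidationError("predicted and measured must be equal-length vectors")
    if predicted.size == 0:
        raise ValidationError("rmse of empty input is undefined")
    return float(np.sqrt(np.mean((predicted - measured) ** 2)))


def r_squared(predicted: np.ndarray, measured: np.ndarray,
              convention: str = "eq8_cal") -> float:
    """Coefficient of determination, ``1 - SSE/SST``.

    ``convention="eq8_cal"`` centers SST on the measured mean (the
    classical definition, used for calibration sets); ``"eq9_pred"``
    centers SST on the *predicted* mean, matching the prediction-set
    convention of some NIR reports.  The two agree exactly when the
    predicted and measured means coincide.
    """
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if predicted.shape != measured.shape or predicted.ndim != 1:
        raise ValidationError("predicted and measured must be equal-length vectors")
    sse = float(np.sum((measured - predicted) ** 2))
    if convention == "eq8_cal":
        sst = float(np.sum((measured - measured.mean()) ** 2))
    elif convention == "eq9_pred":
        sst = float(np.sum((measured - predicted.mean()) ** 2))
    else:
        raise ValidationError(f"unknown convention {convention!r}")
    if sst <= 0:
        raise ValidationError("zero total sum of squares; R^2 undefined")
    return 1.0 - sse / sst


def rpd(measured: np.ndarray, rmsep: float) -> tuple[float, str]:
    """Residual predictive deviation: sd(measured, ddof=1) / RMSEP.

    Returns the value and its interpretation band.
    """
    measured = np.asarray(measured, float)
    if measured.size < 2:
        raise ValidationError("RPD needs >= 2 prediction samples")
    if rmsep <= 0:
        raise ValidationError("RPD undefined for rmsep <= 0")
    value = float(measured.std(ddof=1) / rmsep)
    for cutoff, label in RPD_BANDS:
        if value >= cutoff:
            return value, label
    return value, "poor"


@dataclass(frozen=True)
class EvaluationReport:
    """All headline metrics of one model on one analyte."""

    analyte: str
    model: str
    n_components: int
    n_variables: int
    r2_c: float
    rmsecv: float
    rmsec: float
    r2_p: float
    rmsep: float
    rpd: float
    rpd_band: str
    n_calibration: int
    n_prediction: int


def evaluate_model(analyte: str, model_name: str, n_components: int,
                   n_variables: int, rmsecv: float,
                   y_cal: np.ndarray, yhat_cal: np.ndarray,
                   y_pred: np.ndarray, yhat_pred: np.ndarray,
                   prediction_r2_convention: str = "eq9_pred",
                   ) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from predictions."""
    rmsec = rmse(yhat_cal, y_cal)
    rmsep = rmse(yhat_pred, y_pred)
    rpd_value, band = rpd(y_pred, rmsep)
    return EvaluationReport(
        analyte=analyte, model=model_name,
        n_components=n_components, n_variables=n_variables,
        r2_c=r_squared(yhat_cal, y_cal, "eq8_cal"),
        rmsecv=rmsecv, rmsec=rmsec,
        r2_p=r_squared(yhat_pred, y_pred, prediction_r2_convention),
        rmsep=rmsep, rpd=rpd_value, rpd_band=band,
        n_calibration=len(y_cal), n_prediction=len(y_pred),
    )


def percent_rmsep_reduction(rmsep_full: float, rmsep_selected: float) -> float:
    """``100 * (RMSEP_full - RMSEP_selected) / RMSEP_full``."""
    if rmsep_full <= 0:
        raise ValidationError("rmsep_full must be > 0")
    return 100.0 * (rmsep_full - rmsep_selected) / rmsep_full


def _sig4(x: float) -> str:
    """Format to 4 significant figures, plain decimal notation."""
    if x == 0:
        return "0.000"
    return np.format_float_positional(
        x, precision=4, unique=False, fractional=False, trim="k")


def compare_models(reports: list[EvaluationReport],
                   require_cars: bool = True) -> pd.DataFrame:
    """Three-way comparison table, one row per (analyte, model).

    Column order follows the standard reporting layout (PCs, Variables,
    R_c^2, RMSECV, RMSEC, R_p^2, RMSEP, RPD) plus the percent RMSEP
    reduction of CARS-PLS relative to full-spectrum PLS.  Requires the
    full_pls row for every analyte present, and the cars_pls row too
    unless ``require_cars=False`` (selection stages disabled).
    """
    by_key = {(r.analyte, r.model): r for r in reports}
    analytes = list(dict.fromkeys(r.analyte for r in reports))
    required_models = ("full_pls", "cars_pls") if require_cars else ("full_pls",)
    for analyte in analytes:
        for required in required_models:
            if (analyte, required) not in by_key:
                raise ValidationError(
                    f"missing model row {required!r} for analyte {analyte!r}")
    rows = []
    for analyte in analytes:
        full = by_key[(analyte, "full_pls")]
        for model in ("full_pls", "cars_pls", "uve_pls"):
            r = by_key.get((analyte, model))
            if r is None:
                continue
            reduction = (percent_rmsep_reduction(full.rmsep, r.rmsep)
                         if model == "cars_pls" else np.nan)
            rows.append({
                "Parameter": analyte,
                "Model": MODEL_LABELS.get(model, model),
                "PCs": r.n_components,
                "Variables": r.n_variables,
                "R_c^2": r.r2_c,
                "RMSECV": r.rmsecv,
                "RMSEC": r.rmsec,
                "R_p^2": r.r2_p,
                "RMSEP": r.rmsep,
                "RPD": r.rpd,
                "RMSEP reduction vs Full-PLS (%)": reduction,
            })
    return pd.DataFrame(rows)


def render_comparison(table: pd.DataFrame) -> str:
    """Fixed-format text rendering (4 significant figures) of the table."""
    out = table.copy()
    for col in ("R_c^2", "RMSECV", "RMSEC", "R_p^2", "RMSEP", "RPD"):
        out[col] = out[col].map(_sig4)
    out["RMSEP reduction vs Full-PLS (%)"] = table[
        "RMSEP reduction vs Full-PLS (%)"].map(
        lambda v: "" if pd.isna(v) else f"{v:.2f}")
    return out.to_string(index=False)
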