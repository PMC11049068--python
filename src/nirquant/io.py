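"""Plain-text readers/writers for every pipeline artifact.

Formats:

* **Spectra** — CSV; header row = ``sample_id`` then the wavelengths (nm),
  one row per sample, first column the sample ID.
* **References** — CSV; ``sample_id`` column plus one column per analyte
  (g kg^-1).
* **Partition / selection / model / answer key / manifest** — JSON (or YAML
  for configs), documented by the writer functions below.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import SpectraSet
from .pls import PLSModel
from .sampling import PartitionResult
from .synthetic import SyntheticDataset


def write_spectra(s: SpectraSet, path: str | Path) -> None:
    df = s.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.10g")


def read_spectra(path: str | Path) -> SpectraSet:
    df = pd.read_csv(path, index_col=0)
    wavelengths = np.asarray([float(c) for c in df.columns])
    return SpectraSet(absorbance=df.to_numpy(dtype=float),
                      wavelengths_nm=wavelengths,
                      sample_ids=tuple(str(i) for i in df.index))


def write_references(references: pd.DataFrame, path: str | Path) -> None:
    out = references.copy()
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.10g")


def read_references(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    return df


def write_partition(partition: PartitionResult, path: str | Path) -> None:
    payload = {
        "calibration_ids": list(partition.calibration_ids),
        "prediction_ids": list(partition.prediction_ids),
        "order_selected": list(partition.order_selected),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_partition(path: str | Path) -> PartitionResult:
    payload = json.loads(Path(path).read_text())
    return PartitionResult(
        calibration_ids=tuple(payload["calibration_ids"]),
        prediction_ids=tuple(payload["prediction_ids"]),
        order_selected=tuple(payload["order_selected"]),
    )


def write_model(model: PLSModel, path: str | Path) -> None:
    payload = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "coefficients": model.coefficients.tolist(),
        "n_components": model.n_components,
        "wavelength_subset": (None if model.wavelength_subset is None
                              else model.wavelength_subset.tolist()),
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path: str | Path) -> PLSModel:
    payload = json.loads(Path(path).read_text())
    subset = payload["wavelength_subset"]
    return PLSModel(
        x_mean=np.asarray(payload["x_mean"], float),
        y_mean=float(payload["y_mean"]),
        coefficients=np.asarray(payload["coefficients"], float),
        n_components=int(payload["n_components"]),
        wavelength_subset=None if subset is None else np.asarray(subset, int),
    )


def write_selection(selected_channels: np.ndarray, wavelengths_nm: np.ndarray,
                    path: str | Path, diagnostics: dict | None = None) -> None:
    """Selection file: channel indices, their wavelengths, and optional
    diagnostics arrays (RMSECV trace, stability curve, ...)."""
    payload = {
        "selected_channels": [int(c) for c in selected_channels],
        "selected_wavelengths_nm": [float(wavelengths_nm[c])
                                    for c in selected_channels],
    }
    if diagnostics:
        payload["diagnostics"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in diagnostics.items()
        }
    Path(path).write_text(json.dumps(payload))


def read_selection(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["selected_channels"] = np.asarray(
        payload["selected_channels"], dtype=int)
    return payload


def write_answer_key(dataset: SyntheticDataset, path: str | Path) -> None:
    """Ground truth of a synthetic dataset as YAML.

    Schema: ``components`` maps each analyte to its informative channel
    indices; ``scatter`` holds per-sample slope/offset; ``config`` echoes
    the generator settings.
    """
    cfg = dataset.config
    payload = {
        "config": {
            "n_samples": cfg.n_samples,
            "wavelength_start_nm": cfg.wavelength_start_nm,
            "wavelength_end_nm": cfg.wavelength_end_nm,
            "n_channels": cfg.n_channels,
            "baseline_amplitude": cfg.baseline_amplitude,
            "scatter_slope_sd": cfg.scatter_slope_sd,
            "scatter_offset_sd": cfg.scatter_offset_sd,
            "noise_sd": cfg.noise_sd,
            "seed": cfg.seed,
        },
        "components": {
            name: {"informative_channels": idx.tolist()}
            for name, idx in dataset.informative_channels.items()
        },
        "scatter": {
            "slopes": dataset.scatter_slopes.tolist(),
            "offsets": dataset.scatter_offsets.tolist(),
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_answer_key(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
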