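"""Core data containers for NIR calibration workflows.

A :class:`SpectraSet` is the object every pipeline stage consumes and
produces: an ``n x p`` absorbance matrix with a strictly increasing
wavelength axis (nm) and per-sample identifiers.  Reference analyte
concentrations travel alongside as a plain :class:`pandas.DataFrame`
indexed by sample ID (one column per analyte, g kg^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a container or configuration violates its invariants."""


@dataclass(frozen=True)
class SpectraSet:
    """An absorbance matrix with its wavelength axis and sample labels.

    Parameters
    ----------
    absorbance
        ``(n, p)`` float array, absorbance units. No missing values.
    wavelengths_nm
        Length-``p`` strictly increasing axis in nanometres.
    sample_ids
        Length-``n`` sequence of unique string labels.
    """

    absorbance: np.ndarray
    wavelengths_nm: np.ndarray
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if a.ndim != 2:
            raise ValidationError("absorbance must be a 2-D matrix")
        n, p = a.shape
        if n < 1 or p < 2:
            raise ValidationError("need at least 1 sample and 2 channels")
        if not np.all(np.isfinite(a)):
            raise ValidationError("absorbance contains missing/non-finite values")
        if w.shape != (p,):
            raise ValidationError(
                f"wavelength axis length {w.shape} does not match {p} channels"
            )
        if not np.all(np.diff(w) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        ids = tuple(str(s) for s in self.sample_ids) if len(self.sample_ids) else tuple(
            f"S{i:04d}" for i in range(n)
        )
        if len(ids) != n:
            raise ValidationError(f"{len(ids)} sample ids for {n} rows")
        if len(set(ids)) != n:
            raise ValidationError("sample ids must be unique")
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, absorbance: np.ndarray,
                        wavelengths_nm: np.ndarray | None = None) -> "SpectraSet":
        """Return a copy with a new matrix (and optionally a new axis)."""
        w = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return replace(self, absorbance=absorbance, wavelengths_nm=w)

    def select_samples(self, ids: Sequence[str]) -> "SpectraSet":
        """Subset rows by sample ID, preserving the requested order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in ids]
        return replace(
            self,
            absorbance=self.absorbance[rows],
            sample_ids=tuple(str(s) for s in ids),
        )

    def select_channels(self, channels: Sequence[int]) -> "SpectraSet":
        """Subset columns by channel index (kept in ascending order)."""
        idx = np.asarray(sorted(set(int(c) for c in channels)), dtype=int)
        if idx.size < 2:
            raise ValidationError("need at least 2 channels")
        if idx.min() < 0 or idx.max() >= self.n_channels:
            raise ValidationError("channel index out of range")
        return replace(
            self,
            absorbance=self.absorbance[:, idx],
            wavelengths_nm=self.wavelengths_nm[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Spectra as a DataFrame: rows = sample IDs, columns = wavelengths."""
        return pd.DataFrame(
            self.absorbance, index=list(self.sample_ids),
            columns=self.wavelengths_nm,
        )


def make_reference_table(ids: Sequence[str], **analytes: np.ndarray) -> pd.DataFrame:
    """Build a reference-concentration table (g kg^-1) indexed by sample ID."""
    df = pd.DataFrame(dict(analytes), index=[str(s) for s in ids])
    df.index.name = "sample_id"
    return df


def align_references(spectra: SpectraSet, references: pd.DataFrame,
                     analyte: str) -> np.ndarray:
    """Concentration vector for ``analyte`` aligned to the spectra's row order."""
    if analyte not in references.columns:
        raise KeyError(f"analyte {analyte!r} not in reference table "
                       f"(have {list(references.columns)})")
    try:
        y = references.loc[list(spectra.sample_ids), analyte].to_numpy(dtype=float)
    except KeyError as exc:
        raise KeyError(f"reference table is missing spectra sample ids: {exc}") from exc
    if not np.all(np.isfinite(y)):
        raise ValidationError(f"missing reference values for analyte {analyte!r}")
    return y
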