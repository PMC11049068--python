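"""Spectral pretreatments: smoothing, gap derivatives, MSC and SNV.

All operators act row-wise on a :class:`~nirquant.containers.SpectraSet`
and are composable.  Conventions:

* **Smoothing** is a weighted moving average of half-width ``w`` (uniform
  weights by default).  At the edges the window shrinks symmetrically, so
  no data are fabricated and the output keeps the input shape.
* **Gap derivatives** use the gap-difference form: first derivative
  ``(x[k+g] - x[k-g]) / g`` and second derivative
  ``(x[k+g] - 2 x[k] + x[k-g]) / g**2``.  Note the first-derivative
  divisor is ``g``; the conventional central-difference divisor ``2g``
  is available with ``conventional=True``.  Edge channels where the gap
  overruns are trimmed, together with the wavelength axis.
* **MSC** regresses each spectrum on a reference (calibration-mean)
  spectrum, ``x ~= m_i * x_ref + b_i``, then inverts the fitted affine map.
  The reference is always fit on the calibration partition and frozen.
* **SNV** centres each spectrum and scales by its own standard deviation
  (``m - 1`` denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SpectraSet, ValidationError

METHODS = ("raw", "smooth", "d1_sg", "d2_sg", "msc", "snv")


def sg_smooth(s: SpectraSet, w: int = 7,
              weights: np.ndarray | None = None) -> SpectraSet:
    """Moving-average smoothing with half-width ``w``.

    ``weights`` is the length ``2w+1`` smoothing kernel ``h_i`` (uniform if
    omitted); the normalizer is ``H = sum(h_i)``.  Edge channels are
    smoothed with a symmetrically shrunk window.
    """
    if w < 1:
        raise ValidationError("window half-width w must be >= 1")
    p = s.n_channels
    if p < 2 * w + 1:
        raise ValidationError(
            f"window 2*{w}+1 wider than spectrum ({p} channels)")
    if weights is None:
        h = np.ones(2 * w + 1)
    else:
        h = np.asarray(weights, dtype=float)
        if h.shape != (2 * w + 1,):
            raise ValidationError(f"weights must have length {2 * w + 1}")
        if h.sum() <= 0:
            raise ValidationError("normalizer H = sum(weights) must be > 0")

    x = s.absorbance
    out = np.empty_like(x)
    for k in range(p):
        # shrink the window symmetrically near the edges
        r = min(w, k, p - 1 - k)
        kern = h[w - r:w + r + 1]
        out[:, k] = x[:, k - r:k + r + 1] @ kern / kern.sum()
    return s.with_absorbance(out)


def gap_derivative(s: SpectraSet, order: int, g: int = 5,
                   conventional: bool = False) -> SpectraSet:
    """Gap-difference derivative of ``order`` 1 or 2 with gap ``g`` channels.

    Output drops the ``g`` leading and trailing channels (and their
    wavelengths) where the difference is undefined.
    """
    if order not in (1, 2):
        raise ValidationError("order must be 1 or 2")
    if g < 1:
        raise ValidationError("gap g must be >= 1")
    p = s.n_channels
    if p < 2 * g + 1:
        raise ValidationError(f"gap {g} too large for {p} channels")
    x = s.absorbance
    if order == 1:
        divisor = 2.0 * g if conventional else float(g)
        out = (x[:, 2 * g:] - x[:, :-2 * g]) / divisor
    else:
        out = (x[:, 2 * g:] - 2.0 * x[:, g:-g] + x[:, :-2 * g]) / float(g) ** 2
    return s.with_absorbance(out, wavelengths_nm=s.wavelengths_nm[g:-g])


def msc_fit(calibration: SpectraSet) -> np.ndarray:
    """Mean calibration spectrum, the frozen MSC reference."""
    if calibration.n_samples < 2:
        raise ValidationError("MSC reference needs >= 2 calibration spectra")
    return calibration.absorbance.mean(axis=0)


def msc_transform(s: SpectraSet, reference_mean: np.ndarray) -> SpectraSet:
    """Multiplicative scatter correction against a stored reference.

    Per row, OLS of the spectrum on the reference with intercept yields
    ``(m_i, b_i)``; the corrected row is ``(x - b_i) / m_i``.
    """
    ref = np.asarray(reference_mean, dtype=float)
    if ref.shape != (s.n_channels,):
        raise ValidationError(
            f"reference length {ref.shape} does not match {s.n_channels} channels")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise ValidationError("MSC reference spectrum is constant")
    x = s.absorbance
    slopes = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(slopes == 0)
    if bad.size:
        raise ValidationError(
            f"MSC slope m_i = 0 for sample(s) {[s.sample_ids[i] for i in bad[:5]]}")
    offsets = x.mean(axis=1) - slopes * ref.mean()
    out = (x - offsets[:, None]) / slopes[:, None]
    return s.with_absorbance(out)


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-row centre and unit-sd scale (ddof=1)."""
    x = s.absorbance
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        raise ValidationError(
            f"SNV undefined for constant spectrum(s) "
            f"{[s.sample_ids[i] for i in bad[:5]]}")
    return s.with_absorbance((x - mean) / sd)


@dataclass(frozen=True)
class PretreatmentSpec:
    """A named pretreatment with its parameters; apply with :meth:`fit_apply`.

    ``d1_sg`` / ``d2_sg`` denote moving-average smoothing followed by the
    first / second gap derivative.  MSC stores the calibration-mean
    reference at fit time so prediction-set spectra are corrected against
    the calibration reference, never their own mean.
    """

    method: str = "raw"
    window_halfwidth: int = 7
    gap: int = 5
    weights: tuple[float, ...] | None = None
    conventional_first_derivative: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.window_halfwidth < 1:
            raise ValidationError("window_halfwidth must be >= 1")
        if self.gap < 1:
            raise ValidationError("gap must be >= 1")

    def fit(self, calibration: SpectraSet) -> "FittedPretreatment":
        reference = msc_fit(calibration) if self.method == "msc" else None
        return FittedPretreatment(spec=self, reference_mean=reference)

    def fit_apply(self, calibration: SpectraSet,
                  *others: SpectraSet) -> tuple[SpectraSet, ...]:
        """Fit on the calibration set and transform it plus any other sets."""
        fitted = self.fit(calibration)
        return tuple(fitted.apply(s) for s in (calibration, *others))


@dataclass(frozen=True)
class FittedPretreatment:
    spec: PretreatmentSpec
    reference_mean: np.ndarray | None = None

    def apply(self, s: SpectraSet) -> SpectraSet:
        m = self.spec.method
        if m == "raw":
            return s
        if m == "smooth":
            kern = None if self.spec.weights is None else np.asarray(self.spec.weights)
            return sg_smooth(s, self.spec.window_halfwidth, kern)
        if m in ("d1_sg", "d2_sg"):
            kern = None if self.spec.weights is None else np.asarray(self.spec.weights)
            smoothed = sg_smooth(s, self.spec.window_halfwidth, kern)
            order = 1 if m == "d1_sg" else 2
            return gap_derivative(
                smoothed, order, self.spec.gap,
                conventional=self.spec.conventional_first_derivative)
        if m == "msc":
            if self.reference_mean is None:
                raise ValidationError("MSC pretreatment was not fitted")
            return msc_transform(s, self.reference_mean)
        if m == "snv":
            return snv(s)
        raise ValidationError(f"unknown method {m!r}")
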