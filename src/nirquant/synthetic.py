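"""Seeded synthetic NIR dataset generator with a known answer key.

Emulates diffuse-reflectance NIR absorbance spectra of powdered plant
material: Beer-Lambert-style linear mixing of Gaussian-band pure-component
spectra over a 1000-2500 nm axis, plus the three nuisance terms calibration
pipelines are built to defeat —

* a smooth low-order polynomial baseline drift,
* per-sample affine scatter (multiplicative slope ``m_i`` and additive
  offset ``b_i``, the particle-size effect that SNV/MSC remove), and
* additive white instrument noise.

The generator records ground truth (pure spectra, scatter parameters, the
informative channel set of every component) so wavelength-selection recall
and model accuracy are directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SpectraSet, ValidationError, make_reference_table

#: fraction of a pure-component band maximum above which a channel counts
#: as informative in the answer key
INFORMATIVE_FRACTION = 0.01


@dataclass(frozen=True)
class ComponentSpec:
    """One analyte: its absorption bands and concentration range.

    ``band_heights`` are absorbance per (g kg^-1), so a component's
    contribution to a spectrum is ``concentration * sum_of_bands``.
    """

    name: str
    band_centers_nm: tuple[float, ...]
    band_widths_nm: tuple[float, ...]
    band_heights: tuple[float, ...]
    concentration_min: float
    concentration_max: float

    def __post_init__(self) -> None:
        if not (len(self.band_centers_nm) == len(self.band_widths_nm)
                == len(self.band_heights) > 0):
            raise ValidationError(
                f"component {self.name!r}: band lists must be equal, non-zero length")
        if any(w <= 0 for w in self.band_widths_nm):
            raise ValidationError(f"component {self.name!r}: band_widths_nm must be > 0")
        if not (self.concentration_max > self.concentration_min >= 0):
            raise ValidationError(
                f"component {self.name!r}: need concentration_max > concentration_min >= 0")

    def pure_spectrum(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Sum of Gaussian bands evaluated on the wavelength axis."""
        w = np.asarray(wavelengths_nm, dtype=float)
        out = np.zeros_like(w)
        for c, s, h in zip(self.band_centers_nm, self.band_widths_nm,
                           self.band_heights):
            out += h * np.exp(-0.5 * ((w - c) / s) ** 2)
        return out


def default_components() -> tuple[ComponentSpec, ...]:
    """Three analytes plus a bulk matrix, patterned on a dried medicinal-plant powder.

    Analyte concentration ranges follow reported reference ranges (g kg^-1)
    for total saponins, mannitol and naringenin in such material; band
    centres sit near the strong -OH/-NH/-CH absorption features of the
    1000-2500 nm region.  The fourth component is the bulk matrix
    (polysaccharides, water): nearly constant at ~900 g kg^-1 with broad
    bands, it dominates every spectrum (~1 AU) the way cellulose and water
    dominate real powder spectra.  Band heights scale with mass fraction, so
    analytes perturb the spectrum by ~0.01 AU — the regime in which
    multiplicative scatter (acting on the large common matrix signal) is the
    leading nuisance and scatter correction genuinely matters.
    """
    return (
        ComponentSpec(
            name="total_saponins",
            band_centers_nm=(1495.0, 2310.0),
            band_widths_nm=(18.0, 25.0),
            band_heights=(0.0020, 0.0015),
            concentration_min=0.79, concentration_max=5.79,
        ),
        ComponentSpec(
            name="mannitol",
            band_centers_nm=(1940.0, 1580.0),
            band_widths_nm=(22.0, 15.0),
            band_heights=(0.0022, 0.0011),
            concentration_min=1.57, concentration_max=5.91,
        ),
        ComponentSpec(
            name="naringenin",
            band_centers_nm=(2150.0, 1680.0),
            band_widths_nm=(16.0, 12.0),
            band_heights=(0.30, 0.17),
            concentration_min=0.0038, concentration_max=0.0369,
        ),
        ComponentSpec(
            name="matrix",
            band_centers_nm=(1450.0, 1940.0, 2100.0, 2350.0),
            band_widths_nm=(80.0, 60.0, 90.0, 70.0),
            band_heights=(0.0009, 0.0014, 0.0010, 0.0008),
            concentration_min=880.0, concentration_max=920.0,
        ),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic acquisition campaign.

    Defaults mirror a 120-sample study on a 1000-2500 nm axis with 1557
    channels; scatter and noise magnitudes are typical of FT-NIR powder
    measurements (slope sd ~10%, offset sd 0.02 AU, white noise 1 mAU).
    """

    n_samples: int = 120
    wavelength_start_nm: float = 1000.0
    wavelength_end_nm: float = 2500.0
    n_channels: int = 1557
    components: tuple[ComponentSpec, ...] = field(default_factory=default_components)
    baseline_amplitude: float = 0.10
    scatter_slope_sd: float = 0.10
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.n_channels < 2:
            raise ValidationError("n_channels must be >= 2")
        if not self.wavelength_end_nm > self.wavelength_start_nm:
            raise ValidationError("wavelength_end_nm must exceed wavelength_start_nm")
        for name in ("baseline_amplitude", "scatter_slope_sd",
                     "scatter_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.components:
            raise ValidationError("components must be non-empty")
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated spectra plus the ground truth behind them."""

    spectra: SpectraSet
    references: pd.DataFrame
    pure_spectra: np.ndarray          # (n_components, p)
    scatter_slopes: np.ndarray        # (n,) multiplicative m_i
    scatter_offsets: np.ndarray       # (n,) additive b_i
    baselines: np.ndarray             # (n, p) per-sample drift
    informative_channels: dict[str, np.ndarray]  # component -> channel index set
    config: SyntheticConfig


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one fully reproducible synthetic dataset.

    The forward model per sample ``i`` is::

        spectrum_i = m_i * (sum_c conc_{i,c} * pure_c + baseline_i) + b_i + eps_i

    with ``m_i = exp(N(0, scatter_slope_sd))`` (positive, lognormal),
    ``b_i ~ N(0, scatter_offset_sd)``, ``baseline_i`` a random quadratic in
    wavelength scaled to ``baseline_amplitude`` and ``eps_i`` white Gaussian
    noise.  Concentrations are uniform and independent across components.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_channels
    n = config.n_samples
    wavelengths = np.linspace(config.wavelength_start_nm,
                              config.wavelength_end_nm, p)

    pure = np.vstack([c.pure_spectrum(wavelengths) for c in config.components])

    conc = np.column_stack([
        rng.uniform(c.concentration_min, c.concentration_max, size=n)
        for c in config.components
    ])

    # quadratic drift on a [-1, 1] normalized axis, rescaled to amplitude
    u = np.linspace(-1.0, 1.0, p)
    coeffs = rng.normal(0.0, 1.0, size=(n, 3))
    baselines = (coeffs[:, [0]] + coeffs[:, [1]] * u + coeffs[:, [2]] * u ** 2)
    baselines *= config.baseline_amplitude / 3.0  # three unit-sd terms

    slopes = np.exp(rng.normal(0.0, config.scatter_slope_sd, size=n)) \
        if config.scatter_slope_sd > 0 else np.ones(n)
    offsets = rng.normal(0.0, config.scatter_offset_sd, size=n) \
        if config.scatter_offset_sd > 0 else np.zeros(n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, p)) \
        if config.noise_sd > 0 else np.zeros((n, p))

    clean = conc @ pure
    if config.baseline_amplitude > 0:
        clean = clean + baselines
    absorbance = slopes[:, None] * clean + offsets[:, None] + noise

    ids = [f"S{i:04d}" for i in range(n)]
    spectra = SpectraSet(absorbance=absorbance, wavelengths_nm=wavelengths,
                         sample_ids=tuple(ids))
    references = make_reference_table(
        ids, **{c.name: conc[:, j] for j, c in enumerate(config.components)})

    informative = {
        c.name: np.flatnonzero(pure[j] > INFORMATIVE_FRACTION * pure[j].max())
        for j, c in enumerate(config.components)
    }

    return SyntheticDataset(
        spectra=spectra, references=references, pure_spectra=pure,
        scatter_slopes=slopes, scatter_offsets=offsets, baselines=baselines,
        informative_channels=informative, config=config,
    )
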