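"""Wavelength (variable) selection: UVE and CARS.

Both methods rank spectral channels by the PLS regression coefficients they
earn and keep only channels that carry concentration information.

**UVE (uninformative variable elimination)** appends random-noise channels
to the spectra, refits the PLS model across cross-validation folds, and
scores every channel by the stability ratio ``h_i = mean(beta_i) /
std(beta_i)`` over folds.  Real channels whose |h| does not beat the
noisiest noise channel are eliminated.

**CARS (competitive adaptive reweighted sampling)** runs ``N`` Monte-Carlo
iterations.  Each run fits PLS on a random sample subset, converts |beta|
to weights, enforces an exponentially decreasing retention budget (EDF),
then resamples channels with replacement in proportion to their weights
(adaptive reweighted sampling).  The surviving subset is scored by
cross-validated RMSECV on the whole calibration set; the subset with the
lowest RMSECV wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ValidationError
from .pls import coefficient_paths, cv_rmsecv, _fold_indices


@dataclass(frozen=True)
class UVEResult:
    stability: np.ndarray            # length 2p: real channels then noise
    threshold: float
    selected_channels: np.ndarray    # indices into 0..p-1
    n_real_channels: int


@dataclass(frozen=True)
class EDFSchedule:
    """Exponentially decreasing retention ratios ``r_i = a * exp(-k*i)``.

    Boundary conditions pin the curve: the run-1 budget is the full channel
    count ``p`` and the run-N budget is 2 channels, giving
    ``a = (p/2)**(1/(N-1))`` and ``k = ln(p/2)/(N-1)``.
    """

    a: float
    k: float
    ratios: np.ndarray

    def budget(self, i: int, p: int) -> int:
        """Channel budget at run ``i`` (1-based)."""
        return int(np.ceil(self.ratios[i - 1] * p))


@dataclass(frozen=True)
class CARSResult:
    n_runs: int
    subset_history: tuple[np.ndarray, ...]
    rmsecv_history: np.ndarray
    weight_history: tuple[np.ndarray, ...]
    components_history: np.ndarray
    best_run: int                    # 0-based index into histories
    selected_channels: np.ndarray


def uve_select(X: np.ndarray, y: np.ndarray, n_components: int,
               noise_amplitude: float | None = None,
               folds: int | None = None, seed: int = 0,
               noise_quantile: float | None = None) -> UVEResult:
    """Uninformative variable elimination with random-noise augmentation.

    Appends ``p`` seeded uniform-noise channels (default amplitude
    ``1e-10 * max|X|`` — small enough not to perturb the fit, nonzero so
    noise-channel coefficients are defined), collects the PLS coefficient
    vector over cross-validation folds (leave-one-out when ``folds`` is
    None), and keeps real channels whose stability ``|h|`` exceeds the
    noise-block threshold (its max, or the ``noise_quantile`` quantile of
    ``|h|`` if given).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if noise_amplitude is None:
        noise_amplitude = 1e-10 * float(np.abs(X).max())
    if noise_amplitude <= 0:
        raise ValidationError("noise_amplitude must be > 0")
    rng = np.random.default_rng(seed)
    noise = rng.uniform(0.0, noise_amplitude, size=(n, p))
    Xa = np.column_stack([X, noise])

    fold_sets = _fold_indices(n, folds)
    betas = np.empty((len(fold_sets), 2 * p))
    for f, val in enumerate(fold_sets):
        train = np.setdiff1d(np.arange(n), val)
        a = min(n_components, len(train) - 1, 2 * p)
        betas[f] = coefficient_paths(Xa[train], y[train], a)[a - 1]

    mean = betas.mean(axis=0)
    std = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = mean / std
    degenerate = std == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} channel(s) had zero coefficient spread "
            "across folds; their stability is set to +/-inf")
        h[degenerate] = np.sign(mean[degenerate]) * np.inf
        h[degenerate & (mean == 0)] = np.inf

    noise_abs = np.abs(h[p:])
    if noise_quantile is None:
        threshold = float(noise_abs.max())
    else:
        threshold = float(np.quantile(noise_abs, noise_quantile))
    selected = np.flatnonzero(np.abs(h[:p]) > threshold)
    return UVEResult(stability=h, threshold=threshold,
                     selected_channels=selected, n_real_channels=p)


def edf_schedule(p: int, n_runs: int) -> EDFSchedule:
    """Exponential decay schedule from a full-spectrum budget down to 2."""
    if p < 2:
        raise ValidationError("p must be >= 2")
    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    return EDFSchedule(a=a, k=k, ratios=a * np.exp(-k * i))


def cars_select(X: np.ndarray, y: np.ndarray, a_max: int,
                n_runs: int = 100, mc_fraction: float = 0.8,
                seed: int = 0, cv_folds: int | None = None) -> CARSResult:
    """Competitive adaptive reweighted sampling.

    Per run ``i``: (1) draw ``mc_fraction`` of the calibration samples
    without replacement; (2) fit PLS on the surviving channel subset;
    (3) weight channels by normalized |beta|; (4) keep the ``ceil(r_i * p)``
    heaviest channels (EDF forced removal); (5) resample that many channels
    with replacement proportionally to weight and keep the distinct draws
    (ARS); (6) score the surviving subset by cross-validated RMSECV on the
    full calibration set (leave-one-out when ``cv_folds`` is None), with
    the component count re-optimized by the inner RMSECV curve up to
    ``a_max``.  Eliminated channels never re-enter.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if not (0.0 < mc_fraction <= 1.0):
        raise ValidationError("mc_fraction must be in (0, 1]")
    if p < 2:
        raise ValidationError("need at least 2 channels")
    schedule = edf_schedule(p, n_runs)
    rng = np.random.default_rng(seed)
    n_mc = max(2, int(round(mc_fraction * n)))

    subset = np.arange(p)
    subset_history: list[np.ndarray] = []
    weight_history: list[np.ndarray] = []
    rmsecv_history: list[float] = []
    components_history: list[int] = []

    for i in range(1, n_runs + 1):
        samples = rng.choice(n, size=n_mc, replace=False)
        Xmc, ymc = X[np.ix_(samples, subset)], y[samples]
        a_cap = min(a_max, n_mc - 1, subset.size)
        # component count for the weight fit re-optimized by inner CV so the
        # coefficient vector is not an overfit, all-noise ranking
        a_fit = cv_rmsecv(Xmc, ymc, a_cap,
                          folds=min(5, n_mc)).optimal_components
        beta = coefficient_paths(Xmc, ymc, a_fit)[a_fit - 1]
        absb = np.abs(beta)
        total = absb.sum()
        if total == 0:
            weights = np.full(subset.size, 1.0 / subset.size)
        else:
            weights = absb / total

        budget = min(schedule.budget(i, p), subset.size)
        # forced removal: heaviest channels first (stable order on ties)
        keep = np.sort(np.argsort(-weights, kind="stable")[:budget])
        kept_channels = subset[keep]
        kept_weights = weights[keep]

        # adaptive reweighted sampling: distinct channels from a weighted
        # draw with replacement
        wsum = kept_weights.sum()
        prob = None if wsum == 0 else kept_weights / wsum
        draw = rng.choice(kept_channels.size, size=budget, replace=True, p=prob)
        survivors = kept_channels[np.unique(draw)]

        if survivors.size < 2:
            warnings.warn(
                f"CARS subset collapsed below 2 channels at run {i}; "
                f"stopping early with {len(subset_history)} recorded runs")
            break
        subset = survivors

        cv = cv_rmsecv(X[:, subset], y,
                       min(a_max, subset.size), folds=cv_folds)
        subset_history.append(subset.copy())
        weight_history.append(kept_weights)
        rmsecv_history.append(cv.min_rmsecv)
        components_history.append(cv.optimal_components)

    if not subset_history:
        raise ValidationError("CARS recorded no valid runs")
    rmsecv = np.asarray(rmsecv_history)
    best = int(np.argmin(rmsecv))
    return CARSResult(
        n_runs=len(subset_history),
        subset_history=tuple(subset_history),
        rmsecv_history=rmsecv,
        weight_history=tuple(weight_history),
        components_history=np.asarray(components_history),
        best_run=best,
        selected_channels=subset_history[best],
    )
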