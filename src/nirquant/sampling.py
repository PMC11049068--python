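"""Outlier screening and calibration/prediction partitioning.

Mahalanobis screening works in a low-dimensional principal-component score
space because spectral matrices have far more channels than samples, making
the full-space covariance singular.  Partitioning uses the deterministic
Kennard-Stone max-min algorithm so the calibration set spans the spectral
space and its reference range covers the prediction set's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .containers import SpectraSet, ValidationError


@dataclass(frozen=True)
class OutlierReport:
    sample_ids: tuple[str, ...]
    distances: np.ndarray
    threshold: float
    flagged_ids: tuple[str, ...]

    @property
    def retained_ids(self) -> tuple[str, ...]:
        flagged = set(self.flagged_ids)
        return tuple(s for s in self.sample_ids if s not in flagged)


@dataclass(frozen=True)
class PartitionResult:
    calibration_ids: tuple[str, ...]
    prediction_ids: tuple[str, ...]
    order_selected: tuple[str, ...]


def mahalanobis_screen(s: SpectraSet, k_components: int = 5,
                       sd_multiplier: float = 3.0,
                       y: np.ndarray | None = None) -> OutlierReport:
    """Flag spectra whose Mahalanobis distance exceeds mean + k*sd.

    Distances are computed in the ``k_components``-dimensional PCA score
    space of the (centered) spectra, with the covariance estimated from the
    scores.  ``y`` optionally appends a standardized concentration column to
    the matrix before PCA, for joint spectra+concentration screening.
    """
    n = s.n_samples
    if not (n > k_components >= 1):
        raise ValidationError(
            f"need n > k_components >= 1 (n={n}, k={k_components})")
    x = s.absorbance
    if y is not None:
        yv = np.asarray(y, dtype=float)
        if yv.shape != (n,):
            raise ValidationError("y must be one value per sample")
        sd = yv.std(ddof=1)
        if sd == 0:
            raise ValidationError("y is constant; cannot standardize")
        # scale concentration to match the spectra's overall spread
        yv = (yv - yv.mean()) / sd * x.std()
        x = np.column_stack([x, yv])

    xc = x - x.mean(axis=0)
    # PCA scores via thin SVD; rank check guards degenerate score axes
    u, sv, _ = np.linalg.svd(xc, full_matrices=False)
    if np.sum(sv > sv[0] * 1e-12) < k_components:
        raise ValidationError(
            f"spectra have rank < {k_components}; use a smaller k_components")
    scores = u[:, :k_components] * sv[:k_components]

    cov = np.cov(scores, rowvar=False).reshape(k_components, k_components)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular covariance in score space; use a smaller k_components"
        ) from exc
    centered = scores - scores.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
    distances = np.sqrt(np.maximum(d2, 0.0))

    threshold = float(distances.mean() + sd_multiplier * distances.std(ddof=1))
    flagged = tuple(s.sample_ids[i]
                    for i in np.flatnonzero(distances > threshold))
    return OutlierReport(sample_ids=s.sample_ids, distances=distances,
                         threshold=threshold, flagged_ids=flagged)


def kennard_stone(s: SpectraSet, n_calibration: int) -> PartitionResult:
    """Kennard-Stone max-min partition in spectral Euclidean space.

    Seeds with the two most distant samples, then repeatedly adds the
    candidate whose minimum distance to the selected set is largest, until
    ``n_calibration`` samples are selected.  Ties break on the lowest sample
    index, so the partition is deterministic.
    """
    n = s.n_samples
    if not (2 <= n_calibration <= n):
        raise ValidationError(
            f"n_calibration must be in [2, {n}], got {n_calibration}")
    x = s.absorbance
    dist = cdist(x, x)

    # seed: maximal pairwise distance, lowest-index pair on ties
    flat = np.argmax(dist)
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    selected_mask = np.zeros(n, dtype=bool)
    selected_mask[selected] = True
    # min distance from each candidate to the selected set
    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])

    while len(selected) < n_calibration:
        min_dist[selected_mask] = -np.inf
        nxt = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        selected.append(nxt)
        selected_mask[nxt] = True
        min_dist = np.minimum(min_dist, dist[nxt])

    order = tuple(s.sample_ids[k] for k in selected)
    cal = set(selected)
    calibration = tuple(s.sample_ids[k] for k in range(n) if k in cal)
    prediction = tuple(s.sample_ids[k] for k in range(n) if k not in cal)
    return PartitionResult(calibration_ids=calibration,
                           prediction_ids=prediction,
                           order_selected=order)
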