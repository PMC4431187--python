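"""Kennard-Stone calibration/prediction sample partitioning.

The classic max-min design: start from the two most distant samples, then
repeatedly add the sample whose minimal Euclidean distance to the selected
set is largest. The procedure is deterministic; ties break to the lowest
sample index. Distances are computed on the raw spectra so a single split is
shared across all preprocessing comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datasets import SpectraSet

__all__ = ["SplitResult", "kennard_stone"]


@dataclass(frozen=True)
class SplitResult:
    """Calibration indices (in selection order) and prediction indices."""

    calibration: tuple[int, ...]
    prediction: tuple[int, ...]

    def __post_init__(self) -> None:
        overlap = set(self.calibration) & set(self.prediction)
        if overlap:
            raise ValueError(f"calibration/prediction overlap: {sorted(overlap)}")

    @property
    def n_samples(self) -> int:
        return len(self.calibration) + len(self.prediction)

    def calibration_sorted(self) -> np.ndarray:
        return np.asarray(sorted(self.calibration), dtype=int)

    def prediction_sorted(self) -> np.ndarray:
        return np.asarray(sorted(self.prediction), dtype=int)


def kennard_stone(spectra: SpectraSet | np.ndarray, n_calibration: int) -> SplitResult:
    """Kennard-Stone selection of ``n_calibration`` calibration samples."""
    x = spectra.absorbance if isinstance(spectra, SpectraSet) else np.asarray(spectra, float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if not 2 <= n_calibration <= n:
        raise ValueError(
            f"n_calibration must be in [2, {n}], got {n_calibration}"
        )
    dist = squareform(pdist(x, metric="euclidean"))
    # initial pair: maximal distance; np.argmax takes the first (lowest
    # flat index) maximum, so duplicate-spectra ties are broken to the
    # lowest index pair.
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_calibration:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    remaining = tuple(k for k in range(n) if k not in set(selected))
    return SplitResult(calibration=tuple(selected), prediction=remaining)
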