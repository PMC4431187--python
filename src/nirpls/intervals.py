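"""Wavelength-interval variable selection: SiPLS and MWPLS.

SiPLS splits the spectrum into equidistant subintervals (default 20),
exhaustively evaluates every combination of ``combo_size`` of them (default
3, i.e. C(20,3) = 1140 joint models) and ranks the combinations by the
leave-one-out RMSECV of a PLS model restricted to the combined variables,
each with its own PRESS-selected factor count.

MWPLS slides a contiguous window of size H across the spectrum and maps the
LOO RMSECV of a PLS model on each window; if no window beats the
full-spectrum RMSECV, window selection offers no gain for that analyte.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import SpectraSet, WavelengthGrid
from .pls import loo_press

__all__ = [
    "IntervalSet",
    "SiPLSEntry",
    "SiPLSResult",
    "MWPLSResult",
    "make_intervals",
    "sipls_search",
    "mwpls_scan",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalSet:
    """Equidistant partition of the variable axis into half-open ranges."""

    n_variables: int
    bounds: tuple[tuple[int, int], ...]

    @property
    def n_intervals(self) -> int:
        return len(self.bounds)

    def columns(self, which) -> np.ndarray:
        """Concatenated variable indices of the given interval numbers."""
        return np.concatenate(
            [np.arange(*self.bounds[i]) for i in sorted(which)]
        )

    def mask(self, which) -> np.ndarray:
        m = np.zeros(self.n_variables, dtype=bool)
        m[self.columns(which)] = True
        return m

    def nm_label(self, i: int, grid: WavelengthGrid) -> str:
        """Interval label in integer-nm form, e.g. "870–940 nm"."""
        lo, hi = self.bounds[i]
        wl = grid.wavelengths()
        start = wl[lo]
        stop = grid.start_nm + grid.step_nm * hi  # half-open end
        return f"{start:.0f}–{stop:.0f} nm"


def make_intervals(n_variables: int, n_intervals: int) -> IntervalSet:
    """Split ``[0, P)`` into equidistant half-open ranges.

    Sizes differ by at most one; any remainder goes to the leading
    intervals. With P = 2800 and 20 intervals, all are exactly 140 wide.
    """
    if not 1 <= n_intervals <= n_variables:
        raise ValueError(
            f"n_intervals must be in [1, {n_variables}], got {n_intervals}"
        )
    base, extra = divmod(n_variables, n_intervals)
    bounds = []
    start = 0
    for i in range(n_intervals):
        width = base + (1 if i < extra else 0)
        bounds.append((start, start + width))
        start += width
    return IntervalSet(n_variables=n_variables, bounds=tuple(bounds))


@dataclass(frozen=True)
class SiPLSEntry:
    intervals: tuple[int, ...]
    n_factors: int
    rmsecv: float


@dataclass
class SiPLSResult:
    """Exhaustive interval-combination search, ranked by RMSECV."""

    entries: list[SiPLSEntry]  # sorted ascending by RMSECV
    interval_set: IntervalSet
    combo_size: int
    baseline_rmsecv: float
    baseline_factors: int
    a_max: int

    @property
    def best(self) -> SiPLSEntry:
        return self.entries[0]

    def top(self, n: int = 10) -> list[SiPLSEntry]:
        return self.entries[:n]

    def best_mask(self) -> np.ndarray:
        return self.interval_set.mask(self.best.intervals)

    @property
    def improves_on_full_spectrum(self) -> bool:
        return self.best.rmsecv <= self.baseline_rmsecv


def sipls_search(
    x: np.ndarray | SpectraSet,
    y: np.ndarray,
    n_intervals: int = 20,
    combo_size: int = 3,
    a_max: int = 10,
) -> SiPLSResult:
    """Synergy-interval PLS: score every C(n_intervals, combo_size) model.

    Each combination concatenates its intervals' variables, picks its factor
    count by LOO PRESS (capped at ``a_max`` and at what the subset supports)
    and records the RMSECV at that count. Deterministic; ties in the ranking
    break lexicographically on the interval tuple.
    """
    xm = x.absorbance if isinstance(x, SpectraSet) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = xm.shape
    if combo_size > n_intervals:
        raise ValueError("combo_size cannot exceed n_intervals")
    iset = make_intervals(p, n_intervals)
    baseline = loo_press(xm, y, a_max=a_max)
    entries = []
    for combo in itertools.combinations(range(n_intervals), combo_size):
        cols = iset.columns(combo)
        if cols.size < 1:
            logger.warning("combination %s has no variables; skipped", combo)
            continue
        sub = xm[:, cols]
        curve = loo_press(sub, y, a_max=min(a_max, cols.size))
        entries.append(
            SiPLSEntry(
                intervals=combo,
                n_factors=curve.selected,
                rmsecv=curve.selected_rmsecv,
            )
        )
    entries.sort(key=lambda e: (e.rmsecv, e.intervals))
    return SiPLSResult(
        entries=entries,
        interval_set=iset,
        combo_size=combo_size,
        baseline_rmsecv=baseline.selected_rmsecv,
        baseline_factors=baseline.selected,
        a_max=a_max,
    )


@dataclass
class MWPLSResult:
    """Moving-window PLS scan: RMSECV map per window size and position."""

    window_sizes: tuple[int, ...]
    starts: dict[int, np.ndarray]  # H -> window start positions
    rmsecv: dict[int, np.ndarray]  # H -> RMSECV per start
    factors: dict[int, np.ndarray]  # H -> selected factors per start
    baseline_rmsecv: float
    stride: int

    def best_window(self, h: int) -> tuple[int, float, int]:
        """(start, rmsecv, n_factors) of the best window of size ``h``."""
        i = int(np.argmin(self.rmsecv[h]))
        return int(self.starts[h][i]), float(self.rmsecv[h][i]), int(self.factors[h][i])

    @property
    def any_window_beats_full_spectrum(self) -> bool:
        return any(
            float(np.min(r)) < self.baseline_rmsecv for r in self.rmsecv.values()
        )


def mwpls_scan(
    x: np.ndarray | SpectraSet,
    y: np.ndarray,
    window_sizes: tuple[int, ...] = tuple(range(13, 42, 2)),
    a_max: int = 10,
    stride: int = 1,
) -> MWPLSResult:
    """Moving-window PLS over all listed window sizes.

    Window sizes default to the odd values 13..41. Each window's factor count
    comes from LOO PRESS capped at ``min(a_max, H - 1)``. A stride larger
    than one thins the start positions for speed; position 0 is always
    included.
    """
    xm = x.absorbance if isinstance(x, SpectraSet) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = xm.shape
    if min(window_sizes) < 3:
        raise ValueError("minimum window size is 3")
    if max(window_sizes) > p:
        raise ValueError(
            f"window size {max(window_sizes)} exceeds {p} variables"
        )
    baseline = loo_press(xm, y, a_max=a_max)
    starts_d, rmsecv_d, factors_d = {}, {}, {}
    for h in window_sizes:
        starts = np.arange(0, p - h + 1, stride)
        vals = np.empty(starts.size)
        facs = np.empty(starts.size, dtype=int)
        cap = min(a_max, h - 1)
        for i, s in enumerate(starts):
            sub = xm[:, s : s + h]
            curve = loo_press(sub, y, a_max=cap)
            vals[i] = curve.selected_rmsecv
            facs[i] = curve.selected
        starts_d[h], rmsecv_d[h], factors_d[h] = starts, vals, facs
    return MWPLSResult(
        window_sizes=tuple(window_sizes),
        starts=starts_d,
        rmsecv=rmsecv_d,
        factors=factors_d,
        baseline_rmsecv=baseline.selected_rmsecv,
        stride=stride,
    )
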