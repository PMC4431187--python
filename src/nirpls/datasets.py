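"""In-memory containers for NIR calibration data.

A :class:`SpectraSet` holds an ``N x P`` absorbance matrix on a fixed
:class:`WavelengthGrid`; a :class:`ReferenceSet` holds the per-sample analyte
concentrations (mg/mL) that serve as regression targets.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["WavelengthGrid", "SpectraSet", "ReferenceSet"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid, half-open ``[start_nm, stop_nm)``.

    The default grid (800-2200 nm at 0.5 nm) has exactly 2800 points, matching
    a scanning NIR process analyzer recording over that range.
    """

    start_nm: float = 800.0
    stop_nm: float = 2200.0
    step_nm: float = 0.5

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        if self.start_nm >= self.stop_nm:
            raise ValueError(
                f"start_nm ({self.start_nm}) must be below stop_nm ({self.stop_nm})"
            )
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "grid span must be an integer multiple of step_nm; "
                f"got span {self.stop_nm - self.start_nm} / step {self.step_nm}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm))

    def wavelengths(self) -> np.ndarray:
        """Grid values in nm, strictly increasing, length :attr:`n_points`."""
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, nm: float) -> int:
        """Index of the grid point containing ``nm`` (half-open bins)."""
        if not (self.start_nm <= nm < self.stop_nm):
            raise ValueError(f"{nm} nm outside grid [{self.start_nm}, {self.stop_nm})")
        return int((nm - self.start_nm) / self.step_nm)


def _default_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


@dataclass
class SpectraSet:
    """Absorbance spectra for a set of samples on a common wavelength grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D (samples x wavelengths) array")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {self.wavelengths.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not self.sample_ids:
            self.sample_ids = _default_ids(self.absorbance.shape[0])
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("sample_ids length does not match the number of spectra")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Copy of this set with a new absorbance matrix of the same shape."""
        if absorbance.shape != self.absorbance.shape:
            raise ValueError("replacement absorbance must preserve the matrix shape")
        return replace(self, absorbance=np.asarray(absorbance, dtype=float))

    def subset(self, indices) -> "SpectraSet":
        """Row subset (new object; metadata rows follow the samples)."""
        indices = np.asarray(indices, dtype=int)
        meta = self.metadata.iloc[indices] if self.metadata is not None else None
        return SpectraSet(
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
            metadata=meta,
        )


@dataclass
class ReferenceSet:
    """Reference-method concentrations (mg/mL), one column per analyte."""

    analytes: list[str]
    concentrations: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.concentrations = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        if self.concentrations.shape[1] != len(self.analytes):
            raise ValueError("concentration columns must match the analyte list")
        if not self.sample_ids:
            self.sample_ids = _default_ids(self.concentrations.shape[0])
        if len(self.sample_ids) != self.concentrations.shape[0]:
            raise ValueError("sample_ids length does not match the concentration rows")

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    def column(self, analyte: str) -> np.ndarray:
        try:
            j = self.analytes.index(analyte)
        except ValueError:
            raise KeyError(
                f"unknown analyte {analyte!r}; have {self.analytes}"
            ) from None
        return self.concentrations[:, j]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.concentrations, index=self.sample_ids, columns=self.analytes
        )

    def subset(self, indices) -> "ReferenceSet":
        indices = np.asarray(indices, dtype=int)
        return ReferenceSet(
            analytes=list(self.analytes),
            concentrations=self.concentrations[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
        )
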