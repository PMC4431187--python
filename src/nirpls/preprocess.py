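"""Spectral preprocessing menu.

Implements the eight-method comparison menu common in NIR calibration work:
raw pass-through, Savitzky-Golay smoothing (9 or 11 points), SG smoothing
with embedded first/second derivative, unit-norm normalisation, multiplicative
scatter correction (MSC) and standard normal variate (SNV).

Statistics learned from calibration data (the MSC reference spectrum) are
frozen in a :class:`Preprocessor` and reused on prediction data, so held-out
spectra are never allowed to influence the transform.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .datasets import SpectraSet

__all__ = [
    "PreprocessMethod",
    "Preprocessor",
    "METHOD_NAMES",
    "savitzky_golay",
    "snv",
    "msc",
    "normalize",
    "apply_named",
]

#: Canonical method names, in conventional comparison-table order.
METHOD_NAMES = ("RAW", "SG9", "SG11", "SG11+1D", "SG11+2D", "NORMALIZE", "MSC", "SNV")


@dataclass(frozen=True)
class PreprocessMethod:
    """A named preprocessing method with its resolved parameters."""

    name: str
    window: int | None = None
    polyorder: int = 2
    deriv: int = 0

    def __post_init__(self) -> None:
        if self.window is not None:
            if self.window % 2 == 0 or self.window < self.polyorder + 1:
                raise ValueError(
                    f"window must be odd and >= polyorder + 1, got {self.window}"
                )
        if self.deriv not in (0, 1, 2):
            raise ValueError(f"derivative order must be 0, 1 or 2, got {self.deriv}")

    @classmethod
    def from_name(cls, name: str) -> "PreprocessMethod":
        key = name.strip().upper().replace(" ", "")
        table = {
            "RAW": cls("RAW"),
            "SG9": cls("SG9", window=9),
            "SG11": cls("SG11", window=11),
            "SG11+1D": cls("SG11+1D", window=11, deriv=1),
            "SG11+2D": cls("SG11+2D", window=11, deriv=2),
            "NORMALIZE": cls("NORMALIZE"),
            "MSC": cls("MSC"),
            "SNV": cls("SNV"),
        }
        if key not in table:
            raise ValueError(
                f"unknown preprocessing method {name!r}; valid names: "
                + ", ".join(METHOD_NAMES)
            )
        return table[key]


def savitzky_golay(
    spectra: SpectraSet, window: int, polyorder: int = 2, deriv: int = 0
) -> SpectraSet:
    """Savitzky-Golay smoothing / derivative filter along the wavelength axis.

    Derivatives are reported per grid step (the 0.5 nm increment of the
    default grid); edge windows are evaluated from the same polynomial fit
    ("interp" mode) so the grid length is preserved.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be below window {window}")
    if spectra.n_variables < window:
        raise ValueError(
            f"need at least {window} wavelengths, have {spectra.n_variables}"
        )
    out = savgol_filter(
        spectra.absorbance, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=1.0, axis=1, mode="interp",
    )
    return spectra.with_absorbance(out)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: each spectrum to mean 0, sample sd 1."""
    x = spectra.absorbance
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(
            f"constant spectrum (zero sd), sample {spectra.sample_ids[bad[0]]!r}"
        )
    return spectra.with_absorbance((x - mu) / sd)


def _msc_coeffs(x: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row intercept/slope of the least-squares fit of x on reference."""
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant")
    slope = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    intercept = x.mean(axis=1) - slope * reference.mean()
    return intercept, slope


def msc(
    spectra: SpectraSet, reference: np.ndarray | None = None
) -> tuple[SpectraSet, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is regressed on the reference, ``x ~ a + b*ref``, and
    replaced by ``(x - a) / b``. The reference defaults to the mean spectrum
    of the given set and is returned so prediction data can reuse it.
    """
    x = spectra.absorbance
    if reference is None:
        reference = x.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (spectra.n_variables,):
        raise ValueError("MSC reference length must match the wavelength grid")
    intercept, slope = _msc_coeffs(x, reference)
    if np.any(slope == 0):
        i = int(np.flatnonzero(slope == 0)[0])
        raise ValueError(
            f"MSC fitted slope is zero for sample {spectra.sample_ids[i]!r}"
        )
    corrected = (x - intercept[:, None]) / slope[:, None]
    return spectra.with_absorbance(corrected), reference


def normalize(spectra: SpectraSet, norm: str = "l2") -> SpectraSet:
    """Row-wise normalisation; default dialect is unit Euclidean norm.

    Alternatives: ``minmax`` (rows to [0, 1]) and ``area`` (unit L1 norm).
    """
    x = spectra.absorbance
    if norm == "l2":
        scale = np.linalg.norm(x, axis=1)
        if np.any(scale == 0):
            i = int(np.flatnonzero(scale == 0)[0])
            raise ValueError(f"all-zero spectrum, sample {spectra.sample_ids[i]!r}")
        return spectra.with_absorbance(x / scale[:, None])
    if norm == "minmax":
        lo, hi = x.min(axis=1, keepdims=True), x.max(axis=1, keepdims=True)
        span = hi - lo
        if np.any(span == 0):
            raise ValueError("constant spectrum cannot be min-max normalised")
        return spectra.with_absorbance((x - lo) / span)
    if norm == "area":
        scale = np.abs(x).sum(axis=1)
        if np.any(scale == 0):
            raise ValueError("all-zero spectrum cannot be area normalised")
        return spectra.with_absorbance(x / scale[:, None])
    raise ValueError(f"unknown normalisation dialect {norm!r}")


class Preprocessor:
    """A preprocessing method with frozen calibration statistics.

    ``fit_transform`` learns any data-dependent statistics (currently the MSC
    reference spectrum) on calibration data; ``transform`` applies the frozen
    transform to new spectra.
    """

    def __init__(self, method: PreprocessMethod | str):
        if isinstance(method, str):
            method = PreprocessMethod.from_name(method)
        self.method = method
        self.msc_reference: np.ndarray | None = None

    @property
    def name(self) -> str:
        return self.method.name

    def fit_transform(self, spectra: SpectraSet) -> SpectraSet:
        if self.method.name == "MSC":
            out, self.msc_reference = msc(spectra)
            return out
        return self._stateless(spectra)

    def transform(self, spectra: SpectraSet) -> SpectraSet:
        if self.method.name == "MSC":
            if self.msc_reference is None:
                raise ValueError(
                    "MSC reference not fitted; call fit_transform on "
                    "calibration data first"
                )
            out, _ = msc(spectra, reference=self.msc_reference)
            return out
        return self._stateless(spectra)

    def _stateless(self, spectra: SpectraSet) -> SpectraSet:
        m = self.method
        if m.name == "RAW":
            return spectra
        if m.name in ("SG9", "SG11", "SG11+1D", "SG11+2D"):
            return savitzky_golay(spectra, m.window, m.polyorder, m.deriv)
        if m.name == "NORMALIZE":
            return normalize(spectra)
        if m.name == "SNV":
            return snv(spectra)
        raise ValueError(f"unknown preprocessing method {m.name!r}")


def apply_named(
    method: str | PreprocessMethod,
    spectra: SpectraSet,
    context: str = "calibration",
    preprocessor: Preprocessor | None = None,
) -> tuple[SpectraSet, Preprocessor]:
    """Apply a method by name, honouring the calibration/prediction split.

    In ``calibration`` context a new :class:`Preprocessor` is fitted (and
    returned for reuse); in ``prediction`` context the supplied fitted
    preprocessor is applied with its statistics frozen.
    """
    if context not in ("calibration", "prediction"):
        raise ValueError("context must be 'calibration' or 'prediction'")
    if context == "prediction":
        if preprocessor is None:
            raise ValueError("prediction context requires a fitted preprocessor")
        return preprocessor.transform(spectra), preprocessor
    pp = preprocessor or Preprocessor(method)
    return pp.fit_transform(spectra), pp
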