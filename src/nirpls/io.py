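"""Delimited-text file formats for spectra, references, splits and reports.

The spectra file is a CSV whose header is ``sample_id``, optional metadata
columns prefixed ``meta_``, then the wavelengths in nm; one row per sample.
References are a CSV of ``sample_id`` plus one column per analyte (mg/mL).
Splits are two columns (sample id, set label) so every downstream run reuses
the identical partition. Round-tripping any of these preserves values
bit-exactly.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import ReferenceSet, SpectraSet
from .sampling import SplitResult

__all__ = [
    "write_spectra", "read_spectra",
    "write_references", "read_references",
    "load_dataset",
    "write_split", "read_split",
    "write_ground_truth",
]

_GRID_TOL = 1e-9


def write_spectra(path, spectra: SpectraSet) -> None:
    cols = {}
    if spectra.metadata is not None:
        for c in spectra.metadata.columns:
            cols[f"meta_{c}"] = spectra.metadata[c].to_numpy()
    frame = pd.DataFrame(cols, index=pd.Index(spectra.sample_ids, name="sample_id"))
    wl_cols = [f"{w:.1f}" for w in spectra.wavelengths]
    frame = pd.concat(
        [frame, pd.DataFrame(spectra.absorbance, index=frame.index, columns=wl_cols)],
        axis=1,
    )
    # %.17g round-trips doubles bit-exactly
    frame.to_csv(path, float_format="%.17g")


def read_spectra(path) -> SpectraSet:
    frame = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    meta_cols = [c for c in frame.columns if c.startswith("meta_")]
    wl_cols = [c for c in frame.columns if not c.startswith("meta_")]
    wavelengths = np.array([float(c) for c in wl_cols])
    steps = np.diff(wavelengths)
    if np.any(steps <= 0):
        raise ValueError(f"wavelengths not strictly increasing in {path}")
    if np.ptp(steps) > _GRID_TOL:
        raise ValueError(f"irregular wavelength grid in {path}")
    meta = None
    if meta_cols:
        meta = frame[meta_cols].rename(columns=lambda c: c[len("meta_"):])
    return SpectraSet(
        wavelengths=wavelengths,
        absorbance=frame[wl_cols].to_numpy(dtype=float),
        sample_ids=[str(i) for i in frame.index],
        metadata=meta,
    )


def write_references(path, references: ReferenceSet) -> None:
    references.frame().rename_axis("sample_id").to_csv(path, float_format="%.17g")


def read_references(path) -> ReferenceSet:
    frame = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    return ReferenceSet(
        analytes=[str(c) for c in frame.columns],
        concentrations=frame.to_numpy(dtype=float),
        sample_ids=[str(i) for i in frame.index],
    )


def load_dataset(spectra_path, references_path) -> tuple[SpectraSet, ReferenceSet]:
    """Read spectra and references and align the references by sample id."""
    spectra = read_spectra(spectra_path)
    refs = read_references(references_path)
    order = {sid: i for i, sid in enumerate(refs.sample_ids)}
    missing = [sid for sid in spectra.sample_ids if sid not in order]
    if missing:
        raise ValueError(
            f"sample id {missing[0]!r} has spectra but no reference value"
        )
    refs = refs.subset([order[sid] for sid in spectra.sample_ids])
    return spectra, refs


def write_split(path, split: SplitResult, sample_ids) -> None:
    labels = {}
    for i in split.calibration:
        labels[sample_ids[i]] = "calibration"
    for i in split.prediction:
        labels[sample_ids[i]] = "prediction"
    frame = pd.DataFrame(
        {"set": [labels[sid] for sid in sample_ids]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    frame.to_csv(path)


def read_split(path, sample_ids) -> SplitResult:
    frame = pd.read_csv(path, index_col="sample_id")
    order = {sid: i for i, sid in enumerate(sample_ids)}
    missing = [sid for sid in frame.index if sid not in order]
    if missing:
        raise ValueError(f"split file names unknown sample id {missing[0]!r}")
    cal, pred = [], []
    for sid, label in frame["set"].items():
        (cal if label == "calibration" else pred).append(order[sid])
    return SplitResult(calibration=tuple(cal), prediction=tuple(pred))


def write_ground_truth(path, truth: dict) -> None:
    """Structured-text sidecar with the generator's latent draws."""
    record = {}
    # pure spectra / water background are deterministic functions of the
    # recorded bands; the sidecar keeps the latent draws only
    skip = {"pure_spectra", "water_background"}
    for key, value in truth.items():
        if key in skip:
            continue
        if isinstance(value, np.ndarray):
            record[key] = np.asarray(value).tolist()
        elif isinstance(value, dict):
            record[key] = {
                k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
                for k, v in value.items()
            }
        else:
            record[key] = value
    Path(path).write_text(yaml.safe_dump(record, sort_keys=False))
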