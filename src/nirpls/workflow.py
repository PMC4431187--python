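"""End-to-end comparison workflow.

Reproduces the full experimental design on any dataset: Kennard-Stone split,
eight-method preprocessing comparison with PRESS-selected factors, SiPLS
search with a PLS-versus-SiPLS table, an MWPLS scan summary, and single
versus bagging-PLS comparisons (full spectrum and SiPLS-masked) with RMSEP
convergence curves. All outputs are delimited text plus a plain-text
summary; every stochastic stage derives its seed from the config, so a rerun
with the same config is numerically identical.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .bagging import fit_bagging, predict_bagging, rmsep_curve
from .datasets import ReferenceSet, SpectraSet, WavelengthGrid
from .intervals import mwpls_scan, sipls_search
from .pls import evaluate
from .preprocess import METHOD_NAMES
from .sampling import SplitResult, kennard_stone

__all__ = ["RunConfig", "run_workflow", "WorkflowError"]

logger = logging.getLogger(__name__)


class WorkflowError(RuntimeError):
    """A workflow stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    spectra: str
    references: str
    output_dir: str
    seed: int
    split: str | None = None  # optional precomputed split file
    analytes: list[str] = field(default_factory=list)  # empty = all
    methods: list[str] = field(default_factory=lambda: list(METHOD_NAMES))
    n_calibration: int = 50
    a_max: int = 10
    sipls_n_intervals: int = 20
    sipls_combo_size: int = 3
    mwpls_window_sizes: list[int] = field(
        default_factory=lambda: list(range(13, 42, 2))
    )
    mwpls_stride: int = 10
    bagging_members: int = 500

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for key in ("spectra", "references"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config {key} path does not exist: {p}")
        if cfg.split and not Path(cfg.split).exists():
            raise FileNotFoundError(f"config split path does not exist: {cfg.split}")
        return cfg


def _metrics_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analyte": m.analyte,
                "method": m.method,
                "latent_factors": m.n_factors,
                "RMSEC": m.rmsec,
                "R2_cal": m.r2_cal,
                "RMSECV": m.rmsecv,
                "R2_cv": m.r2_cv,
                "RMSEP": m.rmsep,
                "R2_pre": m.r2_pre,
            }
            for m in rows
        ]
    )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except WorkflowError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise WorkflowError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("split")
def _split_stage(spectra: SpectraSet, config: RunConfig, outdir: Path) -> SplitResult:
    if config.split:
        split = nio.read_split(config.split, spectra.sample_ids)
        logger.info("split: reused %s", config.split)
    else:
        split = kennard_stone(spectra, config.n_calibration)
        logger.info(
            "split: Kennard-Stone, %d calibration / %d prediction",
            len(split.calibration), len(split.prediction),
        )
    nio.write_split(outdir / "split.csv", split, spectra.sample_ids)
    return split


@_stage("preprocessing")
def _preprocessing_stage(spectra, references, analyte, split, config, outdir):
    rows, curves, models = [], {}, {}
    for method in config.methods:
        metrics, model, curve = evaluate(
            spectra, references, analyte, split, method=method, a_max=config.a_max
        )
        rows.append(metrics)
        curves[metrics.method] = curve
        models[metrics.method] = (metrics, model)
        logger.info(
            "preprocessing %s/%s: A=%d RMSECV=%.5g", analyte, metrics.method,
            metrics.n_factors, metrics.rmsecv,
        )
    frame = _metrics_frame(rows)
    frame.to_csv(outdir / f"preprocessing_{analyte}.csv", index=False)
    press = pd.DataFrame(
        {name: pd.Series(c.press, index=np.arange(1, c.press.size + 1))
         for name, c in curves.items()}
    ).rename_axis("latent_factors")
    press.to_csv(outdir / f"press_curves_{analyte}.csv")
    # carry the RMSECV winner forward; exact ties prefer the raw spectra
    order = sorted(rows, key=lambda m: (m.rmsecv, m.method != "RAW"))
    winner = order[0]
    logger.info("preprocessing winner for %s: %s", analyte, winner.method)
    return frame, winner, models[winner.method]


@_stage("sipls")
def _sipls_stage(spectra, references, analyte, split, method, config, outdir, grid):
    from .preprocess import Preprocessor

    cal_idx = split.calibration_sorted()
    pp = Preprocessor(method)
    cal = pp.fit_transform(spectra.subset(cal_idx))
    y_cal = references.column(analyte)[cal_idx]
    result = sipls_search(
        cal.absorbance, y_cal,
        n_intervals=config.sipls_n_intervals,
        combo_size=config.sipls_combo_size,
        a_max=config.a_max,
    )
    logger.info(
        "sipls %s: %d combinations, best %s RMSECV=%.5g (full spectrum %.5g)",
        analyte, len(result.entries), result.best.intervals,
        result.best.rmsecv, result.baseline_rmsecv,
    )
    top = result.top(10)
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(top) + 1),
            "intervals": [" ".join(str(i) for i in e.intervals) for e in top],
            "nm_ranges": [
                ", ".join(result.interval_set.nm_label(i, grid) for i in e.intervals)
                for e in top
            ],
            "latent_factors": [e.n_factors for e in top],
            "RMSECV": [e.rmsecv for e in top],
        }
    )
    frame.to_csv(outdir / f"sipls_{analyte}.csv", index=False)
    return result


@_stage("mwpls")
def _mwpls_stage(spectra, references, analyte, split, method, config, outdir):
    from .preprocess import Preprocessor

    cal_idx = split.calibration_sorted()
    pp = Preprocessor(method)
    cal = pp.fit_transform(spectra.subset(cal_idx))
    y_cal = references.column(analyte)[cal_idx]
    result = mwpls_scan(
        cal.absorbance, y_cal,
        window_sizes=tuple(config.mwpls_window_sizes),
        a_max=config.a_max,
        stride=config.mwpls_stride,
    )
    rows = []
    for h in result.window_sizes:
        start, val, fac = result.best_window(h)
        rows.append(
            {"window_size": h, "best_start": start, "best_RMSECV": val,
             "latent_factors": fac}
        )
    frame = pd.DataFrame(rows)
    frame["full_spectrum_RMSECV"] = result.baseline_rmsecv
    frame.to_csv(outdir / f"mwpls_{analyte}.csv", index=False)
    logger.info(
        "mwpls %s: any window beats full spectrum: %s", analyte,
        result.any_window_beats_full_spectrum,
    )
    return result


@_stage("bagging")
def _bagging_stage(spectra, references, analyte, split, method, full_model,
                   sipls_result, config, outdir, seed):
    from .preprocess import Preprocessor

    cal_idx = split.calibration_sorted()
    pred_idx = split.prediction_sorted()
    pp = Preprocessor(method)
    cal = pp.fit_transform(spectra.subset(cal_idx))
    pred = pp.transform(spectra.subset(pred_idx))
    y = references.column(analyte)
    y_cal, y_pred = y[cal_idx], y[pred_idx]

    metrics_full, model_full = full_model
    ens_full = fit_bagging(
        cal.absorbance, y_cal, n_members=config.bagging_members,
        n_factors=metrics_full.n_factors, seed=seed,
    )
    curve_full = rmsep_curve(ens_full, pred.absorbance, y_pred)

    mask = sipls_result.best_mask()
    from .pls import evaluate as _evaluate

    sipls_metrics, sipls_model, _ = _evaluate(
        spectra, references, analyte, split, method=method, mask=mask,
        n_factors=sipls_result.best.n_factors, a_max=config.a_max,
    )
    ens_sipls = fit_bagging(
        cal.absorbance, y_cal, n_members=config.bagging_members,
        n_factors=sipls_result.best.n_factors, mask=mask, seed=seed + 1,
    )
    curve_sipls = rmsep_curve(ens_sipls, pred.absorbance, y_pred)

    pd.DataFrame(
        {"iteration": np.arange(1, curve_full.size + 1),
         "RMSEP_full_bagging": curve_full,
         "RMSEP_sipls_bagging": curve_sipls}
    ).to_csv(outdir / f"bagging_curve_{analyte}.csv", index=False)

    comparison = pd.DataFrame(
        [
            {"model": "PLS", "RMSEP": metrics_full.rmsep},
            {"model": "SiPLS", "RMSEP": sipls_metrics.rmsep},
            {"model": "bagging-PLS", "RMSEP": float(curve_full[-1])},
            {"model": "SiPLS+bagging-PLS", "RMSEP": float(curve_sipls[-1])},
        ]
    )
    comparison.to_csv(outdir / f"rmsep_comparison_{analyte}.csv", index=False)
    logger.info(
        "bagging %s: PLS %.5g, SiPLS %.5g, bagging %.5g, SiPLS+bagging %.5g",
        analyte, metrics_full.rmsep, sipls_metrics.rmsep,
        curve_full[-1], curve_sipls[-1],
    )
    return {
        "pls_metrics": metrics_full,
        "sipls_metrics": sipls_metrics,
        "bagging_rmsep": float(curve_full[-1]),
        "sipls_bagging_rmsep": float(curve_sipls[-1]),
        "curve_full": curve_full,
        "curve_sipls": curve_sipls,
        "comparison": comparison,
    }


def run_workflow(config: RunConfig) -> dict:
    """Execute the full comparison workflow; returns the report bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("nirpls")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("config: %s", config)
        spectra, references = nio.load_dataset(config.spectra, config.references)
        step = np.diff(spectra.wavelengths)[0]
        grid = WavelengthGrid(
            start_nm=float(spectra.wavelengths[0]),
            stop_nm=float(spectra.wavelengths[-1] + step),
            step_nm=float(step),
        )
        analytes = config.analytes or references.analytes
        split = _split_stage(spectra, config, outdir)

        report: dict = {"split": split, "analytes": {}}
        summary_lines = [
            f"samples: {spectra.n_samples} ({len(split.calibration)} calibration"
            f" / {len(split.prediction)} prediction), "
            f"variables: {spectra.n_variables}",
        ]
        for a_idx, analyte in enumerate(analytes):
            pre_frame, winner, full_model = _preprocessing_stage(
                spectra, references, analyte, split, config, outdir
            )
            sipls_result = _sipls_stage(
                spectra, references, analyte, split, winner.method, config,
                outdir, grid,
            )
            mwpls_result = _mwpls_stage(
                spectra, references, analyte, split, winner.method, config, outdir
            )
            bag = _bagging_stage(
                spectra, references, analyte, split, winner.method, full_model,
                sipls_result, config, outdir, seed=config.seed + 1000 * a_idx,
            )
            pls_vs_sipls = _metrics_frame(
                [bag["pls_metrics"], bag["sipls_metrics"]]
            )
            pls_vs_sipls.insert(1, "model", ["PLS", "SiPLS"])
            pls_vs_sipls.to_csv(outdir / f"pls_vs_sipls_{analyte}.csv", index=False)
            report["analytes"][analyte] = {
                "preprocessing": pre_frame,
                "winner": winner,
                "sipls": sipls_result,
                "mwpls": mwpls_result,
                "bagging": bag,
            }
            best_nm = ", ".join(
                sipls_result.interval_set.nm_label(i, grid)
                for i in sipls_result.best.intervals
            )
            summary_lines += [
                "",
                f"[{analyte}]",
                f"  preprocessing winner: {winner.method} "
                f"(A={winner.n_factors}, RMSECV={winner.rmsecv:.5g} mg/mL)",
                f"  SiPLS best intervals: {best_nm} "
                f"(RMSECV={sipls_result.best.rmsecv:.5g} mg/mL, "
                f"full spectrum {sipls_result.baseline_rmsecv:.5g})",
                f"  MWPLS beats full spectrum: "
                f"{mwpls_result.any_window_beats_full_spectrum}",
                f"  RMSEP (mg/mL): PLS {bag['pls_metrics'].rmsep:.5g}, "
                f"SiPLS {bag['sipls_metrics'].rmsep:.5g}, "
                f"bagging-PLS {bag['bagging_rmsep']:.5g}, "
                f"SiPLS+bagging {bag['sipls_bagging_rmsep']:.5g}",
            ]
        (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
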