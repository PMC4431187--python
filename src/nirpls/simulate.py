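"""Synthetic extraction-process NIR data with known ground truth.

The generator emulates an online NIR sensor watching a three-batch aqueous
herbal extraction: flavonoid concentrations follow first-order extraction
kinetics sampled on a batch-wise schedule, spectra are Beer-Lambert mixtures
of Gaussian pure-component bands on top of a dominant water band near
1950 nm, and measurement artefacts (multiplicative scatter, linear baseline,
additive/shot noise, reference-assay error) are drawn from a seeded RNG.
Every latent draw is returned in a ground-truth record so downstream
estimators can be tested for parameter recovery.

Concentration envelopes follow the reference-assay ranges of the emulated
study: naringin 0.2303-2.5504, hesperidin 0.0146-0.1889, neohesperidin
0.1893-2.0272 mg/mL.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ReferenceSet, SpectraSet, WavelengthGrid

__all__ = [
    "ComponentBand",
    "KineticsSpec",
    "NoiseSpec",
    "pure_component_spectra",
    "extraction_kinetics",
    "extraction_profiles",
    "simulate_dataset",
    "default_fixture",
    "default_bands",
    "default_kinetics",
    "interval_recovery_fixture",
    "informative_intervals",
    "DEFAULT_FIXTURE_SEED",
]

#: Documented seed of the packaged 75-sample fixture.
DEFAULT_FIXTURE_SEED = 20150414

ANALYTES = ("naringin", "hesperidin", "neohesperidin")


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorption band of a pure component.

    ``amplitude`` is absorbance per (mg/mL) at the band centre; ``width_nm``
    is the Gaussian sigma.
    """

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError(f"width_nm must be positive, got {self.width_nm}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


# Sampling schedule: (batch, phase, interval minutes). Batch phases are
# heating (30 min up to the boil), then 0-1 h and 1-1.5 h of timed
# extraction; samples sit at phase_start + i*interval up to the phase end.
DEFAULT_SCHEDULE: tuple[tuple[int, str, float], ...] = (
    (1, "heating", 3.0),
    (1, "0-1h", 4.0),
    (1, "1-1.5h", 4.0),
    (2, "heating", 5.0),
    (2, "0-1h", 5.0),
    (2, "1-1.5h", 5.0),
    (3, "heating", 5.0),
    (3, "0-1h", 6.0),
    (3, "1-1.5h", 10.0),
)


@dataclass(frozen=True)
class KineticsSpec:
    """First-order extraction kinetics, three sequential batches.

    ``plateau[b, a]`` is the asymptotic concentration of analyte ``a`` in
    batch ``b`` (mg/mL); it must decrease across batches because each batch
    re-extracts the same herb charge with fresh water. ``rate_per_min[b]`` is
    the first-order rate constant. Clock time ``t`` is measured from the boil
    (heating mapped to negative offsets); kinetics run on
    ``t + heating_min[b]``, i.e. extraction starts when heating starts.
    Lognormal jitter (sd ``plateau_jitter_sd`` per batch x analyte,
    ``rate_jitter_sd`` per batch) gives seed-to-seed variation.
    """

    analytes: tuple[str, ...] = ANALYTES
    plateau: tuple[tuple[float, ...], ...] = ()
    rate_per_min: tuple[float, ...] = (0.05, 0.04, 0.04)
    heating_min: tuple[float, ...] = (30.0, 30.0, 30.0)
    schedule: tuple[tuple[int, str, float], ...] = DEFAULT_SCHEDULE
    plateau_jitter_sd: float = 0.01
    rate_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("sampling schedule must be nonempty")
        if any(interval <= 0 for _, _, interval in self.schedule):
            raise ValueError("schedule intervals must be positive")
        if any(k < 0 for k in self.rate_per_min):
            raise ValueError("rate constants must be nonnegative")
        if self.plateau:
            arr = np.asarray(self.plateau, dtype=float)
            if np.any(arr < 0):
                raise ValueError("plateau concentrations must be nonnegative")
            if arr.shape[0] > 1 and not np.all(np.diff(arr, axis=0) < 0):
                raise ValueError(
                    "plateau concentrations must decrease across batches"
                )

    @property
    def n_batches(self) -> int:
        return len(self.rate_per_min)


def default_kinetics() -> KineticsSpec:
    """Kinetics whose sampled concentrations stay inside the reference
    envelopes (naringin 0.2303-2.5504, hesperidin 0.0146-0.1889,
    neohesperidin 0.1893-2.0272 mg/mL) for all seeds."""
    # per-batch plateau scale: less analyte remains for batches 2 and 3
    batch_scale = np.array([1.0, 0.75, 0.62])
    # plateau amplitude per analyte: 95% of the envelope maximum divided by
    # the asymptote fraction actually reached in batch 1 (1 - e^{-k*118})
    top = np.array([2.5504, 0.1889, 2.0272])
    amp = 0.95 * top / -np.expm1(-0.05 * 118.0)
    plateau = tuple(tuple(amp * s) for s in batch_scale)
    return KineticsSpec(plateau=plateau)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement artefacts applied to clean Beer-Lambert mixtures.

    ``additive_sd`` is the absolute absorbance noise sd; ``None`` resolves at
    simulation time to 0.5% of the median clean absorbance.
    ``shot_fraction`` adds signal-proportional (heteroscedastic) noise.
    A fraction of samples carry a transient broad-band artefact (a Gaussian
    bump of random position, width and amplitude) emulating particle/bubble
    events that pass an online probe's inline filters; these high-leverage
    spectra are what makes single-model calibration unstable on process
    streams. Reference concentrations get relative plus absolute assay noise
    to mimic an imperfect chromatographic reference method.
    """

    additive_sd: float | None = None
    shot_fraction: float = 0.02
    baseline_offset_range: tuple[float, float] = (-0.03, 0.03)
    baseline_slope_range: tuple[float, float] = (-5e-5, 5e-5)
    scatter_range: tuple[float, float] = (0.90, 1.10)
    water_amplitude: float = 1.0
    water_center_nm: float = 1950.0
    water_width_nm: float = 90.0
    outlier_fraction: float = 0.08
    outlier_amplitude_range: tuple[float, float] = (0.03, 0.12)
    reference_rel_sd: float = 0.03
    reference_abs_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.additive_sd is not None and self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")
        if self.scatter_range[0] <= 0:
            raise ValueError("multiplicative scatter factors must be positive")

    @classmethod
    def none(cls) -> "NoiseSpec":
        """Noiseless limit: unit scatter, flat baseline, exact references.

        The water band is kept (it is a constant background, removed by
        centering), so noiseless spectra are still realistic mixtures.
        """
        return cls(
            additive_sd=0.0,
            shot_fraction=0.0,
            baseline_offset_range=(0.0, 0.0),
            baseline_slope_range=(0.0, 0.0),
            scatter_range=(1.0, 1.0),
            outlier_fraction=0.0,
            reference_rel_sd=0.0,
            reference_abs_frac=0.0,
        )


def default_bands() -> dict[str, tuple[ComponentBand, ...]]:
    """Pure-component band placement for the default fixture.

    Each analyte's dominant bands sit inside the spectral regions an
    interval-selection run is expected to recover (hesperidin near 870-940,
    1430-1500 and 1570-1640 nm; naringin 1290-1360, 1570-1640, 1640-1710 nm;
    neohesperidin 940-1010, 1290-1360, 1640-1710 nm). Amplitudes are scaled
    so each analyte contributes a comparable ~0.2 AU at its maximum
    concentration despite hesperidin's ~13x lower range.
    """
    return {
        "naringin": (
            ComponentBand(1318.0, 13.0, 0.075),
            ComponentBand(1598.0, 12.0, 0.055),
            ComponentBand(1668.0, 13.0, 0.080),
        ),
        "hesperidin": (
            ComponentBand(905.0, 14.0, 1.10),
            ComponentBand(1465.0, 15.0, 0.90),
            ComponentBand(1610.0, 12.0, 0.70),
        ),
        "neohesperidin": (
            ComponentBand(975.0, 14.0, 0.095),
            ComponentBand(1340.0, 12.0, 0.060),
            ComponentBand(1690.0, 13.0, 0.075),
        ),
    }


def pure_component_spectra(
    bands: Mapping[str, Sequence[ComponentBand]], grid: WavelengthGrid
) -> np.ndarray:
    """Pure-component spectra matrix (analytes x P), Gaussian band sums.

    Row ``a`` is ``sum_b amplitude_b * exp(-(lambda - center_b)^2 /
    (2 width_b^2))`` over analyte ``a``'s bands. Every band centre must lie
    inside the grid.
    """
    wl = grid.wavelengths()
    rows = []
    for analyte, analyte_bands in bands.items():
        if len(analyte_bands) == 0:
            raise ValueError(f"analyte {analyte!r} has no bands")
        row = np.zeros_like(wl)
        for band in analyte_bands:
            if not (grid.start_nm <= band.center_nm < grid.stop_nm):
                raise ValueError(
                    f"band centre {band.center_nm} nm of {analyte!r} lies outside "
                    f"the grid [{grid.start_nm}, {grid.stop_nm})"
                )
            row += band.amplitude * np.exp(
                -((wl - band.center_nm) ** 2) / (2.0 * band.width_nm**2)
            )
        rows.append(row)
    return np.vstack(rows)


def extraction_kinetics(t_min, plateau, rate_per_min) -> np.ndarray:
    """First-order extraction law ``C(t) = C_inf (1 - e^{-k t})``, 0 for t<0."""
    if np.any(np.asarray(rate_per_min) < 0):
        raise ValueError("rate constant must be nonnegative")
    t = np.maximum(np.asarray(t_min, dtype=float), 0.0)
    return np.asarray(plateau) * -np.expm1(-np.asarray(rate_per_min) * t)


def _schedule_times(spec: KineticsSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample clock times (min, boil = 0) and batch labels from the schedule."""
    phase_span = {"0-1h": (0.0, 60.0), "1-1.5h": (60.0, 90.0)}
    times, batches = [], []
    for batch, phase, interval in spec.schedule:
        if phase == "heating":
            t0, t1 = -spec.heating_min[batch - 1], 0.0
        else:
            try:
                t0, t1 = phase_span[phase]
            except KeyError:
                raise ValueError(
                    f"unknown phase {phase!r}; expected heating, 0-1h or 1-1.5h"
                ) from None
        pts = np.arange(t0 + interval, t1 + interval / 2.0, interval)
        pts = pts[pts <= t1 + 1e-9]
        times.extend(pts)
        batches.extend([batch] * len(pts))
    return np.asarray(times), np.asarray(batches, dtype=int)


def extraction_profiles(
    spec: KineticsSpec | None = None, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concentration profiles over the sampling schedule.

    Returns ``(C, times, batches)`` where ``C`` is N x n_analytes (mg/mL),
    ``times`` are clock minutes (0 = boil reached, heating negative) and
    ``batches`` are 1-based batch labels. Within each batch concentrations
    are monotone nondecreasing in time.
    """
    spec = spec or default_kinetics()
    if not spec.plateau:
        from dataclasses import replace

        spec = replace(spec, plateau=default_kinetics().plateau)
    times, batches = _schedule_times(spec)
    plateau = np.asarray(spec.plateau, dtype=float)  # (n_batches, n_analytes)
    rates = np.asarray(spec.rate_per_min, dtype=float)
    rng = np.random.default_rng(seed)
    jit_p = np.exp(spec.plateau_jitter_sd * rng.standard_normal(plateau.shape))
    jit_k = np.exp(spec.rate_jitter_sd * rng.standard_normal(rates.shape))
    conc = np.empty((times.size, plateau.shape[1]))
    for b in range(spec.n_batches):
        sel = batches == b + 1
        t_eff = times[sel] + spec.heating_min[b]
        conc[sel] = extraction_kinetics(
            t_eff[:, None], plateau[b] * jit_p[b], rates[b] * jit_k[b]
        )
    return conc, times, batches


def simulate_dataset(
    grid: WavelengthGrid | None = None,
    bands: Mapping[str, Sequence[ComponentBand]] | None = None,
    kinetics: KineticsSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> tuple[SpectraSet, ReferenceSet, dict]:
    """Simulate one online-NIR extraction run.

    ``spectrum_i = m_i (sum_a C_ia * pure_a + water) + offset_i +
    slope_i (lambda - lambda_mid) + eps_i``. The same seed reproduces the
    dataset bit-exactly; the returned ground-truth record stores every latent
    draw (true concentrations, scatter factors, baselines, noise sd).
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    grid = grid or WavelengthGrid()
    bands = bands if bands is not None else default_bands()
    kinetics = kinetics or default_kinetics()
    noise = noise or NoiseSpec()

    pure = pure_component_spectra(bands, grid)  # (n_analytes, P)
    analytes = list(bands.keys())
    if kinetics.plateau and len(kinetics.analytes) != len(analytes):
        raise ValueError(
            "kinetics analyte count does not match the band dictionary"
        )

    ss = np.random.SeedSequence(seed)
    s_kin, s_noise, s_ref = ss.spawn(3)
    conc, times, batches = extraction_profiles(kinetics, seed=s_kin)
    n, p = conc.shape[0], grid.n_points
    wl = grid.wavelengths()

    water = noise.water_amplitude * np.exp(
        -((wl - noise.water_center_nm) ** 2) / (2.0 * noise.water_width_nm**2)
    )
    clean = conc @ pure + water  # (n, P)

    rng = np.random.default_rng(s_noise)
    m = rng.uniform(*noise.scatter_range, size=n)
    offsets = rng.uniform(*noise.baseline_offset_range, size=n)
    slopes = rng.uniform(*noise.baseline_slope_range, size=n)
    sd = noise.additive_sd
    if sd is None:
        sd = 0.005 * float(np.median(clean))
    lam_mid = 0.5 * (grid.start_nm + grid.stop_nm)
    baseline = offsets[:, None] + slopes[:, None] * (wl - lam_mid)
    # transient particle/bubble events: broad Gaussian bumps on a few samples
    is_outlier = rng.random(n) < noise.outlier_fraction
    bump = np.zeros((n, p))
    bump_params = []
    for i in np.flatnonzero(is_outlier):
        amp = rng.uniform(*noise.outlier_amplitude_range)
        margin = min(50.0, 0.25 * (grid.stop_nm - grid.start_nm))
        center = rng.uniform(grid.start_nm + margin, grid.stop_nm - margin)
        width = rng.uniform(30.0, 120.0)
        bump[i] = amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
        bump_params.append((int(i), amp, center, width))
    eps_sd = np.sqrt(sd**2 + (noise.shot_fraction * clean) ** 2)
    eps = eps_sd * rng.standard_normal((n, p))
    absorbance = m[:, None] * clean + baseline + bump + eps

    ref_rng = np.random.default_rng(s_ref)
    ref_noise = conc * (
        noise.reference_rel_sd * ref_rng.standard_normal(conc.shape)
    ) + (noise.reference_abs_frac * conc.mean(axis=0)) * ref_rng.standard_normal(
        conc.shape
    )
    measured = conc + ref_noise

    ids = [f"S{i + 1:03d}" for i in range(n)]
    meta = pd.DataFrame({"batch": batches, "time_min": times}, index=ids)
    spectra = SpectraSet(
        wavelengths=wl, absorbance=absorbance, sample_ids=ids, metadata=meta
    )
    references = ReferenceSet(
        analytes=analytes, concentrations=measured, sample_ids=ids
    )
    truth = {
        "seed": seed,
        "analytes": analytes,
        "bands": {
            a: [(b.center_nm, b.width_nm, b.amplitude) for b in bs]
            for a, bs in bands.items()
        },
        "grid": (grid.start_nm, grid.stop_nm, grid.step_nm),
        "true_concentrations": conc,
        "times_min": times,
        "batches": batches,
        "scatter": m,
        "baseline_offsets": offsets,
        "baseline_slopes": slopes,
        "outlier_events": bump_params,
        "additive_sd": sd,
        "pure_spectra": pure,
        "water_background": water,
    }
    return spectra, references, truth


def default_fixture(
    seed: int = DEFAULT_FIXTURE_SEED,
) -> tuple[SpectraSet, ReferenceSet, dict]:
    """The packaged 75-sample, 2800-variable three-batch fixture.

    Band placement keeps each analyte's informative signal localised to a few
    20ths of the spectrum, so interval selection has a recoverable truth.
    """
    return simulate_dataset(seed=seed)


def interval_recovery_fixture(
    seed: int,
    grid: WavelengthGrid | None = None,
    n_intervals: int = 10,
    informative: tuple[int, ...] = (2, 5, 8),
    n_samples: int = 75,
    noise: NoiseSpec | None = None,
) -> tuple[SpectraSet, np.ndarray, dict]:
    """Reduced-scale fixture with an interval-confined, recoverable truth.

    One synthetic component per informative interval, its Gaussian band
    centred mid-interval and narrow enough (sigma = interval width / 10)
    that its tails fall below the noise floor before the interval boundary. Component
    concentrations are drawn independently (uniform 0.5-2.5 mg/mL) and the
    response is their sum ("total content"), so every informative interval
    carries information the others cannot supply — a combination must cover
    them all to predict well. The standard measurement-artefact model
    applies; the response gets the usual reference-assay noise.

    Returns ``(spectra, y, truth)`` with the latent draws in ``truth``.
    """
    grid = grid or WavelengthGrid(800.0, 1000.0, 1.0)
    # explicit noise floor: the median-absorbance rule degenerates on a
    # reduced grid that excludes the water band
    noise = noise or NoiseSpec(additive_sd=1e-3)
    from .intervals import make_intervals

    iset = make_intervals(grid.n_points, n_intervals)
    wl = grid.wavelengths()
    bands = {}
    for j, i in enumerate(informative):
        lo, hi = iset.bounds[i]
        center = 0.5 * (wl[lo] + wl[hi - 1])
        width = (wl[hi - 1] - wl[lo]) / 10.0
        bands[f"component_{j + 1}"] = (ComponentBand(center, width, 0.08),)
    pure = pure_component_spectra(bands, grid)

    ss = np.random.SeedSequence((seed, 1))
    s_conc, s_noise, s_ref = ss.spawn(3)
    conc = np.random.default_rng(s_conc).uniform(
        0.5, 2.5, size=(n_samples, len(informative))
    )
    water = noise.water_amplitude * np.exp(
        -((wl - noise.water_center_nm) ** 2) / (2.0 * noise.water_width_nm**2)
    )
    clean = conc @ pure + water
    rng = np.random.default_rng(s_noise)
    n, p = clean.shape
    m = rng.uniform(*noise.scatter_range, size=n)
    offsets = rng.uniform(*noise.baseline_offset_range, size=n)
    slopes = rng.uniform(*noise.baseline_slope_range, size=n)
    sd = noise.additive_sd
    if sd is None:
        sd = 0.005 * float(np.median(clean))
    lam_mid = 0.5 * (grid.start_nm + grid.stop_nm)
    baseline = offsets[:, None] + slopes[:, None] * (wl - lam_mid)
    eps = np.sqrt(sd**2 + (noise.shot_fraction * clean) ** 2) * rng.standard_normal(
        (n, p)
    )
    absorbance = m[:, None] * clean + baseline + eps
    y_true = conc.sum(axis=1)
    ref_rng = np.random.default_rng(s_ref)
    y = y_true + y_true * noise.reference_rel_sd * ref_rng.standard_normal(n) + (
        noise.reference_abs_frac * y_true.mean()
    ) * ref_rng.standard_normal(n)
    spectra = SpectraSet(wavelengths=wl, absorbance=absorbance)
    truth = {
        "seed": seed,
        "informative_intervals": tuple(informative),
        "bands": bands,
        "concentrations": conc,
        "y_true": y_true,
        "scatter": m,
        "baseline_offsets": offsets,
        "baseline_slopes": slopes,
        "additive_sd": sd,
    }
    return spectra, y, truth


def informative_intervals(
    bands: Sequence[ComponentBand], grid: WavelengthGrid, n_intervals: int
) -> tuple[int, ...]:
    """Equidistant-interval indices containing the given band centres."""
    from .intervals import make_intervals

    iset = make_intervals(grid.n_points, n_intervals)
    hits = set()
    for band in bands:
        j = grid.index_of(band.center_nm)
        for i, (lo, hi) in enumerate(iset.bounds):
            if lo <= j < hi:
                hits.add(i)
                break
    return tuple(sorted(hits))
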