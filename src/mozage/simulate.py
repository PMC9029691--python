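"""Synthetic mosquito NIRS spectra, SCP1 delta-Ct values and field
populations.

The generator emulates the statistical structure the analysis assumes, not
cuticle optics: a smooth absorbance baseline plus Gaussian absorption bands
whose amplitudes rise with age and saturate (so old mosquitoes become hard
to separate, as real NIRS calibrations find), wrapped in per-scan
multiplicative/additive scatter, a spectral tilt, and heteroscedastic noise
that is larger in the visible region below 700 nm. Field populations follow
constant-daily-survival (geometric) age demography with parity set by
completion of the first gonotrophic cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import SampleMetadata, SpectraSet, Spectrum

__all__ = [
    "SpectraSimParams",
    "PopulationSimParams",
    "UGAL_LAB_DESIGN",
    "UGAL_SEMI_FIELD_DESIGN",
    "TUCSON_DESIGN",
    "MARICOPA_DESIGN",
    "simulate_spectrum",
    "simulate_known_age_cohort",
    "simulate_scp1_dct",
    "simulate_field_population",
]

# Known-age rearing designs (ages in days post-eclosion) used for the four
# calibration treatments.
UGAL_LAB_DESIGN = (1, 3, 6, 9, 11, 14, 18, 20, 25, 27)
UGAL_SEMI_FIELD_DESIGN = (1, 3, 4, 5, 8, 9, 11, 14, 18)
TUCSON_DESIGN = (1, 3, 4, 5, 6, 7, 8, 9, 12, 13, 14, 16, 18)
MARICOPA_DESIGN = (1, 3, 5, 6, 7, 9, 12, 14, 16, 18)

# (center nm, width nm, base amplitude, age gain, saturation tau days):
# overtone-like bands in the NIR with age-dependent gains, plus fixed
# structure so spectra are not pure age signal.
_DEFAULT_BANDS = (
    (1200.0, 45.0, 0.050, 0.012, 6.0),
    (1450.0, 60.0, 0.180, 0.030, 10.0),
    (1720.0, 40.0, 0.060, 0.018, 8.0),
    (1940.0, 70.0, 0.220, 0.025, 14.0),
    (2100.0, 55.0, 0.090, 0.000, 1.0),
    (2310.0, 45.0, 0.070, 0.015, 12.0),
)


@dataclass
class SpectraSimParams:
    """Spectral generator settings.

    ``baseline`` are polynomial coefficients (ascending powers) over the
    normalised wavelength u = (lambda - 350)/2150; band amplitudes follow
    amp(age) = base + gain * (1 - exp(-age / tau)). ``age_jitter_cv`` is the
    log-scale SD of per-mosquito physiological-age jitter (phys_age =
    age * exp(N(0, cv))) applied by the cohort and field simulators —
    individual biological variation that grows with age and caps how well
    any calibration can recover chronological age.
    """

    grid_start: float = 350.0
    grid_stop: float = 2500.0
    grid_step: float = 1.0
    baseline: tuple[float, ...] = (0.35, 0.15, -0.05)
    bands: tuple[tuple[float, float, float, float, float], ...] = _DEFAULT_BANDS
    scatter_mult_sd: float = 0.08
    scatter_add_sd: float = 0.02
    tilt_sd: float = 0.015
    noise_sd: float = 0.0015
    visible_extra_noise_sd: float = 0.02
    age_jitter_cv: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 or tau <= 0 for _, w, _, _, tau in self.bands):
            raise ValueError("band widths and taus must be positive")
        for name in ("scatter_mult_sd", "scatter_add_sd", "tilt_sd", "noise_sd",
                     "visible_extra_noise_sd", "age_jitter_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + self.grid_step / 2, self.grid_step)


@dataclass
class PopulationSimParams:
    """Field-population demography settings.

    Ages are geometric with parameter (1 - daily_survival), truncated at
    ``max_age``; a female is truly parous once her age reaches
    ``first_cycle_age`` plus individual jitter (time to mate, blood feed and
    oviposit), and the observed parity score flips with
    ``parity_error_rate`` (skein reading error).
    """

    n: int = 400
    daily_survival: float = 0.85
    max_age: int = 30
    first_cycle_age: float = 3.0
    first_cycle_jitter_sd: float = 1.0
    parity_error_rate: float = 0.05
    scp1_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.daily_survival < 1:
            raise ValueError("daily_survival must be in (0, 1)")
        if not 0 <= self.parity_error_rate < 1:
            raise ValueError("parity_error_rate must be in [0, 1)")
        if self.n < 1 or self.max_age < 1:
            raise ValueError("n and max_age must be positive")


def clean_signal(age_days: float, params: SpectraSimParams) -> np.ndarray:
    """Noise- and scatter-free absorbance at a given age."""
    wl = params.grid
    u = (wl - 350.0) / 2150.0
    A = np.polyval(params.baseline[::-1], u)
    for center, width, base, gain, tau in params.bands:
        amp = base + gain * (1.0 - np.exp(-age_days / tau))
        A = A + amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    return A


def simulate_spectrum(
    age_days: float, params: SpectraSimParams, rng: np.random.Generator
) -> Spectrum:
    """One measured spectrum: clean signal under scatter, tilt and noise.

    measured = m * A + c + tilt * (lambda - mid)/span + eps(lambda), with
    m = exp(N(0, scatter_mult_sd)), c ~ N(0, scatter_add_sd), and eps
    heteroscedastic (extra variance below 700 nm).
    """
    if age_days < 0:
        raise ValueError("age must be nonnegative")
    wl = params.grid
    A = clean_signal(age_days, params)
    m = np.exp(rng.normal(0.0, params.scatter_mult_sd))
    c = rng.normal(0.0, params.scatter_add_sd)
    tilt = rng.normal(0.0, params.tilt_sd)
    mid = 0.5 * (wl[0] + wl[-1])
    span = wl[-1] - wl[0]
    eps = rng.normal(0.0, params.noise_sd, size=wl.size)
    if params.visible_extra_noise_sd > 0:
        vis = wl < 700.0
        eps[vis] += rng.normal(0.0, params.visible_extra_noise_sd, size=vis.sum())
    measured = m * A + c + tilt * (wl - mid) / span + eps
    return Spectrum("sim", wl, measured)


def _cohort_from_ages(
    nominal_ages: np.ndarray,
    params: SpectraSimParams,
    rng: np.random.Generator,
    id_prefix: str,
    cohort: str,
    parity: Sequence[str] | None = None,
) -> SpectraSet:
    rows, meta = [], []
    phys = nominal_ages * np.exp(rng.normal(0.0, params.age_jitter_cv, size=nominal_ages.size))
    for i, (age, p_age) in enumerate(zip(nominal_ages, phys)):
        spec = simulate_spectrum(p_age, params, rng)
        rows.append(spec.absorbance)
        meta.append(
            SampleMetadata(
                sample_id=f"{id_prefix}{i:04d}",
                age_days=float(age),
                parity="unknown" if parity is None else parity[i],
                cohort=cohort,
            )
        )
    return SpectraSet(params.grid, np.vstack(rows), meta)


def simulate_known_age_cohort(
    design: Sequence[tuple[float, int]],
    params: SpectraSimParams | None = None,
    seed: int | None = None,
    cohort: str = "lab",
) -> SpectraSet:
    """Lab-reared cohort with exact per-age counts (parity unknown).

    ``design`` is a list of (age_days, count) pairs, e.g. the tested-day
    schedule of a calibration treatment.
    """
    if not design:
        raise ValueError("empty design")
    if any(count < 1 for _, count in design):
        raise ValueError("all counts must be >= 1")
    params = params or SpectraSimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    ages = np.concatenate([np.full(int(count), float(age)) for age, count in design])
    return _cohort_from_ages(ages, params, rng, id_prefix=f"{cohort}_", cohort=cohort)


def simulate_scp1_dct(
    age_days: np.ndarray,
    curve: tuple[float, float, float] = (-2.0, 6.0, 12.0),
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Delta-Ct values from a saturating mean curve plus Gaussian noise.

    dCt = intercept + slope * (1 - exp(-age/tau)) + N(0, noise_sd); the
    slope must be positive (expression falls with age, so delta-Ct rises).
    """
    intercept, slope, tau = curve
    if slope <= 0:
        raise ValueError("slope must be positive: SCP1 delta-Ct increases with age")
    ages = np.asarray(age_days, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    mean = intercept + slope * (1.0 - np.exp(-ages / tau))
    if noise_sd == 0:
        return mean
    rng = rng or np.random.default_rng()
    return mean + rng.normal(0.0, noise_sd, size=ages.size)


def parous_age_threshold_tail(params: PopulationSimParams) -> float:
    """Analytic P(parous) under zero jitter/error: geometric tail above the
    first-cycle age, truncated at max_age (used as a closed-form check)."""
    q = params.daily_survival
    k = int(np.ceil(params.first_cycle_age))
    ages = np.arange(1, params.max_age + 1)
    pmf = (1 - q) * q ** (ages - 1)
    pmf /= pmf.sum()
    return float(pmf[ages >= k].sum())


def simulate_field_population(
    params: PopulationSimParams | None = None,
    spectra_params: SpectraSimParams | None = None,
    seed: int | None = None,
    cohort: str = "field",
) -> SpectraSet:
    """Trap-collected population: geometric ages, parity from first-cycle
    completion, delta-Ct attached to parous individuals only (nulliparous
    females are not assayed). Metadata ``age_days`` records the true
    simulated age for validation; real field samples would carry NaN.
    """
    params = params or PopulationSimParams()
    spectra_params = spectra_params or SpectraSimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    # geometric on {1, 2, ...}: trapped females are at least one day old
    ages = rng.geometric(1.0 - params.daily_survival, size=params.n)
    ages = np.minimum(ages, params.max_age).astype(float)

    threshold = params.first_cycle_age + rng.normal(
        0.0, params.first_cycle_jitter_sd, size=params.n
    )
    true_parous = ages >= np.clip(threshold, 0.0, None)
    flips = rng.random(params.n) < params.parity_error_rate
    observed_parous = true_parous ^ flips

    parity = ["parous" if p else "nulliparous" for p in observed_parous]
    pop = _cohort_from_ages(ages, spectra_params, rng, id_prefix=f"{cohort}_", cohort=cohort, parity=parity)

    # qPCR only on (observed) parous individuals, and only for positive ages
    dct = np.full(params.n, np.nan)
    assay = observed_parous & (ages > 0)
    if assay.any():
        dct[assay] = simulate_scp1_dct(
            ages[assay], noise_sd=params.scp1_noise_sd, rng=rng
        )
    meta = [
        SampleMetadata(
            sample_id=m.sample_id,
            age_days=m.age_days,
            parity=m.parity,
            cohort=m.cohort,
            scp1_delta_ct=float(d),
        )
        for m, d in zip(pop.metadata, dct)
    ]
    return SpectraSet(pop.wavelengths_nm, pop.absorbance_matrix, meta)
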