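"""Population-variability prediction and variance comparison.

Three scenario kinds mirror the classic validation settings for an individual
observer model:

* ``cmf_rgb`` -- variability of color matching functions themselves: sampled
  observers' cone fundamentals are transformed to rgb form (normalized at
  three primary wavelengths), evaluated at a set of measurement wavelengths,
  and the SD across observers is averaged over all (wavelength, primary)
  cells.  Mirrors 10-degree trichromatic matching experiments.
* ``color_matches`` -- variability of CIELAB a*/b* across a battery of display
  matches (see :mod:`indivobs.matching`); the scenario SD is the mean of the
  per-match a* and b* SDs.
* ``rayleigh`` -- SD of anomaloscope red-fraction matches at 2 degrees.

Each prediction draws a fresh cohort ``n_repeats`` times (default 100) and
averages the per-repeat SDs to suppress Monte Carlo noise.  Measured samples,
when available to the user, are compared with a two-sample, two-tailed F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .basis import BasisTables
from .matching import (
    RAYLEIGH_GREEN_NM,
    RAYLEIGH_RED_NM,
    RAYLEIGH_YELLOW_NM,
    RGB_PRIMARY_NM,
    MatchSetup,
    lms_to_rgb_batch,
    rayleigh_match_batch,
    simulate_matches,
)
from .model import cone_fundamentals_batch
from .population import AgeSource, SDTable, generate_population, sample_observers
from .spectral import spline_resample_values

__all__ = [
    "ValidationScenario",
    "PredictedSD",
    "FTestResult",
    "predict_population_sd",
    "variance_ratio_test",
    "default_cmf_wavelengths",
    "area_normalize",
]

_KINDS = ("cmf_rgb", "color_matches", "rayleigh")


def default_cmf_wavelengths(n: int = 35) -> np.ndarray:
    """Default CMF measurement wavelengths: ``n`` points equally spaced in
    wavenumber between 392.2 and 714.3 nm (the span of classic 10-degree
    trichromatic matching experiments)."""
    wavenumbers = np.linspace(1e7 / 714.3, 1e7 / 392.2, n)
    return 1e7 / wavenumbers[::-1]


def area_normalize(cmfs: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Normalize each function of a (..., 3, w) CMF stack to unit area."""
    areas = np.trapezoid(np.abs(cmfs), grid, axis=-1)
    return cmfs / areas[..., None]


@dataclass(frozen=True)
class ValidationScenario:
    """One repeated-cohort prediction setting."""

    kind: str
    n_observers: int
    ages: AgeSource
    field_size: float
    setups: tuple[MatchSetup, ...] = ()          # color_matches only
    rayleigh_nm: tuple[float, float, float] = (RAYLEIGH_RED_NM, RAYLEIGH_GREEN_NM,
                                               RAYLEIGH_YELLOW_NM)
    cmf_wavelengths: tuple = tuple(default_cmf_wavelengths())
    rgb_primaries_nm: tuple[float, float, float] = RGB_PRIMARY_NM
    area_normalized: bool = False                # cmf_rgb only; figure-style SDs
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; expected one of {_KINDS}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_observers < 2:
            raise ValueError("n_observers must be >= 2 to form an SD")
        if self.kind == "color_matches" and not self.setups:
            raise ValueError("color_matches scenario requires match setups")
        object.__setattr__(self, "setups", tuple(self.setups))


@dataclass(frozen=True)
class PredictedSD:
    scenario: ValidationScenario
    per_repeat: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repeat))


def _repeat_sd(scenario: ValidationScenario, sds: SDTable, basis: BasisTables,
               seed_seq: np.random.SeedSequence) -> float:
    specs = sample_observers(scenario.n_observers, scenario.ages, scenario.field_size,
                             sds, seed_seq)
    if scenario.kind == "color_matches":
        population = generate_population(specs, basis)
        stats_by_label = simulate_matches(population, list(scenario.setups), basis)
        per = [(s.sd_a, s.sd_b) for s in stats_by_label.values()]
        return float(np.mean(per))
    batch = cone_fundamentals_batch(specs, basis)
    if scenario.kind == "rayleigh":
        red, green, yellow = scenario.rayleigh_nm
        matches = rayleigh_match_batch(batch, basis.grid, red, green, yellow)
        return float(np.std(matches, ddof=1))
    # cmf_rgb
    rgb = lms_to_rgb_batch(batch, basis.grid, scenario.rgb_primaries_nm)
    if scenario.area_normalized:
        rgb = area_normalize(rgb, basis.grid)
    at_wl = spline_resample_values(basis.grid, rgb, np.asarray(scenario.cmf_wavelengths))
    return float(np.mean(np.std(at_wl, axis=0, ddof=1)))


def predict_population_sd(scenario: ValidationScenario, sds: SDTable,
                          basis: BasisTables) -> PredictedSD:
    """Mean predicted SD over ``n_repeats`` independently sampled cohorts."""
    ss = np.random.SeedSequence(scenario.seed)
    repeats = ss.spawn(scenario.n_repeats)
    values = np.array([_repeat_sd(scenario, sds, basis, rep) for rep in repeats])
    return PredictedSD(scenario=scenario, per_repeat=values)


@dataclass(frozen=True)
class FTestResult:
    statistic: float
    p_value: float
    reject: bool
    df: tuple[int, int] = field(default=(0, 0))


def variance_ratio_test(sample_a, sample_b, alpha: float = 0.05) -> FTestResult:
    """Two-sample, two-tailed F-test of equal variances.

    F = var(a)/var(b) with the n-1 convention; the two-tailed p-value doubles
    the smaller tail of the F(n_a - 1, n_b - 1) distribution.
    """
    a = np.asarray(list(sample_a), float)
    b = np.asarray(list(sample_b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 values")
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    if var_b == 0:
        raise ValueError("denominator sample has zero variance")
    f_stat = var_a / var_b
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(f_stat), dist.sf(f_stat))
    p = min(p, 1.0)
    return FTestResult(statistic=f_stat, p_value=float(p), reject=bool(p < alpha),
                       df=(a.size - 1, b.size - 1))
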