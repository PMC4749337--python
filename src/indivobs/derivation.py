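"""Deriving the eight parameter standard deviations.

Two-step procedure:

*Step 1* pools published inter-observer variability estimates.  Each study's
SD (percent of the mean, or nm for peak-wavelength shifts) is converted to a
variance, the variances are averaged without weighting, and the square root of
the average is the pooled SD.  For lens density, where age ranges differ wildly
between studies, subject-level records are first reduced to an age-controlled
SD: sliding +/-5-year windows around integer age centers, SD%% per window,
averaged over all feasible centers.

*Step 2* rescales the pooled SDs to match the variability of a real color
matching experiment: one scalar ``c1`` multiplies the two prereceptoral SDs
(lens, macula), a second scalar ``c2`` multiplies the six photopigment SDs,
and (c1, c2) in [0,1]^2 minimize the city-block distance between measured and
Monte-Carlo-predicted per-match CIELAB a*/b* SDs over a battery of five
matches.  The objective uses common random numbers, so it is deterministic for
a fixed seed and the fit is a well-posed 2-D bounded minimization.

The experimental target data are unpublished; :func:`synthetic_target`
forward-simulates a finite synthetic cohort (default 75 observers, with
intra-observer repeat noise) to stand in for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .basis import BasisTables
from .matching import MatchSetup, simulate_matches
from .model import MAX_SHIFT_NM, ObserverSpec
from .population import (
    PARAM_NAMES,
    AgeSource,
    SDTable,
    generate_population,
    sample_observers,
)

__all__ = [
    "StudySD",
    "LensSubjectRecord",
    "ScalarPair",
    "ScalarFitResult",
    "pool_sds",
    "lens_windowed_sds",
    "apply_scalars",
    "optimize_scalars",
    "synthetic_target",
    "predict_match_sds",
    "load_literature_sds",
    "step1_from_literature",
    "PARAMETERS",
]

#: Canonical parameter order (matches SDTable field order).
PARAMETERS = ("lens", "macula", "density_L", "density_M", "density_S",
              "shift_L", "shift_M", "shift_S")


@dataclass(frozen=True)
class StudySD:
    """One study's inter-observer SD for one physiological parameter."""

    study_label: str
    parameter: str
    sd_value: float  # % for densities, nm for shifts
    year: int | None = None
    method: str = ""
    n_subjects: str = ""

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.sd_value < 0:
            raise ValueError("sd_value must be >= 0")


@dataclass(frozen=True)
class LensSubjectRecord:
    """One subject's lens density measurement in one study."""

    study_label: str
    age: float
    density: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class ScalarPair:
    """The two step-2 scaling factors (prereceptoral, photopigment)."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        for name, v in (("c1", self.c1), ("c2", self.c2)):
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def pool_sds(values) -> float:
    """Pool study SDs: average the variances, then take the square root.

    All studies weighted equally.
    """
    arr = np.asarray(list(values), float)
    if arr.size == 0:
        raise ValueError("cannot pool an empty list of SDs")
    if np.any(arr < 0):
        raise ValueError("SDs must be nonnegative")
    return float(np.sqrt(np.mean(arr**2)))


def lens_windowed_sds(records: list[LensSubjectRecord],
                      window_halfwidth: float = 5.0) -> dict[str, float]:
    """Age-controlled per-study lens SD [%].

    For each study: at every integer age center with >= 2 subjects within
    +/-``window_halfwidth`` years, SD%% = sample SD (n-1) of windowed densities
    divided by the windowed mean, x100; the study SD is the mean over centers.
    """
    by_study: dict[str, list[LensSubjectRecord]] = {}
    for rec in records:
        by_study.setdefault(rec.study_label, []).append(rec)
    out: dict[str, float] = {}
    for study, recs in by_study.items():
        ages = np.array([r.age for r in recs])
        dens = np.array([r.density for r in recs])
        centers = np.arange(int(np.floor(ages.min())), int(np.ceil(ages.max())) + 1)
        sds = []
        for c in centers:
            mask = np.abs(ages - c) <= window_halfwidth
            if mask.sum() >= 2:
                windowed = dens[mask]
                sds.append(np.std(windowed, ddof=1) / windowed.mean() * 100.0)
        if not sds:
            raise ValueError(f"study {study!r}: no age window holds >= 2 subjects")
        out[study] = float(np.mean(sds))
    return out


def load_literature_sds(path: str | Path | None = None) -> list[StudySD]:
    """Published per-study SDs (packaged transcription of the literature survey)."""
    if path is None:
        path = Path(resources.files("indivobs") / "data" / "literature_sds.csv")
    df = pd.read_csv(path, comment="#")
    return [
        StudySD(study_label=row["study"], parameter=row["parameter"],
                sd_value=float(row["sd"]), year=int(row["year"]),
                method=row["method"], n_subjects=str(row["subjects"]))
        for _, row in df.iterrows()
    ]


def step1_from_literature(studies: list[StudySD] | None = None) -> SDTable:
    """Pool the literature SDs parameter by parameter into a step-1 SDTable."""
    if studies is None:
        studies = load_literature_sds()
    pooled = []
    for param in PARAMETERS:
        vals = [s.sd_value for s in studies if s.parameter == param]
        if not vals:
            raise ValueError(f"no literature SDs for parameter {param!r}")
        pooled.append(pool_sds(vals))
    return SDTable.from_array(pooled, stage="step1")


def apply_scalars(step1: SDTable, scalars: ScalarPair) -> SDTable:
    """Scale the prereceptoral SDs by c1 and the photopigment SDs by c2."""
    return step1.scaled(scalars.c1, scalars.c2, stage="step2")


# ---------------------------------------------------------------------------
# Common-random-number Monte Carlo forward predictor


@dataclass(frozen=True)
class _CrnDraws:
    """Frozen randomness shared by every objective evaluation of one fit."""

    ages: np.ndarray       # (n_mc,)
    z: np.ndarray          # (attempts, n_mc, 8) standard normals

    @classmethod
    def make(cls, seed: int | np.random.SeedSequence, n_mc: int, ages: AgeSource,
             attempts: int = 8) -> "_CrnDraws":
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        age_ss, z_ss = ss.spawn(2)
        age_draws = ages.sample(n_mc, np.random.default_rng(age_ss))
        z = np.random.default_rng(z_ss).standard_normal((attempts, n_mc, 8))
        return cls(ages=age_draws, z=z)


_DEV_LOWER = np.array([-100.0] * 5 + [-MAX_SHIFT_NM] * 3)
_DEV_UPPER = np.array([np.inf] * 5 + [MAX_SHIFT_NM] * 3)


def _deviations_from_crn(draws: _CrnDraws, sds: SDTable) -> np.ndarray:
    """(n_mc, 8) deviations from frozen normals; bounded draws pick the first
    valid pre-drawn attempt, so the map (c1, c2) -> deviations is deterministic."""
    sd = sds.as_array()
    vals = draws.z * sd                                # (attempts, n, 8)
    valid = (vals > _DEV_LOWER) & (vals < _DEV_UPPER)
    first = np.argmax(valid, axis=0)                   # (n, 8)
    n = vals.shape[1]
    picked = vals[first, np.arange(n)[:, None], np.arange(8)]
    picked = np.where(valid.any(axis=0), picked, 0.0)  # exhausted attempts -> mean
    return picked


def predict_match_sds(sds: SDTable, setups: list[MatchSetup], basis: BasisTables,
                      draws: _CrnDraws, field_size: float = 6.5) -> np.ndarray:
    """Monte Carlo per-match SDs (mean of a* and b* SDs) under frozen draws."""
    dev = _deviations_from_crn(draws, sds)
    specs = [
        ObserverSpec(age=float(a), field_size=field_size, **dict(zip(PARAM_NAMES, d)))
        for a, d in zip(draws.ages, dev)
    ]
    population = generate_population(specs, basis)
    stats = simulate_matches(population, setups, basis)
    return np.array([stats[st.label].sd for st in setups])


@dataclass(frozen=True)
class ScalarFitResult:
    scalars: ScalarPair
    objective: float
    n_evaluations: int
    trace: tuple  # ((c1, c2, objective), ...) in evaluation order


def optimize_scalars(step1: SDTable, target_sds, setups: list[MatchSetup],
                     ages: AgeSource, basis: BasisTables, field_size: float = 6.5,
                     n_mc: int = 10_000, seed: int | np.random.SeedSequence = 0,
                     metric: str = "cityblock", coarse_step: float = 0.2,
                     max_evaluations: int = 250) -> ScalarFitResult:
    """Fit the two step-2 scalars to per-match target SDs.

    Bounded derivative-free search on [0,1]^2: a coarse grid scan followed by
    Nelder-Mead polishing with inputs clipped to the box.  Every objective
    evaluation reuses the same Monte Carlo draws (common random numbers), so
    the objective is deterministic and the minimum well-defined at finite n_mc.
    ``metric`` is ``cityblock`` (sum of absolute SD differences) or
    ``euclidean``.
    """
    target = np.asarray(list(target_sds), float)
    if target.shape != (len(setups),):
        raise ValueError(f"need one target SD per setup ({len(setups)}), got {target.shape}")
    if np.any(target < 0):
        raise ValueError("target SDs must be nonnegative")
    if metric not in ("cityblock", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")

    draws = _CrnDraws.make(seed, n_mc, ages)
    trace: list[tuple[float, float, float]] = []

    def objective(x: np.ndarray) -> float:
        c1, c2 = np.clip(x, 0.0, 1.0)
        if len(trace) >= max_evaluations:
            raise _EvaluationBudgetExceeded
        predicted = predict_match_sds(step1.scaled(c1, c2), setups, basis, draws, field_size)
        diff = predicted - target
        val = float(np.abs(diff).sum()) if metric == "cityblock" else float(np.linalg.norm(diff))
        trace.append((float(c1), float(c2), val))
        return val

    grid = np.arange(0.0, 1.0 + 1e-9, coarse_step)
    try:
        best_x, best_f = None, np.inf
        for c1 in grid:
            for c2 in grid:
                f = objective(np.array([c1, c2]))
                if f < best_f:
                    best_x, best_f = np.array([c1, c2]), f
        h = coarse_step / 2.0
        simplex = np.clip(np.array([best_x, best_x + [h, 0.0], best_x + [0.0, h]]), 0.0, 1.0)
        res = minimize(objective, best_x, method="Nelder-Mead",
                       options={"initial_simplex": simplex, "xatol": 1e-3,
                                "fatol": 3e-3, "maxfev": max_evaluations - len(trace)})
    except _EvaluationBudgetExceeded:
        raise RuntimeError(
            f"scalar fit did not converge within {max_evaluations} objective evaluations; "
            f"best so far (c1, c2, objective) = {min(trace, key=lambda t: t[2])}; "
            f"trace has {len(trace)} entries"
        ) from None
    if not res.success:
        raise RuntimeError(
            f"scalar fit did not converge: {res.message}; best so far "
            f"(c1, c2, objective) = {min(trace, key=lambda t: t[2])}; "
            f"trace has {len(trace)} entries"
        )
    x = np.clip(res.x, 0.0, 1.0)
    f = float(res.fun)
    if best_f < f:
        x, f = best_x, best_f
    return ScalarFitResult(scalars=ScalarPair(float(x[0]), float(x[1])), objective=f,
                           n_evaluations=len(trace), trace=tuple(trace))


class _EvaluationBudgetExceeded(Exception):
    pass


def synthetic_target(setups: list[MatchSetup], ages: AgeSource, sds: SDTable,
                     basis: BasisTables, n_observers: int = 75,
                     seed: int | np.random.SeedSequence = 0,
                     field_size: float = 6.5, noise_sd: float = 1.4) -> np.ndarray:
    """Per-match SDs of a finite synthetic cohort (stand-in for measured data).

    Forward-simulates ``n_observers`` observers on the match battery and adds
    zero-mean Gaussian intra-observer noise (default SD 1.4 CIELAB units, the
    magnitude of typical repeat variability) to each observer's a* and b*
    before taking SDs.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sample_ss, noise_ss = ss.spawn(2)
    specs = sample_observers(n_observers, ages, field_size, sds, sample_ss)
    population = generate_population(specs, basis)
    stats = simulate_matches(population, setups, basis)
    rng = np.random.default_rng(noise_ss)
    out = []
    for st in setups:
        ab = stats[st.label].lab[:, 1:3].copy()
        if noise_sd > 0:
            ab += rng.normal(0.0, noise_sd, size=ab.shape)
        ddof = 1 if n_observers > 1 else 0
        out.append(0.5 * (np.std(ab[:, 0], ddof=ddof) + np.std(ab[:, 1], ddof=ddof)))
    return np.array(out)
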