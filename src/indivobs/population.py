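"""Monte Carlo observer populations.

Each of the eight physiological deviation parameters is drawn independently
from a zero-mean normal with the standard deviation given by an
:class:`SDTable`; ages come from an :class:`AgeSource` (an explicit list or a
uniform range).  Draws that would violate the physical bounds of
:class:`~indivobs.model.ObserverSpec` (a percentage deviation <= -100, or a
peak shift beyond +/-30 nm) are rejected and redrawn, so the realized
distributions are truncated normals; at the model's default SDs the bounds sit
beyond 2.7 sigma for every parameter and the truncation is negligible except
for a ~1% SD reduction of the macular parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .basis import BasisTables
from .model import MAX_SHIFT_NM, ConeFundamentals, ObserverSpec, cone_fundamentals_batch

__all__ = [
    "SDTable",
    "AgeSource",
    "sample_observers",
    "sample_deviations",
    "generate_population",
    "truncated_sd",
    "STEP1_PUBLISHED",
    "STEP2_PUBLISHED",
]

PARAM_NAMES = ("d_lens", "d_macula", "d_L", "d_M", "d_S", "s_L", "s_M", "s_S")

#: Step-1 (literature-pooled) standard deviations: percentages for the five
#: density parameters, nm for the three peak-wavelength shifts.
STEP1_PUBLISHED = (19.1, 37.2, 17.9, 17.9, 14.7, 4.0, 3.0, 2.5)
#: Step-2 (scaled to color-matching data) standard deviations; model defaults.
STEP2_PUBLISHED = (18.7, 36.5, 9.0, 9.0, 7.4, 2.0, 1.5, 1.3)


@dataclass(frozen=True)
class SDTable:
    """Standard deviations of the eight deviation parameters.

    ``sd_lens``/``sd_macula``/``sd_dL``/``sd_dM``/``sd_dS`` are percentages,
    ``sd_sL``/``sd_sM``/``sd_sS`` are nm.  ``stage`` records provenance.
    """

    sd_lens: float
    sd_macula: float
    sd_dL: float
    sd_dM: float
    sd_dS: float
    sd_sL: float
    sd_sM: float
    sd_sS: float
    stage: str = "custom"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_array()):
            raise ValueError("standard deviations must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.sd_lens, self.sd_macula, self.sd_dL, self.sd_dM,
                         self.sd_dS, self.sd_sL, self.sd_sM, self.sd_sS])

    @classmethod
    def from_array(cls, values: Sequence[float], stage: str = "custom") -> "SDTable":
        values = list(values)
        if len(values) != 8:
            raise ValueError(f"need 8 SDs, got {len(values)}")
        return cls(*values, stage=stage)

    @classmethod
    def step1(cls) -> "SDTable":
        return cls.from_array(STEP1_PUBLISHED, stage="step1")

    @classmethod
    def step2(cls) -> "SDTable":
        """The model's default variabilities (step-2 scaled)."""
        return cls.from_array(STEP2_PUBLISHED, stage="step2")

    def scaled(self, prereceptoral: float, photopigment: float, stage: str = "custom") -> "SDTable":
        arr = self.as_array()
        arr[:2] *= prereceptoral
        arr[2:] *= photopigment
        return SDTable.from_array(arr, stage=stage)


@dataclass(frozen=True)
class AgeSource:
    """Observer ages: an explicit list, or a uniform range sampler.

    With an explicit list: n == len(list) uses the list as given; n < len draws
    a subset without replacement; n > len samples with replacement.
    """

    ages: tuple | None = None
    uniform: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.ages is None) == (self.uniform is None):
            raise ValueError("provide exactly one of an age list or a uniform range")
        if self.ages is not None:
            ages = tuple(float(a) for a in self.ages)
            if not ages or any(a <= 0 for a in ages):
                raise ValueError("ages must be a non-empty list of positive values")
            object.__setattr__(self, "ages", ages)
        else:
            lo, hi = self.uniform
            if not (0 < lo <= hi):
                raise ValueError(f"invalid uniform age range ({lo}, {hi})")

    @classmethod
    def from_list(cls, ages) -> "AgeSource":
        return cls(ages=tuple(ages))

    @classmethod
    def from_uniform(cls, lo: float, hi: float) -> "AgeSource":
        return cls(uniform=(float(lo), float(hi)))

    @classmethod
    def fixed(cls, age: float) -> "AgeSource":
        return cls(ages=(float(age),))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.ages is not None:
            pool = np.asarray(self.ages)
            if n == pool.size:
                return pool.copy()
            replace_draws = n > pool.size
            return rng.choice(pool, size=n, replace=replace_draws)
        lo, hi = self.uniform
        return rng.uniform(lo, hi, size=n)


# Physical lower/upper bounds enforced by rejection, per parameter.
_LOWER = np.array([-100.0] * 5 + [-MAX_SHIFT_NM] * 3)
_UPPER = np.array([np.inf] * 5 + [MAX_SHIFT_NM] * 3)


def truncated_sd(sd: float, lower: float, upper: float = np.inf) -> float:
    """SD of a Normal(0, sd) truncated to (lower, upper) by rejection."""
    if sd == 0:
        return 0.0
    return float(sd * truncnorm.std(lower / sd, upper / sd))


def _draw_column(rng: np.random.Generator, sd: float, lower: float, upper: float,
                 n: int) -> tuple[np.ndarray, int]:
    """n rejection-resampled Normal(0, sd) draws restricted to (lower, upper)."""
    if sd == 0:
        return np.zeros(n), 0
    col = rng.normal(0.0, sd, size=n)
    rejected = 0
    bad = (col <= lower) | (col >= upper)
    while np.any(bad):
        rejected += int(bad.sum())
        col[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = (col <= lower) | (col >= upper)
    return col, rejected


def sample_deviations(n: int, sds: SDTable,
                      rngs: Sequence[np.random.Generator]) -> tuple[np.ndarray, int]:
    """(n, 8) deviation draws with physical-bound rejection, one stream per column.

    Dedicated per-parameter streams keep one parameter's draws independent of
    how many rejections another parameter needed.
    """
    sd_arr = sds.as_array()
    out = np.empty((n, 8))
    rejected = 0
    for j in range(8):
        out[:, j], rej = _draw_column(rngs[j], sd_arr[j], _LOWER[j], _UPPER[j], n)
        rejected += rej
    return out, rejected


def sample_observers(n: int, ages: AgeSource, field_size: float, sds: SDTable,
                     seed: int | np.random.SeedSequence) -> list[ObserverSpec]:
    """Draw ``n`` observers: ages from ``ages``, deviations from ``sds``.

    A single seed governs a hierarchical stream (ages first, then one stream
    per deviation parameter), so draws are reproducible bit-for-bit.
    """
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    age_ss, *param_ss = ss.spawn(9)
    age_draws = ages.sample(n, np.random.default_rng(age_ss))
    dev, rejected = sample_deviations(n, sds, [np.random.default_rng(s) for s in param_ss])
    if rejected > 0.01 * n * 8:
        warnings.warn(
            f"rejection rate {rejected / (n * 8):.2%} exceeds 1%; "
            "the supplied SDs push parameters against their physical bounds",
            stacklevel=2,
        )
    return [
        ObserverSpec(age=float(age_draws[i]), field_size=field_size,
                     **dict(zip(PARAM_NAMES, dev[i])))
        for i in range(n)
    ]


def generate_population(specs: list[ObserverSpec], basis: BasisTables) -> list[ConeFundamentals]:
    """One set of cone fundamentals per observer, order-preserving."""
    if not specs:
        raise ValueError("specs must be non-empty")
    try:
        batch = cone_fundamentals_batch(specs, basis)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"cone fundamental generation failed for a batch of "
                           f"{len(specs)} observers: {exc}") from exc
    return [
        ConeFundamentals(grid=basis.grid, l=batch[i, 0], m=batch[i, 1], s=batch[i, 2],
                         spec=specs[i], basis_version=basis.version)
        for i in range(len(specs))
    ]
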