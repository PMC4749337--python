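"""Individual cone fundamentals from ten physiological input parameters.

The model extends the CIE 2006 physiological observer (age and field size in)
with eight inter-observer deviation parameters: percentage deviations of lens
density, peak macular pigment density and the three photopigment peak optical
densities, plus nanometre shifts of the three photopigment peak wavelengths.
With all eight deviations at zero it reduces exactly to the average observer
computed from the same basis tables.

Pipeline for one observer:

1. ocular media density  D_ocul(lambda)  -- age-scaled lens component plus the
   stable component, scaled by (1 + d_lens/100);
2. macular density       D_mac(lambda)   -- field-size-dependent peak times the
   relative density table, scaled by (1 + d_macula/100);
3. cone absorptances     alpha_j(lambda) = 1 - 10^(-D_max,j * A_j(lambda - s_j))
   with field-size-dependent peak densities scaled by (1 + d_j/100);
4. quantal fundamentals  alpha_j * 10^(-D_mac - D_ocul); energy fundamentals by
   multiplying with lambda; finally each function is scaled to unit maximum.

All computation is on the basis tables' native 5 nm grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .basis import BasisTables
from .spectral import SpectralFunction, spline_resample_values

__all__ = [
    "ObserverSpec",
    "ConeFundamentals",
    "ocular_media_density",
    "macular_peak_density",
    "macular_density_spectrum",
    "photopigment_peak_density",
    "cone_absorptance",
    "cone_fundamentals",
    "cone_fundamentals_batch",
]

MAX_SHIFT_NM = 30.0
CONES = ("L", "M", "S")


@dataclass(frozen=True)
class ObserverSpec:
    """The ten inputs of the individual observer model.

    Percentage deviations are relative to the population average (0 = average
    observer); shifts are in nm.  A deviation of -100% would null the
    corresponding optical density, so values <= -100 are rejected.
    """

    age: float
    field_size: float
    d_lens: float = 0.0
    d_macula: float = 0.0
    d_L: float = 0.0
    d_M: float = 0.0
    d_S: float = 0.0
    s_L: float = 0.0
    s_M: float = 0.0
    s_S: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.age, self.field_size, self.d_lens, self.d_macula,
                self.d_L, self.d_M, self.d_S, self.s_L, self.s_M, self.s_S)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("ObserverSpec fields must be finite")
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not (0 < self.field_size <= 10):
            raise ValueError(f"field size must be in (0, 10] degrees, got {self.field_size}")
        for name in ("d_lens", "d_macula", "d_L", "d_M", "d_S"):
            if getattr(self, name) <= -100:
                raise ValueError(f"{name} must exceed -100% (negative optical density)")
        for name in ("s_L", "s_M", "s_S"):
            if abs(getattr(self, name)) > MAX_SHIFT_NM:
                raise ValueError(f"|{name}| must be <= {MAX_SHIFT_NM} nm")

    def deviations(self) -> np.ndarray:
        return np.array([self.d_lens, self.d_macula, self.d_L, self.d_M, self.d_S,
                         self.s_L, self.s_M, self.s_S])

    def density_deviation(self, cone: str) -> float:
        return {"L": self.d_L, "M": self.d_M, "S": self.d_S}[cone]

    def shift(self, cone: str) -> float:
        return {"L": self.s_L, "M": self.s_M, "S": self.s_S}[cone]


@dataclass(frozen=True)
class ConeFundamentals:
    """Unit-peak L/M/S spectral sensitivities (energy basis) for one observer."""

    grid: np.ndarray
    l: np.ndarray
    m: np.ndarray
    s: np.ndarray
    spec: ObserverSpec | None = None
    basis_version: str = ""

    def as_matrix(self) -> np.ndarray:
        """(3, n) matrix in L, M, S row order."""
        return np.vstack([self.l, self.m, self.s])

    def on_grid(self, grid_nm: np.ndarray) -> np.ndarray:
        """Spline-resampled (3, n) sensitivities; zero outside the model span."""
        out = spline_resample_values(self.grid, self.as_matrix(), np.asarray(grid_nm, float))
        return np.clip(out, 0.0, None)


def _aging_factor(age: float) -> float:
    # Piecewise-linear lens aging; the two branches agree exactly at age 60.
    if age <= 60:
        return 1.0 + 0.02 * (age - 32.0)
    return 1.56 + 0.0667 * (age - 60.0)


def ocular_media_density(age: float, d_lens: float, basis: BasisTables) -> SpectralFunction:
    """Spectral optical density of lens and other ocular media.

    The average density is ``docul1 * aging_factor(age) + docul2``; the whole
    average is then scaled by ``(1 + d_lens/100)``.
    """
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    avg = basis.docul1 * _aging_factor(age) + basis.docul2
    return SpectralFunction(basis.grid, avg * (1.0 + d_lens / 100.0), name="D_ocul")


def macular_peak_density(field_size: float, d_macula: float) -> float:
    """Peak macular pigment optical density at a given field size [deg]."""
    if field_size <= 0:
        raise ValueError(f"field size must be positive, got {field_size}")
    return 0.485 * math.exp(-field_size / 6.132) * (1.0 + d_macula / 100.0)


def macular_density_spectrum(field_size: float, d_macula: float, basis: BasisTables) -> SpectralFunction:
    peak = macular_peak_density(field_size, d_macula)
    return SpectralFunction(basis.grid, peak * basis.d_rel_macula, name="D_macula")


_PHOTOPIG_CONSTANTS = {"L": (0.38, 0.54), "M": (0.38, 0.54), "S": (0.30, 0.45)}


def photopigment_peak_density(cone: str, field_size: float, d_j: float) -> float:
    """Peak photopigment optical density; L and M share the same formula."""
    if field_size <= 0:
        raise ValueError(f"field size must be positive, got {field_size}")
    base, amp = _PHOTOPIG_CONSTANTS[cone]
    return (base + amp * math.exp(-field_size / 1.333)) * (1.0 + d_j / 100.0)


def _shifted_absorbance(cone: str, s_j, basis: BasisTables) -> np.ndarray:
    """A_j(lambda - s_j) on the model grid by spline evaluation, zero-filled.

    ``s_j`` may be a scalar or a 1-D array of shifts (batched observers).
    """
    s = np.asarray(s_j, float)
    query = basis.grid - s[..., None] if s.ndim else basis.grid - s
    spline = basis.absorbance_spline(cone)
    vals = spline(query)
    inside = (query >= basis.grid[0] - 1e-9) & (query <= basis.grid[-1] + 1e-9)
    return np.clip(np.where(inside, vals, 0.0), 0.0, None)


def cone_absorptance(cone: str, field_size: float, d_j: float, s_j: float,
                     basis: BasisTables) -> SpectralFunction:
    """Cone absorptance 1 - 10^(-D_max * A(lambda - s)); values in [0, 1)."""
    if abs(s_j) > MAX_SHIFT_NM:
        raise ValueError(f"|s_{cone}| must be <= {MAX_SHIFT_NM} nm, got {s_j}")
    d_max = photopigment_peak_density(cone, field_size, d_j)
    a_shift = _shifted_absorbance(cone, s_j, basis)
    return SpectralFunction(basis.grid, 1.0 - 10.0 ** (-d_max * a_shift), name=f"alpha_{cone}")


def cone_fundamentals(spec: ObserverSpec, basis: BasisTables,
                      normalize: bool = True) -> ConeFundamentals:
    """Cone fundamentals for one observer.

    Quantal sensitivities ``alpha_j * 10^(-D_mac - D_ocul)`` are converted to
    the energy basis by multiplying with wavelength; with ``normalize`` each
    function is finally scaled to unit maximum.
    """
    d_ocul = ocular_media_density(spec.age, spec.d_lens, basis).values
    d_mac = macular_density_spectrum(spec.field_size, spec.d_macula, basis).values
    prereceptoral = 10.0 ** (-(d_mac + d_ocul))
    out = {}
    for cone in CONES:
        alpha = cone_absorptance(cone, spec.field_size, spec.density_deviation(cone),
                                 spec.shift(cone), basis).values
        energy = basis.grid * (alpha * prereceptoral)
        if normalize:
            energy = energy / energy.max()
        out[cone] = energy
    return ConeFundamentals(grid=basis.grid, l=out["L"], m=out["M"], s=out["S"],
                            spec=spec, basis_version=basis.version)


def cone_fundamentals_batch(specs: list[ObserverSpec], basis: BasisTables) -> np.ndarray:
    """Vectorized fundamentals for many observers: (n, 3, n_wavelengths).

    Identical to stacking :func:`cone_fundamentals` outputs; used by the Monte
    Carlo population and match-simulation paths where thousands of observers
    are generated per objective evaluation.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    n = len(specs)
    grid = basis.grid
    ages = np.array([sp.age for sp in specs])
    fields = np.array([sp.field_size for sp in specs])
    aging = np.where(ages <= 60, 1.0 + 0.02 * (ages - 32.0), 1.56 + 0.0667 * (ages - 60.0))
    d_lens = np.array([sp.d_lens for sp in specs])
    d_mac = np.array([sp.d_macula for sp in specs])
    d_ocul = (aging[:, None] * basis.docul1 + basis.docul2) * (1 + d_lens / 100.0)[:, None]
    peak_mac = 0.485 * np.exp(-fields / 6.132) * (1 + d_mac / 100.0)
    d_macula = peak_mac[:, None] * basis.d_rel_macula
    prereceptoral = 10.0 ** (-(d_macula + d_ocul))

    out = np.empty((n, 3, grid.size))
    for ci, cone in enumerate(CONES):
        base, amp = _PHOTOPIG_CONSTANTS[cone]
        d_j = np.array([sp.density_deviation(cone) for sp in specs])
        s_j = np.array([sp.shift(cone) for sp in specs])
        d_max = (base + amp * np.exp(-fields / 1.333)) * (1 + d_j / 100.0)
        a_shift = _shifted_absorbance(cone, s_j, basis)
        alpha = 1.0 - 10.0 ** (-d_max[:, None] * a_shift)
        energy = grid * (alpha * prereceptoral)
        out[:, ci, :] = energy / energy.max(axis=1, keepdims=True)
    return out
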