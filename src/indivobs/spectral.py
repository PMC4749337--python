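"""Spectral function container and resampling utilities.

Every tabulated quantity in the model -- ocular-media densities, macular
density, photopigment absorbances, cone fundamentals, stimulus spectra and
color matching functions -- is a set of values on a wavelength grid.  This
module provides the shared container and the natural-cubic-spline resampler
used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "MODEL_GRID_NM",
    "STIMULUS_GRID_NM",
    "SpectralFunction",
    "resample_spectral",
    "spline_resample_values",
]

#: Native grid of the physiological basis tables: 390-830 nm at 5 nm (89 points).
MODEL_GRID_NM = np.arange(390.0, 830.0 + 1e-9, 5.0)

#: Stimulus convention for color-match simulation: 380-780 nm at 1 nm (401 points).
STIMULUS_GRID_NM = np.arange(380.0, 780.0 + 1e-9, 1.0)


@dataclass(frozen=True)
class SpectralFunction:
    """Values sampled on a strictly increasing wavelength grid [nm]."""

    wavelengths: np.ndarray
    values: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError(f"{self.name or 'spectral function'}: need >= 2 wavelengths")
        if vals.shape != wl.shape:
            raise ValueError(
                f"{self.name or 'spectral function'}: values shape {vals.shape} "
                f"!= grid shape {wl.shape}"
            )
        if not np.all(np.diff(wl) > 0):
            raise ValueError(f"{self.name or 'spectral function'}: grid not strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise ValueError(f"{self.name or 'spectral function'}: non-finite entries")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        d = np.diff(self.wavelengths)
        return bool(np.allclose(d, d[0], rtol=rtol))

    def at(self, wavelengths_nm) -> np.ndarray:
        """Natural-cubic-spline evaluation; zero outside the tabulated span."""
        return spline_resample_values(self.wavelengths, self.values, np.asarray(wavelengths_nm, float))


def spline_resample_values(
    source_wl: np.ndarray, source_values: np.ndarray, target_wl: np.ndarray
) -> np.ndarray:
    """Natural cubic spline of ``source_values`` evaluated at ``target_wl``.

    Values are zero-filled outside the source span: extrapolating steep
    prereceptoral densities or pigment flanks is unsafe, and the model treats
    sensitivities as zero beyond tabulation.  ``source_values`` may have any
    leading batch shape; the last axis must match ``source_wl``.
    """
    source_wl = np.asarray(source_wl, float)
    target_wl = np.asarray(target_wl, float)
    if target_wl.size == 0:
        raise ValueError("empty target wavelength grid")
    spline = CubicSpline(source_wl, source_values, axis=-1, bc_type="natural")
    out = spline(target_wl)
    inside = (target_wl >= source_wl[0] - 1e-9) & (target_wl <= source_wl[-1] + 1e-9)
    out = np.where(inside, out, 0.0)
    return out


def resample_spectral(fn: SpectralFunction, target_grid, method: str = "spline") -> SpectralFunction:
    """Resample a spectral function onto ``target_grid`` (nm).

    Natural cubic spline; values at source knots are reproduced exactly and
    values outside the source span are 0.
    """
    if method != "spline":
        raise ValueError(f"unknown resampling method {method!r}")
    target_grid = np.asarray(target_grid, dtype=float)
    values = spline_resample_values(fn.wavelengths, fn.values, target_grid)
    return SpectralFunction(target_grid, values, name=fn.name)
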