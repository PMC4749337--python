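"""Trichromatic color-match simulation.

For an observer with cone sensitivities ``C`` (3 x n matrix on the stimulus
grid), a match between a reference spectrum ``S_ref`` and three matching
primaries at maximum energy ``S_max`` (n x 3) is the intensity triple ``R``
solving ``C S_ref = C S_max R`` -- an exact 3x3 linear solve, with negative
components permitted.  The matched spectrum ``S_max R`` is then expressed in
CIELAB under the CIE 1964 standard observer (matches from different individual
observers live in one common color space, as in anomaloscope or display
matching experiments), against a per-match reference white whose intensity is
set so the reference stimulus has L* = 50.

The module also provides Rayleigh-match simulation (red+green mixture matched
to spectral yellow through the L and M cones only) and the lms -> rgb linear
transform normalized at three primary wavelengths that is used to compare
simulated populations with classic 10-degree color-matching experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .basis import BasisTables
from .model import ConeFundamentals
from .spectral import SpectralFunction, spline_resample_values

__all__ = [
    "MatchSetup",
    "MatchResult",
    "MatchStats",
    "SingularMatchError",
    "xyz_to_lab",
    "reference_white",
    "solve_match",
    "match_to_cielab",
    "simulate_matches",
    "observer_matrix",
    "rayleigh_match",
    "rayleigh_match_batch",
    "lms_to_rgb",
    "lms_to_rgb_batch",
    "RAYLEIGH_RED_NM",
    "RAYLEIGH_GREEN_NM",
    "RAYLEIGH_YELLOW_NM",
    "RGB_PRIMARY_NM",
]

logger = logging.getLogger(__name__)

#: Luminous efficacy constant for tristimulus integration [lm/W].
KM = 683.0

#: Anomaloscope primary/test wavelengths [nm].
RAYLEIGH_RED_NM = 700.0
RAYLEIGH_GREEN_NM = 550.0
RAYLEIGH_YELLOW_NM = 589.0

#: Normalization wavelengths [nm] of the rgb transform (red, green, blue).
RGB_PRIMARY_NM = (645.2, 526.3, 444.4)

_COND_LIMIT = 1e10
_LSTAR_TARGET = 50.0


class SingularMatchError(RuntimeError):
    """The primary matrix is (near-)singular for the matching observer."""


@dataclass(frozen=True)
class MatchSetup:
    """One color match: reference stimulus, three primaries, white rule."""

    reference: SpectralFunction
    primaries_max: np.ndarray  # (n_wavelengths, 3), maximum-energy primary spectra
    white_rule: str = "reference-shape"
    label: str = ""

    def __post_init__(self) -> None:
        prim = np.asarray(self.primaries_max, float)
        n = self.reference.wavelengths.size
        if prim.shape != (n, 3):
            raise ValueError(f"{self.label}: primaries must be ({n}, 3), got {prim.shape}")
        if np.any(prim < 0) or np.any(self.reference.values < 0):
            raise ValueError(f"{self.label}: spectra must be nonnegative")
        if self.white_rule not in ("reference-shape", "equal-energy"):
            raise ValueError(f"{self.label}: unknown white rule {self.white_rule!r}")
        object.__setattr__(self, "primaries_max", prim)

    @property
    def grid(self) -> np.ndarray:
        return self.reference.wavelengths


@dataclass(frozen=True)
class MatchResult:
    """Solved match for one observer."""

    R: np.ndarray                     # (3,) primary intensities
    matched_spectrum: SpectralFunction
    tristimulus: np.ndarray           # (3,) XYZ of the matched spectrum
    lab: np.ndarray                   # (3,) L*, a*, b*
    white_tristimulus: np.ndarray     # (3,) XYZ of the reference white


@dataclass(frozen=True)
class MatchStats:
    """Population statistics for one match setup."""

    label: str
    lab: np.ndarray   # (n_observers, 3)
    sd_a: float
    sd_b: float

    @property
    def sd(self) -> float:
        """Setup-level variability: mean of the a* and b* SDs."""
        return 0.5 * (self.sd_a + self.sd_b)


def xyz_to_lab(xyz: np.ndarray, white: np.ndarray) -> np.ndarray:
    """CIELAB from tristimulus values; standard cube-root/linear-toe function.

    ``xyz`` may have any leading batch shape with XYZ on the last axis.
    """
    white = np.asarray(white, float)
    if white[1] <= 0:
        raise ValueError("reference white must have positive Y")
    t = np.asarray(xyz, float) / white
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def tristimulus(spectrum: np.ndarray, cmfs_on_grid: np.ndarray) -> np.ndarray:
    """XYZ = KM * CMF . spectrum (unit wavelength step absorbed in the scale)."""
    return KM * cmfs_on_grid @ np.asarray(spectrum, float)


def reference_white(setup: MatchSetup, basis: BasisTables) -> tuple[SpectralFunction, np.ndarray]:
    """Reference-white spectrum and tristimulus for a match setup.

    The white shares the reference's spectral shape (neutral matches) or is
    equal-energy (saturated matches), with its intensity set so the reference
    stimulus comes out at L* = 50 under the CIE 1964 observer, i.e.
    Y_ref / Y_n = ((50 + 16) / 116)^3.
    """
    if not np.any(setup.reference.values > 0):
        raise ValueError(f"{setup.label}: reference spectrum is identically zero")
    cmfs = basis.cie1964_on(setup.grid)
    y_ref = float(tristimulus(setup.reference.values, cmfs)[1])
    if y_ref <= 0:
        raise ValueError(f"{setup.label}: reference has nonpositive luminance")
    y_n_target = y_ref / ((_LSTAR_TARGET + 16.0) / 116.0) ** 3
    shape = setup.reference.values if setup.white_rule == "reference-shape" else np.ones_like(setup.grid)
    y_shape = float(tristimulus(shape, cmfs)[1])
    white_values = shape * (y_n_target / y_shape)
    t_n = tristimulus(white_values, cmfs)
    return SpectralFunction(setup.grid, white_values, name=f"{setup.label}-white"), t_n


def _as_cmf_matrix(cmfs, grid: np.ndarray) -> np.ndarray:
    if isinstance(cmfs, ConeFundamentals):
        return cmfs.on_grid(grid)
    mat = np.asarray(cmfs, float)
    if mat.shape != (3, grid.size):
        raise ValueError(f"observer CMFs must be (3, {grid.size}), got {mat.shape}")
    return mat


def solve_match(cmfs, setup: MatchSetup) -> np.ndarray:
    """Primary intensities R solving C S_ref = C S_max R for observer ``cmfs``."""
    C = _as_cmf_matrix(cmfs, setup.grid)
    A = C @ setup.primaries_max
    if np.linalg.cond(A) > _COND_LIMIT:
        raise SingularMatchError(
            f"match {setup.label!r}: primary matrix is near-singular for this observer"
        )
    R = np.linalg.solve(A, C @ setup.reference.values)
    if np.any(R < 0):
        logger.debug("match %r: negative primary intensity %s", setup.label, R)
    return R


def match_to_cielab(R: np.ndarray, setup: MatchSetup, white: np.ndarray,
                    basis: BasisTables) -> MatchResult:
    """Reconstruct the matched spectrum and express it in CIELAB.

    The CIE 1964 observer -- not the matching observer -- integrates the
    matched spectrum, so matches of different individuals share a color space.
    """
    R = np.asarray(R, float)
    matched = setup.primaries_max @ R
    cmfs = basis.cie1964_on(setup.grid)
    t_matched = tristimulus(matched, cmfs)
    lab = xyz_to_lab(t_matched, white)
    return MatchResult(
        R=R,
        matched_spectrum=SpectralFunction(setup.grid, matched, name=f"{setup.label}-matched"),
        tristimulus=t_matched,
        lab=lab,
        white_tristimulus=np.asarray(white, float),
    )


def observer_matrix(population: list[ConeFundamentals], grid: np.ndarray) -> np.ndarray:
    """(n_observers, 3, n_wavelengths) sensitivities resampled to ``grid``."""
    if not population:
        raise ValueError("population must be non-empty")
    model_grid = population[0].grid
    stack = np.stack([cf.as_matrix() for cf in population])
    out = spline_resample_values(model_grid, stack, np.asarray(grid, float))
    return np.clip(out, 0.0, None)


def simulate_matches(population: list[ConeFundamentals], setups: list[MatchSetup],
                     basis: BasisTables) -> dict[str, MatchStats]:
    """Solve every setup for every observer; per-setup CIELAB and a*/b* SDs.

    SDs use the n-1 convention.  Any near-singular setup aborts with a
    :class:`SingularMatchError` naming the setup.
    """
    if not population or not setups:
        raise ValueError("population and setups must be non-empty")
    grid = setups[0].grid
    for st in setups:
        if st.grid.shape != grid.shape or not np.allclose(st.grid, grid):
            raise ValueError(f"setup {st.label!r} is on a different stimulus grid")
    C = observer_matrix(population, grid)          # (n, 3, w)
    cmfs64 = basis.cie1964_on(grid)                # (3, w)
    n = C.shape[0]
    results: dict[str, MatchStats] = {}
    for st in setups:
        A = C @ st.primaries_max                   # (n, 3, 3)
        if np.max(np.linalg.cond(A)) > _COND_LIMIT:
            raise SingularMatchError(
                f"match {st.label!r}: primary matrix near-singular for at least one observer"
            )
        b = C @ st.reference.values                # (n, 3)
        R = np.linalg.solve(A, b[..., None])[..., 0]    # (n, 3)
        matched = R @ st.primaries_max.T           # (n, w)
        t = KM * matched @ cmfs64.T                # (n, 3)
        _, t_n = reference_white(st, basis)
        lab = xyz_to_lab(t, t_n)
        ddof = 1 if n > 1 else 0
        results[st.label] = MatchStats(
            label=st.label,
            lab=lab,
            sd_a=float(np.std(lab[:, 1], ddof=ddof)),
            sd_b=float(np.std(lab[:, 2], ddof=ddof)),
        )
    return results


def _lms_at(cmfs, wavelengths) -> np.ndarray:
    """lms values at arbitrary wavelengths, (..., 3, n_wl)."""
    if isinstance(cmfs, ConeFundamentals):
        grid, mat = cmfs.grid, cmfs.as_matrix()
    else:
        grid, mat = cmfs
    return np.clip(spline_resample_values(grid, mat, np.asarray(wavelengths, float)), 0.0, None)


def rayleigh_match(cmfs: ConeFundamentals, red_nm: float = RAYLEIGH_RED_NM,
                   green_nm: float = RAYLEIGH_GREEN_NM,
                   yellow_nm: float = RAYLEIGH_YELLOW_NM) -> float:
    """Rayleigh match as the red fraction of the red+green mixture in [0, 1].

    Solves the 2x2 system in the L and M cone signals for mixture weights
    (w_R, w_G) with ``w_R LM(red) + w_G LM(green) = LM(yellow)`` and reports
    ``w_R / (w_R + w_G)`` on a fixed linear radiance scale (unit-radiance
    monochromatic primaries).  Scale-invariant in the observer's sensitivities.
    """
    vals = _lms_at(cmfs, [red_nm, green_nm, yellow_nm])   # (3 cones, 3 wl)
    A = vals[:2, :2]
    y = vals[:2, 2]
    if np.linalg.cond(A) > _COND_LIMIT:
        raise SingularMatchError("Rayleigh primaries are indistinguishable for this observer")
    w = np.linalg.solve(A, y)
    return float(w[0] / (w[0] + w[1]))


def rayleigh_match_batch(batch: np.ndarray, grid: np.ndarray,
                         red_nm: float = RAYLEIGH_RED_NM,
                         green_nm: float = RAYLEIGH_GREEN_NM,
                         yellow_nm: float = RAYLEIGH_YELLOW_NM) -> np.ndarray:
    """Vectorized Rayleigh red fractions for a (n, 3, w) fundamentals batch."""
    vals = np.clip(spline_resample_values(grid, batch, np.array([red_nm, green_nm, yellow_nm])),
                   0.0, None)                               # (n, 3, 3)
    A = vals[:, :2, :2]
    y = vals[:, :2, 2]
    w = np.linalg.solve(A, y[..., None])[..., 0]
    return w[:, 0] / w.sum(axis=1)


@dataclass(frozen=True)
class RgbCmfs:
    """rgb-form CMFs: unit value at each of the three normalization wavelengths."""

    grid: np.ndarray
    rgb: np.ndarray       # (3, n_wavelengths) in r, g, b row order
    matrix: np.ndarray    # (3, 3) transform such that rgb = matrix @ lms


def lms_to_rgb(cmfs: ConeFundamentals,
               primary_wavelengths: tuple[float, float, float] = RGB_PRIMARY_NM) -> RgbCmfs:
    """Linear lms -> rgb transform normalized at three primary wavelengths.

    The 3x3 matrix is the inverse of the lms values at the primaries, so the
    resulting r, g, b functions equal the unit vectors there.
    """
    P = _lms_at(cmfs, primary_wavelengths)     # columns: lms at each primary
    if np.linalg.cond(P) > _COND_LIMIT:
        raise SingularMatchError("lms values at the rgb primaries are singular")
    M = np.linalg.inv(P)
    return RgbCmfs(grid=cmfs.grid, rgb=M @ cmfs.as_matrix(), matrix=M)


def lms_to_rgb_batch(batch: np.ndarray, grid: np.ndarray,
                     primary_wavelengths: tuple[float, float, float] = RGB_PRIMARY_NM
                     ) -> np.ndarray:
    """Vectorized rgb CMFs, (n, 3, w), for a (n, 3, w) fundamentals batch."""
    P = np.clip(spline_resample_values(grid, batch, np.asarray(primary_wavelengths, float)),
                0.0, None)                     # (n, 3, 3)
    M = np.linalg.inv(P)
    return M @ batch
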