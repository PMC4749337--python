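"""Synthetic color-match stimuli.

The two-scalar derivation and the applied-color-matching validation both need a
battery of five matches: three with neutral broadband references (white-shaped
reference white) and two with saturated cyan and orange references
(equal-energy reference white), all matched with three broadband display-like
primaries.  The experimental spectra behind that battery are unpublished, so
this module generates a synthetic battery with the same character: Gaussian
RGB display primaries and broadband/neutral vs. narrowband/saturated
references.  Spectra live on the 380-780 nm, 1 nm stimulus grid.
"""

from __future__ import annotations

import numpy as np

from .matching import MatchSetup
from .spectral import STIMULUS_GRID_NM, SpectralFunction

__all__ = ["generate_fixture_stimuli", "display_primaries"]


def _gaussian(grid: np.ndarray, peak_nm: float, sigma_nm: float, amplitude: float = 1.0) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((grid - peak_nm) / sigma_nm) ** 2)


def display_primaries(grid: np.ndarray | None = None) -> np.ndarray:
    """(n, 3) maximum-energy spectra of three broadband display-like primaries."""
    grid = STIMULUS_GRID_NM if grid is None else np.asarray(grid, float)
    red = _gaussian(grid, 610.0, 25.0)
    green = _gaussian(grid, 540.0, 28.0)
    blue = _gaussian(grid, 450.0, 18.0)
    return np.column_stack([red, green, blue])


def generate_fixture_stimuli(kind: str = "five_matches", seed: int = 0) -> list[MatchSetup]:
    """Deterministic synthetic match setups.

    ``five_matches``: matches 1/2/5 have neutral broadband references under a
    reference-shaped white; matches 3/4 have saturated cyan and orange
    references under an equal-energy white.  ``toy``: a single flat-reference
    match with seed-jittered Gaussian primaries, for quick experiments.
    """
    grid = STIMULUS_GRID_NM
    if kind == "five_matches":
        primaries = display_primaries(grid)
        ramp = (grid - grid[0]) / (grid[-1] - grid[0])
        refs = {
            "match1_neutral_flat": (np.full_like(grid, 0.8), "reference-shape"),
            "match2_neutral_cool": (1.15 - 0.5 * ramp, "reference-shape"),
            "match3_cyan": (_gaussian(grid, 490.0, 24.0), "equal-energy"),
            "match4_orange": (_gaussian(grid, 600.0, 26.0), "equal-energy"),
            "match5_neutral_warm": (0.65 + 0.5 * ramp, "reference-shape"),
        }
        return [
            MatchSetup(reference=SpectralFunction(grid, vals, name=label),
                       primaries_max=primaries, white_rule=rule, label=label)
            for label, (vals, rule) in refs.items()
        ]
    if kind == "toy":
        rng = np.random.default_rng(seed)
        peaks = np.array([610.0, 540.0, 450.0]) + rng.uniform(-5, 5, size=3)
        widths = rng.uniform(15, 30, size=3)
        primaries = np.column_stack([_gaussian(grid, p, w) for p, w in zip(peaks, widths)])
        ref = SpectralFunction(grid, np.full_like(grid, 0.5), name="toy_reference")
        return [MatchSetup(reference=ref, primaries_max=primaries,
                           white_rule="equal-energy", label="toy")]
    raise ValueError(f"unknown fixture kind {kind!r}")
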