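"""Synthetic physiological basis tables (analytic stand-ins).

The observer model consumes five fixed reference tables -- the two ocular-media
(lens) density components, the relative macular pigment density, and the three
low-density photopigment absorbances -- plus the CIE 1964 10-degree observer.
The canonical tabulations are distributed by CIE/CVRL and are not redistributed
here; this module constructs *synthetic* stand-ins from published analytic
templates with the same structure, grids, units and normalization:

* photopigment absorbances: Govardovskii et al. (2000) A1 visual-pigment
  template (alpha + beta bands) at peak wavelengths 560/530/420 nm for the
  L/M/S cones, peak-normalized;
* relative macular density: Gaussian mixture peaking near 460 nm with a
  short-wavelength shoulder, zero beyond ~550 nm, peak-normalized;
* lens/ocular media: a UV chromophore band plus a small scatter-like
  (400/lambda)^4 tail, split into an age-dependent component (docul1) and an
  age-independent component (docul2);
* CIE 1964 10-degree color matching functions: the multi-lobe analytic fits of
  Wyman, Sloan & Shirley (2013).

Every generated file carries a ``synthetic_`` prefix.  The model machinery is
agnostic to which tables it runs on; users holding the licensed CIE data can
point the loader at their own CSVs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .spectral import MODEL_GRID_NM

__all__ = [
    "govardovskii_absorbance",
    "synthetic_macular_relative_density",
    "synthetic_lens_components",
    "cie1964_analytic",
    "build_synthetic_tables",
    "write_packaged_tables",
    "BASIS_VERSION",
]

BASIS_VERSION = "synthetic-v1"

#: Synthetic peak wavelengths [nm] of the low-density pigment absorbances.
PIGMENT_PEAKS_NM = {"L": 560.0, "M": 530.0, "S": 420.0}


def govardovskii_absorbance(lmax_nm: float, wavelengths_nm: np.ndarray) -> np.ndarray:
    """A1 pigment absorbance template of Govardovskii et al. (2000).

    Returns the alpha + beta band absorbance, normalized so the maximum over
    the supplied grid is exactly 1.
    """
    wl = np.asarray(wavelengths_nm, float)
    x = lmax_nm / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax_nm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmax_beta = 189.0 + 0.315 * lmax_nm
    b_beta = -40.5 + 0.195 * lmax_nm
    beta = 0.26 * np.exp(-(((wl - lmax_beta) / b_beta) ** 2))
    total = alpha + beta
    total = total / total.max()
    total[np.argmax(total)] = 1.0
    return total


def synthetic_macular_relative_density(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Relative macular pigment density: main band near 460 nm with shoulders."""
    wl = np.asarray(wavelengths_nm, float)
    g_main = np.exp(-0.5 * ((wl - 458.0) / 22.0) ** 2)
    g_shoulder = 0.65 * np.exp(-0.5 * ((wl - 487.0) / 14.0) ** 2)
    g_blue = 0.55 * np.exp(-0.5 * ((wl - 425.0) / 22.0) ** 2)
    rel = g_main + g_shoulder + g_blue
    rel = rel / rel.max()
    rel[np.argmax(rel)] = 1.0
    return rel


def synthetic_lens_components(wavelengths_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ocular-media density split into aging (docul1) and stable (docul2) parts.

    The total density at the 32-year reference age is a UV chromophore band
    falling steeply through the violet plus a weak scatter-like tail.  The
    chromophore band carries most of the aging, so 60% of it goes to docul1;
    the scatter tail and the remainder are age-independent (docul2).
    """
    wl = np.asarray(wavelengths_nm, float)
    chromophore = 1.40 * np.exp(-0.5 * ((wl - 360.0) / 46.0) ** 2)
    scatter = 0.20 * (400.0 / wl) ** 4
    docul1 = 0.60 * chromophore
    docul2 = 0.40 * chromophore + scatter
    return docul1, docul2


def cie1964_analytic(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Analytic fit to the CIE 1964 10-degree CMFs (Wyman, Sloan & Shirley 2013).

    Returns a (3, n) array of xbar/ybar/zbar.  Accurate to a few percent of
    peak, which suffices for the relative colorimetry done in this package.
    """
    wl = np.asarray(wavelengths_nm, float)
    xbar = 0.398 * np.exp(-1250.0 * np.log((wl + 570.1) / 1014.0) ** 2) + 1.132 * np.exp(
        -234.0 * np.log((1338.0 - wl) / 743.5) ** 2
    )
    ybar = 1.011 * np.exp(-0.5 * ((wl - 556.1) / 46.14) ** 2)
    zbar = 2.060 * np.exp(-32.0 * np.log((wl - 265.8) / 180.4) ** 2)
    return np.vstack([xbar, ybar, zbar])


def build_synthetic_tables() -> dict[str, np.ndarray]:
    """All packaged tables as arrays, keyed by component name."""
    grid = MODEL_GRID_NM.copy()
    docul1, docul2 = synthetic_lens_components(grid)
    cmf_grid = np.arange(380.0, 780.0 + 1e-9, 5.0)
    tables = {
        "grid": grid,
        "docul1": docul1,
        "docul2": docul2,
        "macula_relative": synthetic_macular_relative_density(grid),
        "absorbance_L": govardovskii_absorbance(PIGMENT_PEAKS_NM["L"], grid),
        "absorbance_M": govardovskii_absorbance(PIGMENT_PEAKS_NM["M"], grid),
        "absorbance_S": govardovskii_absorbance(PIGMENT_PEAKS_NM["S"], grid),
        "cie1964_grid": cmf_grid,
        "cie1964_xyz": cie1964_analytic(cmf_grid),
    }
    return tables


def _fmt(v: float) -> str:
    return f"{v:.12g}"


def write_packaged_tables(out_dir: str | Path) -> None:
    """Write the synthetic tables as two-column CSVs plus a sha256 manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = build_synthetic_tables()
    files = {}
    for comp in ("docul1", "docul2", "macula_relative",
                 "absorbance_L", "absorbance_M", "absorbance_S"):
        name = f"synthetic_{comp}.csv"
        lines = [f"# synthetic basis table '{comp}' ({BASIS_VERSION}); see indivobs.synthbasis",
                 "wavelength_nm,value"]
        lines += [f"{_fmt(w)},{_fmt(v)}" for w, v in zip(t["grid"], t[comp])]
        files[name] = "\n".join(lines) + "\n"
    lines = [f"# synthetic CIE 1964 10-degree CMFs, analytic fit ({BASIS_VERSION})",
             "wavelength_nm,x,y,z"]
    for i, w in enumerate(t["cie1964_grid"]):
        x, y, z = t["cie1964_xyz"][:, i]
        lines.append(f"{_fmt(w)},{_fmt(x)},{_fmt(y)},{_fmt(z)}")
    files["synthetic_cie1964_10deg.csv"] = "\n".join(lines) + "\n"

    manifest = []
    for name in sorted(files):
        (out_dir / name).write_text(files[name], encoding="utf-8")
        digest = hashlib.sha256(files[name].encode("utf-8")).hexdigest()
        manifest.append(f"{digest}  {name}")
    (out_dir / "MANIFEST.sha256").write_text("\n".join(manifest) + "\n", encoding="utf-8")
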