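"""Loading and validation of the fixed physiological reference tables.

A :class:`BasisTables` bundle holds everything the observer model needs that is
*not* observer-specific: the two ocular-media density components (``docul1`` is
the age-dependent portion, ``docul2`` the age-independent one), the
peak-normalized relative macular pigment density, the three peak-normalized
low-density photopigment absorbances, and the CIE 1964 10-degree color matching
functions used by the match simulator.

The packaged defaults are synthetic analytic stand-ins (see
:mod:`indivobs.synthbasis`); the loader accepts a user-supplied directory of
CSVs in the same layout, so licensed CIE tabulations can be dropped in.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .spectral import SpectralFunction, spline_resample_values
from .synthbasis import BASIS_VERSION

__all__ = ["BasisTables", "BasisLoadError", "load_basis_tables", "save_basis_tables"]

_COMPONENTS = (
    "docul1",
    "docul2",
    "macula_relative",
    "absorbance_L",
    "absorbance_M",
    "absorbance_S",
)
_PEAK_NORMALIZED = ("macula_relative", "absorbance_L", "absorbance_M", "absorbance_S")
_CMF_NAME = "cie1964_10deg"


class BasisLoadError(ValueError):
    """Fatal problem while loading or validating basis tables."""


@dataclass(frozen=True)
class BasisTables:
    """Validated physiological reference tables on a common 5 nm grid."""

    grid: np.ndarray
    docul1: np.ndarray
    docul2: np.ndarray
    d_rel_macula: np.ndarray
    absorbance_L: np.ndarray
    absorbance_M: np.ndarray
    absorbance_S: np.ndarray
    cie1964_grid: np.ndarray
    cie1964_xyz: np.ndarray  # shape (3, len(cie1964_grid))
    version: str = BASIS_VERSION
    _spline_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        _validate_tables(self)

    def absorbance(self, cone: str) -> np.ndarray:
        try:
            return getattr(self, f"absorbance_{cone}")
        except AttributeError:
            raise ValueError(f"unknown cone type {cone!r}; expected 'L', 'M' or 'S'") from None

    def absorbance_spline(self, cone: str) -> CubicSpline:
        """Natural cubic spline of a pigment absorbance (cached)."""
        key = f"absorbance_{cone}"
        if key not in self._spline_cache:
            self._spline_cache[key] = CubicSpline(
                self.grid, self.absorbance(cone), bc_type="natural"
            )
        return self._spline_cache[key]

    def cie1964_on(self, grid_nm: np.ndarray) -> np.ndarray:
        """CIE 1964 CMFs spline-resampled to ``grid_nm``; zero outside, clipped >= 0."""
        out = spline_resample_values(self.cie1964_grid, self.cie1964_xyz, np.asarray(grid_nm, float))
        return np.clip(out, 0.0, None)


def _validate_tables(t: BasisTables) -> None:
    grid = np.asarray(t.grid, float)
    if grid.ndim != 1 or grid.size < 2:
        raise BasisLoadError("basis grid must be a 1-D array with >= 2 points")
    steps = np.diff(grid)
    if not np.all(steps > 0):
        raise BasisLoadError("basis wavelength grid is not strictly increasing")
    if not np.allclose(steps, 5.0, atol=1e-9):
        raise BasisLoadError("basis wavelength grid must have a constant 5 nm step")
    if grid[0] > 390.0 + 1e-9 or grid[-1] < 830.0 - 1e-9:
        raise BasisLoadError(
            f"basis tables must cover 390-830 nm, got {grid[0]:g}-{grid[-1]:g} nm"
        )
    named = {
        "docul1": t.docul1,
        "docul2": t.docul2,
        "macula_relative": t.d_rel_macula,
        "absorbance_L": t.absorbance_L,
        "absorbance_M": t.absorbance_M,
        "absorbance_S": t.absorbance_S,
    }
    for name, vals in named.items():
        vals = np.asarray(vals, float)
        if vals.shape != grid.shape:
            raise BasisLoadError(f"{name}: shape {vals.shape} does not match grid {grid.shape}")
        if not np.all(np.isfinite(vals)):
            raise BasisLoadError(f"{name}: non-finite values")
        if np.any(vals < 0):
            raise BasisLoadError(f"{name}: negative density/absorbance values")
    for name in _PEAK_NORMALIZED:
        key = "d_rel_macula" if name == "macula_relative" else name
        vals = np.asarray(getattr(t, key), float)
        if abs(vals.max() - 1.0) > 1e-6:
            raise BasisLoadError(
                f"{name}: peak-normalized table must have maximum 1, got {vals.max():.6g}"
            )
    cmf_grid = np.asarray(t.cie1964_grid, float)
    cmf = np.asarray(t.cie1964_xyz, float)
    if not np.all(np.diff(cmf_grid) > 0):
        raise BasisLoadError("CIE 1964 grid is not strictly increasing")
    if cmf.shape != (3, cmf_grid.size):
        raise BasisLoadError(f"CIE 1964 CMFs must be (3, n), got {cmf.shape}")
    if not np.all(np.isfinite(cmf)) or np.any(cmf < 0):
        raise BasisLoadError("CIE 1964 CMFs must be finite and nonnegative")


def _read_csv_columns(path: Path, n_value_cols: int) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise BasisLoadError(f"cannot read basis table {path}: {exc}") from exc
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if parts[0].lower().startswith("wavelength"):
            continue
        if len(parts) != n_value_cols + 1:
            raise BasisLoadError(f"{path.name}: expected {n_value_cols + 1} columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise BasisLoadError(f"{path.name}: non-numeric entry in line {raw!r}") from exc
    if not rows:
        raise BasisLoadError(f"{path.name}: no data rows")
    arr = np.asarray(rows, float)
    return arr[:, 0], arr[:, 1:].T


def _component_path(directory: Path, component: str) -> Path:
    for candidate in (f"synthetic_{component}.csv", f"{component}.csv"):
        p = directory / candidate
        if p.exists():
            return p
    raise BasisLoadError(f"missing basis table for {component!r} in {directory}")


def _packaged_data_dir() -> Path:
    return Path(resources.files("indivobs") / "data")


def _verify_manifest(directory: Path) -> None:
    manifest = directory / "MANIFEST.sha256"
    if not manifest.exists():
        return
    for line in manifest.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        digest, name = line.split()
        path = directory / name
        if not path.exists():
            raise BasisLoadError(f"manifest references missing file {name}")
        actual = hashlib.sha256(path.read_bytes()).hexdigest()
        if actual != digest:
            raise BasisLoadError(f"checksum mismatch for basis table {name}")


def load_basis_tables(source: str | Path | None = None) -> BasisTables:
    """Load basis tables from ``source`` (directory of CSVs) or packaged defaults.

    The packaged defaults are verified against their sha256 manifest.
    Validation failures raise :class:`BasisLoadError`.
    """
    if source is None:
        directory = _packaged_data_dir()
        version = BASIS_VERSION
        _verify_manifest(directory)
    else:
        directory = Path(source)
        if not directory.is_dir():
            raise BasisLoadError(f"basis table source {directory} is not a directory")
        version = f"user:{directory.name}"
        _verify_manifest(directory)

    arrays = {}
    grid = None
    for comp in _COMPONENTS:
        wl, vals = _read_csv_columns(_component_path(directory, comp), 1)
        if grid is None:
            grid = wl
        elif wl.shape != grid.shape or not np.allclose(wl, grid):
            raise BasisLoadError(f"{comp}: wavelength grid differs from other components")
        arrays[comp] = vals[0]
    cmf_wl, cmf = _read_csv_columns(_component_path(directory, _CMF_NAME), 3)

    return BasisTables(
        grid=grid,
        docul1=arrays["docul1"],
        docul2=arrays["docul2"],
        d_rel_macula=arrays["macula_relative"],
        absorbance_L=arrays["absorbance_L"],
        absorbance_M=arrays["absorbance_M"],
        absorbance_S=arrays["absorbance_S"],
        cie1964_grid=cmf_wl,
        cie1964_xyz=cmf,
        version=version,
    )


def save_basis_tables(tables: BasisTables, directory: str | Path) -> None:
    """Write tables as CSVs in the loader's layout (useful for overrides/tests)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def fmt(v: float) -> str:
        return f"{v:.12g}"

    named = {
        "docul1": tables.docul1,
        "docul2": tables.docul2,
        "macula_relative": tables.d_rel_macula,
        "absorbance_L": tables.absorbance_L,
        "absorbance_M": tables.absorbance_M,
        "absorbance_S": tables.absorbance_S,
    }
    for comp, vals in named.items():
        lines = ["wavelength_nm,value"]
        lines += [f"{fmt(w)},{fmt(v)}" for w, v in zip(tables.grid, vals)]
        (directory / f"{comp}.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    lines = ["wavelength_nm,x,y,z"]
    for i, w in enumerate(tables.cie1964_grid):
        x, y, z = tables.cie1964_xyz[:, i]
        lines.append(f"{fmt(w)},{fmt(x)},{fmt(y)},{fmt(z)}")
    (directory / f"{_CMF_NAME}.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def spectral(tables: BasisTables, component: str) -> SpectralFunction:
    """A named component as a :class:`SpectralFunction`."""
    mapping = {
        "docul1": tables.docul1,
        "docul2": tables.docul2,
        "macula_relative": tables.d_rel_macula,
        "absorbance_L": tables.absorbance_L,
        "absorbance_M": tables.absorbance_M,
        "absorbance_S": tables.absorbance_S,
    }
    if component not in mapping:
        raise ValueError(f"unknown component {component!r}")
    return SpectralFunction(tables.grid, mapping[component], name=component)
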