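"""Sampled spectral distributions on a wavelength grid.

The package works on the visible range 380-780 nm.  The canonical grid is
1 nm spaced (401 samples); all photometric integrals are rectangular
(Riemann) sums with an explicit grid step, which makes normalisation
identities exact on the canonical grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CANONICAL_GRID",
    "SpectralDistribution",
    "resample",
    "planck_spectrum",
    "read_spd_csv",
    "write_spd_csv",
]

#: Canonical wavelength grid: 380-780 nm at 1 nm (401 samples).
CANONICAL_GRID: np.ndarray = np.arange(380.0, 781.0, 1.0)
CANONICAL_GRID.setflags(write=False)

_WL_MIN, _WL_MAX = 380.0, 780.0


@dataclass(frozen=True)
class SpectralDistribution:
    """A spectrum sampled on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nm, within [380, 780].
    values
        Spectral irradiance per nm.  Absolute spectra are in W m^-2 nm^-1;
        relative spectra are dimensionless (V-integral normalised to 100).
    is_absolute
        True for absolute irradiance, False for a relative spectrum.
    name
        Optional identifier carried through I/O.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    is_absolute: bool = True
    name: str | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValidationError("wavelengths and values must be 1-d arrays of equal length")
        if wl.size < 2:
            raise ValidationError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if wl[0] < _WL_MIN - 1e-9 or wl[-1] > _WL_MAX + 1e-9:
            raise ValidationError(
                f"wavelengths must lie within [{_WL_MIN:.0f}, {_WL_MAX:.0f}] nm "
                f"(got [{wl[0]:g}, {wl[-1]:g}])"
            )
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValidationError("spectral values must be finite and non-negative")
        wl.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def grid_step_nm(self) -> float:
        """Grid spacing in nm; raises if the grid is not uniform."""
        steps = np.diff(self.wavelengths_nm)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValidationError("grid spacing is not uniform; resample first")
        return float(steps[0])

    def scaled(self, k: float) -> "SpectralDistribution":
        """Return the spectrum multiplied pointwise by ``k`` (k > 0)."""
        if k <= 0:
            raise ValidationError("scale factor must be positive")
        return dataclasses.replace(self, values=self.values * k)

    def on_canonical_grid(self) -> "SpectralDistribution":
        """Return self if already on the canonical grid, else a resampled copy."""
        if self.wavelengths_nm.size == CANONICAL_GRID.size and np.array_equal(
            self.wavelengths_nm, CANONICAL_GRID
        ):
            return self
        return resample(self, CANONICAL_GRID)


def resample(spd: SpectralDistribution, grid: np.ndarray) -> SpectralDistribution:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    Wavelengths outside the input's support are filled with 0, so narrow-band
    inputs stay narrow-band.  The ``is_absolute`` flag and name are preserved.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValidationError("target grid must be a non-empty 1-d array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError("target grid must be strictly increasing")
    out = np.interp(grid, spd.wavelengths_nm, spd.values, left=0.0, right=0.0)
    return SpectralDistribution(grid, out, is_absolute=spd.is_absolute, name=spd.name)


# Planck constants (CODATA): second radiation constant c2 = h*c/kB in m K.
_C2 = 1.438776877e-2


def planck_spectrum(cct_K: float, grid: np.ndarray | None = None) -> np.ndarray:
    """Blackbody spectral radiance on ``grid`` (nm), in arbitrary units.

    Planck's law: B(lambda, T) ~ lambda^-5 / (exp(c2 / (lambda T)) - 1).
    The absolute scale is irrelevant here; callers rescale to a target
    illuminance.
    """
    if grid is None:
        grid = CANONICAL_GRID
    lam_m = np.asarray(grid, dtype=float) * 1e-9
    x = _C2 / (lam_m * float(cct_K))
    return lam_m ** -5.0 / np.expm1(x)


SPD_CSV_COLUMNS = ("wavelength_nm", "irradiance_W_m2_nm")


def read_spd_csv(path) -> SpectralDistribution:
    """Read an SPD CSV with header ``wavelength_nm,irradiance_W_m2_nm``.

    ``#`` lines are comments.  Samples outside 380-780 nm are dropped.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"could not parse SPD CSV {path!s}: {exc}") from exc
    missing = [c for c in SPD_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"SPD CSV {path!s} is missing columns {missing}")
    wl = df[SPD_CSV_COLUMNS[0]].to_numpy(dtype=float)
    vals = df[SPD_CSV_COLUMNS[1]].to_numpy(dtype=float)
    keep = (wl >= _WL_MIN) & (wl <= _WL_MAX)
    import os

    name = os.path.splitext(os.path.basename(str(path)))[0]
    return SpectralDistribution(wl[keep], vals[keep], is_absolute=True, name=name)


def write_spd_csv(spd: SpectralDistribution, path) -> None:
    """Write an SPD to the two-column CSV format."""
    df = pd.DataFrame(
        {SPD_CSV_COLUMNS[0]: spd.wavelengths_nm, SPD_CSV_COLUMNS[1]: spd.values}
    )
    df.to_csv(path, index=False)
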