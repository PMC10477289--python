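"""Photoreceptor sensitivity curves and the daylight reference.

SYNTHETIC STAND-IN DATA.  The curves built here are analytic Gaussian
templates standing in for the standardised tabulations (CIE 1924 photopic
luminous efficiency V(lambda); CIE S 026 S-cone-opic and melanopic action
spectra), and the daylight reference is a 6500 K Planckian radiator standing
in for D65.  They reproduce the qualitative structure that matters for the
model — peak positions, relative bandwidths, the monotone blue-content
ordering of warm vs. cold white light — but NOT the standards' exact values,
so receptor ratios and equivalent daylight illuminances computed with the
default library differ in detail from toolbox outputs based on the official
tables.  Every identity in this package (normalisations, round trips,
degeneracies, fits) holds for any fixed, internally consistent curve set.

Template parameters:

====================  ==========  ============
curve                 peak (nm)   sigma (nm)
====================  ==========  ============
V (photopic)          555         41.9
S-cone-opic           448         30
melanopic (ipRGC)     490         40
====================  ==========  ============

The V template's width matches the classic single-Gaussian approximation of
V(lambda) (FWHM approximately 99 nm); its peak is placed exactly at 555 nm so the
normalisation V(555) = max V = 1 is exact on the canonical grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ValidationError
from .spectra import CANONICAL_GRID, SpectralDistribution, planck_spectrum

__all__ = ["SensitivityLibrary", "default_library", "RECEPTORS"]

#: Receptor ids with a packaged sensitivity curve.
RECEPTORS = ("s_cone", "melanopic")

_MAXIMUM_LUMINOUS_EFFICACY = 683.0  # lm/W at 555 nm, fixed by definition

_V_PEAK, _V_SIGMA = 555.0, 41.9
_S_PEAK, _S_SIGMA = 448.0, 30.0
_MEL_PEAK, _MEL_SIGMA = 490.0, 40.0
_DAYLIGHT_CCT = 6500.0


def _gaussian(grid: np.ndarray, peak: float, sigma: float) -> np.ndarray:
    g = np.exp(-0.5 * ((grid - peak) / sigma) ** 2)
    return g / g.max()


@dataclass(frozen=True)
class SensitivityLibrary:
    """Sensitivity curves and daylight reference on the canonical 1 nm grid.

    All sensitivity curves are peak-normalised to 1.  ``d65`` is the daylight
    reference spectrum stored scaled to a photopic illuminance of exactly
    1 lux, so receptor-weighted integrals of ``d65`` are directly "per lux of
    daylight" — the denominator of every equivalent daylight illuminance.
    """

    grid: np.ndarray
    V: np.ndarray
    s_cone: np.ndarray
    melanopic: np.ndarray
    d65: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.size
        for label in ("V", "s_cone", "melanopic", "d65"):
            arr = getattr(self, label)
            if arr.shape != (n,):
                raise ValidationError(f"curve {label} is not on the library grid")
        for label in ("V", "s_cone", "melanopic"):
            arr = getattr(self, label)
            if arr.min() < 0 or arr.max() > 1 + 1e-12:
                raise ValidationError(f"sensitivity curve {label} must lie in [0, 1]")
        i555 = int(np.searchsorted(self.grid, 555.0))
        if abs(self.V[i555] - self.V.max()) > 1e-6:
            raise ValidationError("V must peak at 555 nm (within 1e-6)")

    @property
    def step_nm(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def curve(self, receptor: str) -> np.ndarray:
        """Return the sensitivity curve for a receptor id ('s_cone', 'melanopic')."""
        if receptor not in RECEPTORS:
            raise ValidationError(
                f"unknown receptor {receptor!r}; expected one of {RECEPTORS}"
            )
        return getattr(self, receptor)

    @property
    def d65_spd(self) -> SpectralDistribution:
        """The daylight reference as a SpectralDistribution (1 lux)."""
        return SpectralDistribution(self.grid, self.d65, is_absolute=True, name="d65_synthetic")


@lru_cache(maxsize=1)
def default_library() -> SensitivityLibrary:
    """Build the default (synthetic stand-in) sensitivity library.

    Deterministic and cached; see the module docstring for what these curves
    do and do not represent.
    """
    grid = np.asarray(CANONICAL_GRID, dtype=float)
    V = _gaussian(grid, _V_PEAK, _V_SIGMA)
    s = _gaussian(grid, _S_PEAK, _S_SIGMA)
    m = _gaussian(grid, _MEL_PEAK, _MEL_SIGMA)
    day = planck_spectrum(_DAYLIGHT_CCT, grid)
    # scale the daylight reference to exactly 1 lux
    ev = _MAXIMUM_LUMINOUS_EFFICACY * float(np.sum(day * V)) * float(grid[1] - grid[0])
    day = day / ev
    for arr in (grid, V, s, m, day):
        arr.setflags(write=False)
    return SensitivityLibrary(grid=grid, V=V, s_cone=s, melanopic=m, d65=day)
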