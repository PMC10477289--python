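"""Photometric and photoreceptor signals of a light-source spectrum.

Given an absolute spectral irradiance distribution E(lambda) the model uses
three scalar inputs:

* ``Ev``  — photopic illuminance, 683 * integral E * V dlambda, in lux;
* ``S``   — S-cone signal: S-cone-weighted integral of the *relative*
  spectrum divided by its V-weighted integral (dimensionless);
* ``G``   — ipRGC (melanopic) signal, defined analogously.

The relative spectrum is E scaled so its V-weighted integral is 100; the
factors 683 and 100 cancel in the S and G ratios but are implemented so the
intermediate quantities match their photometric definitions exactly.

Alpha-opic equivalent daylight illuminance (EDI) accounting is also provided:
the EDI of a spectrum for a receptor is the illuminance of the daylight
reference producing the same receptor-weighted irradiance.  ``ratios_from_edi``
converts published (Ev, EDI) pairs back to S/G ratios without the underlying
spectra.

All integrals are rectangular sums on the canonical 1 nm grid; spectra on
other grids are linearly resampled first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSpectrumError, UnitError, ValidationError
from .sensitivities import RECEPTORS, SensitivityLibrary, default_library
from .spectra import SpectralDistribution

__all__ = [
    "ReceptorSignals",
    "photopic_illuminance",
    "relative_spectrum",
    "s_ratio",
    "g_ratio",
    "alpha_opic_edi",
    "ratios_from_edi",
    "compute_signals",
]

MAXIMUM_LUMINOUS_EFFICACY = 683.0  # lm/W
RELATIVE_NORMALISATION = 100.0
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class ReceptorSignals:
    """Per-stimulus model inputs: (Ev, S, G), optionally with alpha-opic EDIs."""

    Ev: float
    S: float
    G: float
    edi: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if not (self.Ev > 0 and self.S > 0 and self.G > 0):
            raise ValidationError("Ev, S and G must all be positive")


def _weighted_integral(spd: SpectralDistribution, curve: np.ndarray, lib: SensitivityLibrary) -> float:
    c = spd.on_canonical_grid()
    return float(np.sum(c.values * curve)) * lib.step_nm


def photopic_illuminance(
    spd: SpectralDistribution, lib: SensitivityLibrary | None = None
) -> float:
    """Photopic illuminance Ev = 683 * integral E(lambda) V(lambda) dlambda, in lux."""
    lib = lib or default_library()
    if not spd.is_absolute:
        raise UnitError("photopic illuminance requires an absolute spectrum")
    return MAXIMUM_LUMINOUS_EFFICACY * _weighted_integral(spd, lib.V, lib)


def relative_spectrum(
    spd: SpectralDistribution, lib: SensitivityLibrary | None = None
) -> SpectralDistribution:
    """Relative spectrum: E scaled so its V-weighted integral equals 100.

    Invariant under absolute rescaling of the input.
    """
    lib = lib or default_library()
    if not spd.is_absolute:
        raise UnitError("relative_spectrum expects an absolute spectrum")
    c = spd.on_canonical_grid()
    v_int = _weighted_integral(c, lib.V, lib)
    if v_int <= _DEGENERATE_TOL:
        raise DegenerateSpectrumError(
            f"V-weighted integral {v_int:g} below tolerance; spectrum carries no photopic power"
        )
    return SpectralDistribution(
        c.wavelengths_nm,
        c.values * (RELATIVE_NORMALISATION / v_int),
        is_absolute=False,
        name=spd.name,
    )


def _receptor_over_v(
    spd: SpectralDistribution, curve: np.ndarray, lib: SensitivityLibrary
) -> float:
    # Ratio of the receptor- and V-weighted integrals of the relative
    # spectrum (Riemann steps cancel, but are kept explicit via the shared
    # helper).  Uses the relative spectrum so intermediates match their
    # definitions; the ratio itself is scale-invariant.
    rel = spd if not spd.is_absolute else relative_spectrum(spd, lib)
    v_int = _weighted_integral(rel, lib.V, lib)
    if v_int <= _DEGENERATE_TOL:
        raise DegenerateSpectrumError("V-weighted integral below tolerance")
    return _weighted_integral(rel, curve, lib) / v_int


def s_ratio(spd: SpectralDistribution, lib: SensitivityLibrary | None = None) -> float:
    """S-cone signal: S-cone-opic over V-weighted integral of the relative spectrum."""
    lib = lib or default_library()
    return _receptor_over_v(spd, lib.s_cone, lib)


def g_ratio(spd: SpectralDistribution, lib: SensitivityLibrary | None = None) -> float:
    """ipRGC (melanopic) signal: melanopic over V-weighted integral of the relative spectrum."""
    lib = lib or default_library()
    return _receptor_over_v(spd, lib.melanopic, lib)


def alpha_opic_edi(
    spd: SpectralDistribution,
    receptor: str,
    lib: SensitivityLibrary | None = None,
) -> float:
    """Equivalent daylight illuminance of ``spd`` for a receptor, in lux.

    Defined as the receptor-weighted irradiance of ``spd`` divided by the
    receptor-weighted irradiance per lux of the packaged daylight reference;
    the EDI of the daylight reference itself equals its own illuminance by
    construction.
    """
    lib = lib or default_library()
    if not spd.is_absolute:
        raise UnitError("alpha-opic EDI requires an absolute spectrum")
    curve = lib.curve(receptor)
    per_lux = float(np.sum(lib.d65 * curve)) * lib.step_nm  # d65 is stored at 1 lux
    return _weighted_integral(spd, curve, lib) / per_lux


def _daylight_ratio(receptor: str, lib: SensitivityLibrary) -> float:
    """Receptor-over-V ratio of the packaged daylight reference."""
    curve = lib.curve(receptor)
    return float(np.sum(lib.d65 * curve)) / float(np.sum(lib.d65 * lib.V))


def ratios_from_edi(
    Ev: float,
    edi: float,
    receptor: str,
    lib: SensitivityLibrary | None = None,
) -> float:
    """Recover the S or G ratio of a stimulus from its (Ev, alpha-opic EDI) pair.

    Identity: (EDI / Ev) * r_daylight(receptor) equals the receptor-over-V
    ratio of the original spectrum, where r_daylight is the same ratio for
    the packaged daylight reference.  This bridges published per-stimulus
    EDI tables to the model inputs without the underlying spectra.
    """
    lib = lib or default_library()
    if not Ev > 0:
        raise ValidationError("Ev must be positive")
    return (edi / Ev) * _daylight_ratio(receptor, lib)


def compute_signals(
    spd: SpectralDistribution,
    lib: SensitivityLibrary | None = None,
    with_edi: bool = True,
) -> ReceptorSignals:
    """Compute the full (Ev, S, G[, EDIs]) signal record for one spectrum."""
    lib = lib or default_library()
    edi = (
        {r: alpha_opic_edi(spd, r, lib) for r in RECEPTORS} if with_edi else None
    )
    return ReceptorSignals(
        Ev=photopic_illuminance(spd, lib),
        S=s_ratio(spd, lib),
        G=g_ratio(spd, lib),
        edi=edi,
    )
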