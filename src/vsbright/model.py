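"""The compressive multi-channel brightness model and its published presets.

The model maps the three receptor signals of a stimulus to a predicted
visually scaled brightness M on the observers' 0-100 rating scale:

    M = a * [ Ev^gamma * (alpha * S^delta1 + beta * G^delta2) ] + b

``Ev`` is the photopic illuminance in lux, ``S`` the S-cone ratio and ``G``
the ipRGC (melanopic) ratio.  ``gamma`` compresses the illuminance scale and
``delta1``/``delta2`` compress the blue-sensitive channel signals; ``alpha``
and ``beta`` weight the two channels and ``(a, b)`` is the linear transform
onto the rating scale.  M is deliberately not clipped to [0, 100] — clipping
belongs to the simulation of individual observer responses, not to the model.

Presets
-------
``fotios_1998``
    The Fotios-Levermore equivalent-luminance form: gamma = 1 (no
    illuminance compression), S-channel only with exponent 0.24, i.e.
    M = a * Ev * (S/V)^0.24 + b.  Carries the published rating-scale fit
    (a, b) = (0.036, 40.946).
``final_sg``
    The published final S+G parameterisation:
    M = 8.9974 * [Ev^0.2629 * (S^0.074 + 0.5 * G^0.0424)] - 1.3307.
``v_only``
    Illuminance-only reduction a * Ev^gamma + b (alpha = 1, delta1 = 0,
    beta = 0), with neutral (gamma, a, b) = (1, 1, 0) meant to be fitted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "BrightnessModelParams",
    "ModelPreset",
    "PRESET_NAMES",
    "get_preset",
    "model_raw",
    "model_m",
    "evaluate_raw",
    "evaluate_m",
    "fotios_equivalent_luminance",
    "final_model_closed_form",
]


@dataclass(frozen=True)
class BrightnessModelParams:
    """One parameterisation of the brightness model.

    alpha, beta : channel weights (>= 0, not both zero)
    gamma       : illuminance compression exponent, in (0, 1.5]
    delta1/2    : S and G compression exponents, in [0, 1]
    a, b        : linear transform onto the rating scale
    """

    alpha: float
    beta: float
    gamma: float
    delta1: float
    delta2: float
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.5):
            raise ValidationError(f"gamma must be in (0, 1.5], got {self.gamma}")
        for nm in ("delta1", "delta2"):
            d = getattr(self, nm)
            if not (0.0 <= d <= 1.0):
                raise ValidationError(f"{nm} must be in [0, 1], got {d}")
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be non-negative")
        if self.alpha + self.beta <= 0:
            raise ValidationError("alpha + beta must be positive")

    def replace(self, **kw) -> "BrightnessModelParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ModelPreset:
    """A named, optionally frozen parameterisation."""

    name: str
    params: BrightnessModelParams
    frozen: bool = False

    def to_json(self) -> str:
        return json.dumps({"name": self.name, **self.params.to_dict()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelPreset":
        d = json.loads(text)
        name = d.pop("name", "custom")
        return cls(name=name, params=BrightnessModelParams(**d), frozen=False)


_PRESETS = {
    "fotios_1998": ModelPreset(
        "fotios_1998",
        BrightnessModelParams(
            alpha=1.0, beta=0.0, gamma=1.0, delta1=0.24, delta2=0.24,
            a=0.036, b=40.946,
        ),
        frozen=True,
    ),
    "final_sg": ModelPreset(
        "final_sg",
        BrightnessModelParams(
            alpha=1.0, beta=0.5, gamma=0.2629, delta1=0.074, delta2=0.0424,
            a=8.9974, b=-1.3307,
        ),
        frozen=True,
    ),
    "v_only": ModelPreset(
        "v_only",
        BrightnessModelParams(
            alpha=1.0, beta=0.0, gamma=1.0, delta1=0.0, delta2=0.0, a=1.0, b=0.0
        ),
        frozen=True,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> ModelPreset:
    """Look up a named preset ('fotios_1998', 'final_sg', 'v_only')."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
        ) from None


def _power(base, expo: float, label: str):
    """base**expo with domain checking for fractional exponents."""
    base = np.asarray(base, dtype=float)
    if expo != int(expo) and np.any(base < 0):
        raise DomainError(f"negative {label} with fractional exponent {expo}")
    if expo == 0.0:
        return np.ones_like(base)
    return base ** expo


def evaluate_raw(params: BrightnessModelParams, Ev, S, G):
    """Vectorised bracket term Ev^gamma * (alpha S^delta1 + beta G^delta2)."""
    Ev = np.asarray(Ev, dtype=float)
    if np.any(Ev <= 0):
        raise DomainError("Ev must be positive")
    bracket = params.alpha * _power(S, params.delta1, "S") + params.beta * _power(
        G, params.delta2, "G"
    )
    return _power(Ev, params.gamma, "Ev") * bracket


def evaluate_m(params: BrightnessModelParams, Ev, S, G):
    """Vectorised model value a * raw + b (not clipped)."""
    return params.a * evaluate_raw(params, Ev, S, G) + params.b


def model_raw(params: BrightnessModelParams, sig) -> float:
    """Bracket term for one ReceptorSignals record."""
    return float(evaluate_raw(params, sig.Ev, sig.S, sig.G))


def model_m(params: BrightnessModelParams, sig) -> float:
    """Model brightness a * raw + b for one ReceptorSignals record."""
    return float(evaluate_m(params, sig.Ev, sig.S, sig.G))


FOTIOS_EXPONENT = 0.24


def fotios_equivalent_luminance(Lv: float, s_over_v: float) -> float:
    """Fotios-Levermore equivalent luminance  L_eq = Lv * (S/V)^0.24.

    ``Lv`` may be any V-weighted absolute quantity (luminance or
    illuminance); the result carries the same unit.
    """
    if np.any(np.asarray(s_over_v) <= 0):
        raise DomainError("S/V ratio must be positive")
    if np.any(np.asarray(Lv) < 0):
        raise DomainError("Lv must be non-negative")
    return Lv * s_over_v ** FOTIOS_EXPONENT


def final_model_closed_form(Ev, S, G):
    """Hard-coded closed form of the published final S+G model.

    Kept literal (independent of the preset machinery) so preset evaluation
    can be checked against it:
    M = 8.9974 * [Ev^0.2629 * (1.0 * S^0.074 + 0.5 * G^0.0424)] - 1.3307.
    """
    Ev = np.asarray(Ev, dtype=float)
    S = np.asarray(S, dtype=float)
    G = np.asarray(G, dtype=float)
    return 8.9974 * (Ev ** 0.2629 * (1.0 * S ** 0.074 + 0.5 * G ** 0.0424)) - 1.3307
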