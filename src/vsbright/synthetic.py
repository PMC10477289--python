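"""Synthetic stimuli and observers for exercising the fitting pipeline.

The generator emulates the structure of the magnitude-estimation study the
model targets: a 5 correlated-colour-temperature x 5 illuminance design
(2700-10,000 K by 45-2000 lx, 25 stimuli), 28 observers rating brightness on
a continuous 0-100 scale against an anchor stimulus defined as 100 (the
coldest/brightest cell by default), additive Gaussian response noise and
responses clipped to the scale.

Stimulus spectra are Planckian radiators (optionally with a 460 nm Gaussian
"blue boost" component) rescaled to the target illuminance.  Planck's law is
self-contained and reproduces the lever the model needs: blue content — and
with it the S and G ratios — rises monotonically with CCT at fixed
illuminance.  The CCT labels of boosted spectra are nominal (no CCT solver
here).  Real RGBW LED spectra are spikier than any Planckian curve, and real
observers are not exchangeable Gaussian noise around the model; passing
tests on these data shows the pipeline recovers what it simulates, not that
the model is true of human observers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .fitting import ExperimentDataset
from .model import BrightnessModelParams, evaluate_m, get_preset
from .sensitivities import SensitivityLibrary, default_library
from .signals import compute_signals, photopic_illuminance
from .spectra import CANONICAL_GRID, SpectralDistribution, planck_spectrum, write_spd_csv

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "planckian_spd",
    "blue_boost_gaussian",
    "make_design",
    "simulate_observers",
    "simulate",
    "write_outputs",
]

DEFAULT_CCTS = (2700.0, 3100.0, 4100.0, 5000.0, 10000.0)
DEFAULT_EVS = (45.0, 90.0, 470.0, 1000.0, 2000.0)

BOOST_PEAK_NM = 460.0
BOOST_SIGMA_NM = 20.0


def _cell_id(cct_K: float, ev_lux: float) -> str:
    return f"{cct_K:g}K_{ev_lux:g}lx"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    ``blue_boost`` maps CCT -> amplitude of a 460 nm (sigma 20 nm) Gaussian
    added to the Planckian curve, expressed as a fraction of the Planckian
    peak; a scalar applies to every CCT.  Default 0 (pure Planckian): the
    Planckian family already spans the S/G spread the design needs.
    ``noise_sd`` is the per-response observer noise in rating-scale units.
    """

    cct_list_K: tuple[float, ...] = DEFAULT_CCTS
    ev_list_lux: tuple[float, ...] = DEFAULT_EVS
    blue_boost: float | dict[float, float] = 0.0
    noise_sd: float = 5.0
    n_observers: int = 28
    anchor_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cct_list_K or not self.ev_list_lux:
            raise ValidationError("design lists must be non-empty")
        if any(e <= 0 for e in self.ev_list_lux):
            raise ValidationError("all Ev must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_observers < 1:
            raise ValidationError("n_observers must be >= 1")
        if self.anchor_id is not None and self.anchor_id not in self.design_ids():
            raise ValidationError(f"anchor_id {self.anchor_id!r} is not a design cell")

    def design_ids(self) -> tuple[str, ...]:
        return tuple(
            _cell_id(c, e) for c in self.cct_list_K for e in self.ev_list_lux
        )

    def resolved_anchor_id(self) -> str:
        """The anchor cell: explicit, else the coldest CCT at the highest Ev."""
        if self.anchor_id is not None:
            return self.anchor_id
        return _cell_id(max(self.cct_list_K), max(self.ev_list_lux))

    def boost_for(self, cct_K: float) -> float:
        if isinstance(self.blue_boost, dict):
            return float(self.blue_boost.get(cct_K, 0.0))
        return float(self.blue_boost)

    def to_dict(self) -> dict:
        """JSON-stable representation (tuples as lists, dict keys as str)."""
        d = dataclasses.asdict(self)
        d["cct_list_K"] = list(d["cct_list_K"])
        d["ev_list_lux"] = list(d["ev_list_lux"])
        if isinstance(d["blue_boost"], dict):
            d["blue_boost"] = {str(k): v for k, v in d["blue_boost"].items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def planckian_spd(
    cct_K: float, ev_lux: float, lib: SensitivityLibrary | None = None
) -> SpectralDistribution:
    """Planckian spectrum on the canonical grid, scaled to a target illuminance."""
    if not (1000.0 <= cct_K <= 20000.0):
        raise ValidationError(f"CCT {cct_K} K outside the supported range [1000, 20000]")
    if ev_lux <= 0:
        raise ValidationError("target illuminance must be positive")
    lib = lib or default_library()
    vals = planck_spectrum(cct_K, CANONICAL_GRID)
    spd = SpectralDistribution(CANONICAL_GRID, vals, name=_cell_id(cct_K, ev_lux))
    return spd.scaled(ev_lux / photopic_illuminance(spd, lib))


def blue_boost_gaussian(amplitude: float, grid: np.ndarray | None = None) -> np.ndarray:
    """The 460 nm (sigma 20 nm) boost component at unit Planckian peak."""
    g = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    return amplitude * np.exp(-0.5 * ((g - BOOST_PEAK_NM) / BOOST_SIGMA_NM) ** 2)


def make_design(
    config: GeneratorConfig, lib: SensitivityLibrary | None = None
) -> list[SpectralDistribution]:
    """Build the full-factorial stimulus set (CCT x Ev), each at its target Ev."""
    lib = lib or default_library()
    out: list[SpectralDistribution] = []
    for cct in config.cct_list_K:
        base = planck_spectrum(cct, CANONICAL_GRID)
        base = base / base.max()
        boost = blue_boost_gaussian(config.boost_for(cct))
        shape = base + boost
        for ev in config.ev_list_lux:
            spd = SpectralDistribution(CANONICAL_GRID, shape, name=_cell_id(cct, ev))
            out.append(spd.scaled(ev / photopic_illuminance(spd, lib)))
    return out


@dataclass(frozen=True)
class SyntheticDataset:
    """A simulated experiment: dataset rows plus generating spectra and truth."""

    dataset: ExperimentDataset
    spectra: dict[str, SpectralDistribution]
    truth: np.ndarray  # noise-free anchored model value per stimulus
    true_params: BrightnessModelParams
    config: GeneratorConfig


def simulate_observers(
    design: list[SpectralDistribution],
    true_params: BrightnessModelParams,
    config: GeneratorConfig,
    lib: SensitivityLibrary | None = None,
) -> SyntheticDataset:
    """Simulate anchored 0-100 ratings for every stimulus in the design.

    The noise-free model value of each stimulus is rescaled multiplicatively
    so the anchor stimulus sits exactly at 100 (the anchor defines the
    scale), then each observer response is ``clip(M + N(0, noise_sd), 0,
    100)``.  Means can therefore sit below 100 at the anchor under noise,
    as in real magnitude estimation.  Deterministic given ``config.seed``.
    """
    lib = lib or default_library()
    ids = [s.name or f"stim_{i}" for i, s in enumerate(design)]
    if len(set(ids)) != len(ids):
        raise ValidationError("design spectra must have unique names")
    sigs = [compute_signals(s, lib) for s in design]
    Ev = np.array([s.Ev for s in sigs])
    S = np.array([s.S for s in sigs])
    G = np.array([s.G for s in sigs])
    m = np.asarray(evaluate_m(true_params, Ev, S, G), dtype=float)

    anchor = config.resolved_anchor_id()
    if anchor not in ids:
        raise ValidationError(f"anchor stimulus {anchor!r} not present in the design")
    m_anchor = m[ids.index(anchor)]
    if m_anchor <= 0:
        raise ValidationError("anchor stimulus has non-positive model value; cannot anchor scale")
    truth = 100.0 * m / m_anchor

    rng = np.random.default_rng(config.seed)
    responses = truth[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(ids), config.n_observers)
    )
    np.clip(responses, 0.0, 100.0, out=responses)
    vsb_mean = responses.mean(axis=1)
    vsb_sd = (
        responses.std(axis=1, ddof=1) if config.n_observers > 1 else np.zeros(len(ids))
    )
    dataset = ExperimentDataset(
        ids=tuple(ids),
        Ev=Ev,
        S=S,
        G=G,
        vsb_mean=vsb_mean,
        vsb_sd=vsb_sd,
        n_observers=np.full(len(ids), config.n_observers),
    )
    return SyntheticDataset(
        dataset=dataset,
        spectra={i: s for i, s in zip(ids, design)},
        truth=truth,
        true_params=true_params,
        config=config,
    )


def simulate(
    config: GeneratorConfig | None = None,
    true_params: BrightnessModelParams | None = None,
    lib: SensitivityLibrary | None = None,
) -> SyntheticDataset:
    """Convenience: build the design and simulate observers in one call.

    Defaults: the 5 x 5 study design and the published final S+G model as
    the generating truth.
    """
    config = config or GeneratorConfig()
    true_params = true_params or get_preset("final_sg").params
    lib = lib or default_library()
    return simulate_observers(make_design(config, lib), true_params, config, lib)


def write_outputs(sdata: SyntheticDataset, outdir) -> dict:
    """Write dataset CSV, per-stimulus SPD CSVs and a JSON manifest.

    Returns the manifest dict (config echo, seed, truth parameters, config
    hash) that was written to ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sdata.dataset.to_csv(outdir / "dataset.csv")
    spd_dir = outdir / "spds"
    spd_dir.mkdir(exist_ok=True)
    for sid, spd in sdata.spectra.items():
        write_spd_csv(spd, spd_dir / f"{sid}.csv")
    manifest = {
        "config": sdata.config.to_dict(),
        "config_hash": sdata.config.config_hash(),
        "seed": sdata.config.seed,
        "true_params": sdata.true_params.to_dict(),
        "anchor_id": sdata.config.resolved_anchor_id(),
        "n_stimuli": len(sdata.dataset),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
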