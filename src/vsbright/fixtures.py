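"""Packaged per-stimulus tables of the reference experiment.

Two fixtures transcribe the published per-stimulus tables of the 25-light
study the model was built on (the raw spectra and observer ratings were
never deposited):

* ``table1`` — photometric/colorimetric descriptors: CCT (K), Duv,
  illuminance (lux), CIE 1931 chromaticity (x, y);
* ``table2`` — alpha-opic equivalent daylight illuminances in lux
  (melanopic, rhodopic, L-, M-, S-cone-opic) per stimulus.

``table2_signals`` bridges the EDI table to the model inputs: dividing an
alpha-opic EDI by the stimulus illuminance and multiplying by the daylight
reference's receptor ratio recovers the stimulus's S or G ratio without its
spectrum.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import ValidationError
from .sensitivities import SensitivityLibrary, default_library
from .signals import ratios_from_edi

__all__ = ["FIXTURE_NAMES", "load_fixture", "table2_signals"]

FIXTURE_NAMES = ("table1", "table2")


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table ('table1' or 'table2') as a DataFrame."""
    if name not in FIXTURE_NAMES:
        raise ValidationError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    ref = resources.files(__package__) / "data" / f"{name}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def table2_signals(lib: SensitivityLibrary | None = None) -> pd.DataFrame:
    """Model-input signals for the 25 reference stimuli, from the EDI fixture.

    Returns one row per stimulus with ``Ev_lux``, the recovered ``S_ratio``
    (from the S-cone-opic EDI) and ``G_ratio`` (from the melanopic EDI),
    plus the source EDI columns.
    """
    lib = lib or default_library()
    df = load_fixture("table2")
    df = df.assign(
        S_ratio=[
            ratios_from_edi(ev, edi, "s_cone", lib)
            for ev, edi in zip(df["Ev_lux"], df["sc_edi"])
        ],
        G_ratio=[
            ratios_from_edi(ev, edi, "melanopic", lib)
            for ev, edi in zip(df["Ev_lux"], df["mel_edi"])
        ],
    )
    return df[["id", "Ev_lux", "S_ratio", "G_ratio", "sc_edi", "mel_edi", "rh_edi", "lc_edi", "mc_edi"]]
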