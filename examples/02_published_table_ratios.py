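"""Recover model inputs from the packaged per-stimulus EDI table.

The reference experiment's spectra were never published, but its per-stimulus
alpha-opic equivalent daylight illuminances were.  Dividing an EDI by the
stimulus illuminance and multiplying by the daylight reference's own
receptor ratio recovers the S and G model inputs without the spectra.
The printout shows the recovered ratios for one stimulus per CCT at
maximum illuminance: S and G rise monotonically from 2700 K to 10,000 K.
"""

import vsbright as vb

df = vb.table2_signals().set_index("id")
print(f"{'id':8s} {'Ev (lx)':>8s} {'S':>8s} {'G':>8s}")
for sid in ("SPD_6", "SPD_17", "SPD_16", "SPD_10", "SPD_14"):  # 2700 -> 10,000 K at 2000 lx
    row = df.loc[sid]
    print(f"{sid:8s} {row['Ev_lux']:8.0f} {row['S_ratio']:8.4f} {row['G_ratio']:8.4f}")
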