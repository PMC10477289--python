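"""Evaluate the brightness model presets on a warm vs. cold light ramp.

Prints the predicted visually scaled brightness M of the final S+G model
for Planckian stimuli at 2700 K and 10,000 K across the illuminance range of
the reference design.  Two effects are visible: brightness grows strongly
compressively with illuminance (exponent 0.2629, so a 44-fold illuminance
step far less than 44-folds M), and at every level the cold, blue-rich
spectrum is predicted brighter than the warm one at identical lux.
"""

import vsbright as vb

params = vb.get_preset("final_sg").params
print(f"{'Ev (lx)':>8s} {'M @ 2700K':>10s} {'M @ 10000K':>11s}")
for ev in (45.0, 90.0, 470.0, 1000.0, 2000.0):
    row = []
    for cct in (2700.0, 10000.0):
        sig = vb.compute_signals(vb.planckian_spd(cct, ev), with_edi=False)
        row.append(vb.model_m(params, sig))
    print(f"{ev:8.0f} {row[0]:10.2f} {row[1]:11.2f}")
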