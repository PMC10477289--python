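"""Compute photoreceptor signals for a warm and a cold white light.

Builds two blackbody (Planckian) spectra at the same photopic illuminance
and prints the model's inputs for each: Ev (lux), the S-cone ratio S, the
ipRGC ratio G, and the alpha-opic equivalent daylight illuminances (EDI).
At equal illuminance the 10,000 K light carries several times more
short-wavelength power, so its S and G signals — and its EDIs — are much
larger: this spectral lever is what lets brightness models separate "blue
content" from plain illuminance.
"""

import vsbright as vb

for cct in (2700.0, 10000.0):
    spd = vb.planckian_spd(cct, ev_lux=500.0)
    sig = vb.compute_signals(spd)
    print(f"{cct:7.0f} K @ 500 lx:  Ev = {sig.Ev:7.2f} lx   S = {sig.S:.4f}   G = {sig.G:.4f}")
    print(f"           S-cone EDI = {sig.edi['s_cone']:7.2f} lx   melanopic EDI = {sig.edi['melanopic']:7.2f} lx")
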