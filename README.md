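# vsbright

Modelling human brightness perception under photopic (daytime) conditions
from photoreceptor signals of the light-source spectrum.

Standard photometry weights a spectrum with the luminous efficiency function
V(λ) and calls the result — illuminance in lux, luminance in cd/m² —
"physical brightness". Perceived brightness does not follow it: at equal
illuminance, white light with more short-wavelength ("blue") content looks
brighter, which implicates the S-cones and the melanopsin-containing ipRGCs
alongside the L+M luminance channel. `vsbright` implements a compressive
multi-channel model of that effect, the signal computations that feed it,
the staged fitting procedure used to calibrate it against anchored 0–100
magnitude-estimation ratings, and a synthetic-observer generator so the full
pipeline can be exercised end to end.

## The model

The predicted visually scaled brightness M of a stimulus is

```
M = a · [ Ev^γ · (α · S^δ₁ + β · G^δ₂) ] + b
```

with inputs computed from the absolute spectral irradiance E(λ) on
380–780 nm:

- `Ev = 683 ∫ E(λ) V(λ) dλ` — photopic illuminance (lux);
- `S  = ∫ E_rel s(λ) dλ / ∫ E_rel V(λ) dλ` — S-cone ratio of the relative
  spectrum E_rel (E scaled so its V-integral is 100);
- `G` — the analogous ipRGC (melanopic) ratio.

γ compresses the illuminance scale, δ₁/δ₂ compress the blue-channel
signals, α/β weight the channels, and (a, b) maps onto the rating scale.
Three presets are shipped: the published final S+G parameterisation
(`final_sg`: α=1, β=0.5, γ=0.2629, δ₁=0.074, δ₂=0.0424, a=8.9974,
b=−1.3307), the Fotios–Levermore equivalent-luminance form
(`fotios_1998`: M = a·Ev·(S/V)^0.24 + b) and the illuminance-only reduction
(`v_only`: M = a·Ev^γ + b).

Fitting uses variable projection ((a, b) solved by OLS at every candidate
point), a staged procedure mirroring the historical modelling sequence, a
seeded multistart bounded global optimizer, and a brute-force grid oracle
for verification. Alpha-opic equivalent daylight illuminance (EDI)
accounting bridges published per-stimulus EDI tables (packaged as fixtures)
to the model's S and G inputs.

The default sensitivity library uses clearly-labelled **synthetic analytic
stand-in curves** (Gaussian templates, plus a 6500 K Planckian daylight
reference) rather than the standardised CIE tabulations — see
`docs/methods.md` for exactly what that does and does not affect.

## Worked example

`examples/04_simulate_and_fit.py` simulates the 5 CCT × 5 illuminance
design (28 observers, anchored 0–100 scale, response noise SD 5) with the
final S+G model as ground truth, then refits it in stages:

```
stage                            rmse       r2   gamma   beta
step1_fotios                   7.8035   0.8797  1.0000  0.000
step1_v_only                   2.2386   0.9901  0.2403  0.000
step2_alpha1_beta0             0.9121   0.9984  0.2378  0.000
...
step4_global                   0.9121   0.9984  0.2378  0.000

best stage: step4_global  (true gamma 0.2629, recovered 0.2378)
```

The uncompressed Fotios form fits worst; every stage with a free
illuminance exponent lands near the true γ, and the global fit reaches the
noise floor of the simulated means (5/√28 ≈ 0.94 rating units). The other
examples print receptor signals for warm vs. cold light
(`01_photoreceptor_signals.py`: at 500 lx, S rises from 0.219 at 2700 K to
1.058 at 10,000 K), recover S/G from the packaged EDI table
(`02_published_table_ratios.py`) and tabulate model predictions
(`03_brightness_model.py`).

A thin CLI wraps the same functions:

```
vsbright simulate --seed 3 --out runs/sim
vsbright fit runs/sim/dataset.csv --mode staged --out runs/fit
vsbright evaluate runs/fit/params.json runs/sim/dataset.csv --out runs/metrics.json
vsbright compute-signals table2 -o signals.csv
```

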