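"""Simulate a magnitude-estimation experiment and refit the model.

Generates the 5 CCT x 5 illuminance design, simulates 28 observers rating
each stimulus on the anchored 0-100 scale (noise SD 5) with the published
final S+G model as ground truth, then runs the staged fitting procedure.
The printed ledger mirrors the historical modelling sequence: the
uncompressed Fotios-Levermore form fits worst, fixed channel-weight scans
with a compressive illuminance exponent do far better, and the global
multistart fit (alpha pinned at 1) is best — its RMSE approaches the
observer-noise floor of the simulated means, 5/sqrt(28) = 0.94 rating units.
"""

import vsbright as vb

sim = vb.simulate(vb.GeneratorConfig(noise_sd=5.0, seed=1))
ledger = vb.staged_fit(sim.dataset, seed=1)

print(f"{'stage':28s} {'rmse':>8s} {'r2':>8s} {'gamma':>7s} {'beta':>6s}")
for row in ledger:
    p = row.params
    print(f"{row.label:28s} {row.rmse:8.4f} {row.r2:8.4f} {p.gamma:7.4f} {p.beta:6.3f}")
best = ledger.best
print(f"\nbest stage: {best.label}  (true gamma 0.2629, recovered {best.params.gamma:.4f})")
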