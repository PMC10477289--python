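# Methods

## Model

Brightness is modelled as a compressive combination of three photoreceptor
signals of the stimulus spectrum:

    M = a · [ Ev^γ · (α · S^δ₁ + β · G^δ₂) ] + b

`Ev` is photopic illuminance (lux), `S` and `G` are the S-cone and ipRGC
(melanopic) ratios of the relative spectrum. The model assumes photopic
adaptation throughout: rod signals are saturated above roughly 10 cd/m² and
are not represented. Chromatic opponency (L−M) is likewise outside the
model — only the achromatic V-weighted channel and the two "blue-sensitive"
channels enter. M is the predicted mean rating on an anchored 0–100 scale
and is deliberately not clipped to that range; clipping is a property of
individual observer responses, not of the model, so it is applied only
inside the observer simulation.

Parameter roles, defaults and admissible ranges:

| parameter | meaning                          | range    | notes |
|-----------|----------------------------------|----------|-------|
| γ         | illuminance compression exponent | (0, 1.5] | final preset 0.2629; 1 = no compression |
| δ₁, δ₂    | S / G compression exponents      | [0, 1]   | δ = 0 collapses a channel term to its weight |
| α, β      | channel weights                  | ≥ 0, α+β > 0 | share a scale with `a` (see degeneracies) |
| a, b      | rating-scale transform           | free     | solved in closed form, never searched |

`Ev` enters in absolute lux. Any V-weighted absolute quantity (e.g. a
luminance) can be passed instead; the fitted `a` absorbs the unit choice.
No lux↔cd/m² conversion is provided, since it depends on scene reflectance.

## Signal computation

All integrals are rectangular (Riemann) sums on the canonical 1 nm grid
380–780 nm; inputs on other grids are linearly interpolated, zero-filled
outside their support. The rectangular rule makes the normalisation
identities exact: the relative spectrum (V-integral scaled to 100) always
integrates back to 100 within 1e-9, and the 683 and 100 factors cancel
exactly in the S and G ratios. They are nevertheless implemented, so each
intermediate matches its photometric definition. A spectrum whose V-weighted
integral is below 1e-12 raises a degenerate-spectrum error rather than
producing infinities.

Equivalent daylight illuminance (EDI): the receptor-weighted irradiance of
the stimulus divided by the receptor-weighted irradiance per lux of the
packaged daylight reference. Storing the reference pre-scaled to exactly
1 lux makes "EDI of the reference = its own illuminance" an identity. The
inverse bridge `(EDI / Ev) · r_ref(receptor)` recovers S or G exactly
(round-trip error < 1e-9 in tests), which is how the packaged per-stimulus
EDI table is turned into model inputs without the original spectra.

## Sensitivity curves — synthetic stand-ins

The standardised tabulations (the 1924 photopic V(λ) and the alpha-opic
action spectra, plus the D65 spectrum) are not redistributable from this
environment, so the default library generates analytic stand-ins at import
time, labelled synthetic in their docstrings:

- V(λ): Gaussian, peak 555 nm, σ = 41.9 nm — the width of the classic
  single-Gaussian approximation of V(λ); placing the peak exactly on the
  555 nm grid point makes V(555) = max V = 1 exact.
- S-cone-opic: Gaussian, peak 448 nm, σ = 30 nm.
- melanopic: Gaussian, peak 490 nm, σ = 40 nm.
- daylight reference: 6500 K Planckian radiator (stand-in for D65).

These reproduce the structure the model depends on — peak positions,
bandwidth ordering, and a monotone increase of S and G with blue content
(the synthetic design spans a 4.8-fold S-ratio spread from 2700 K to
10,000 K) — but not the standards' exact values. Consequently absolute S/G
ratios and EDIs computed here differ in detail from toolbox outputs based
on the official tables, and no test asserts third-decimal agreement with
published per-stimulus EDI values. Every identity the package tests
(normalisations, scale invariance, round trips, fit degeneracies, parameter
recovery) holds for any fixed, internally consistent curve set.

## Synthetic experiment generator

The generator emulates the anchored magnitude-estimation design the model
is calibrated on: a full factorial of 5 CCTs (2700, 3100, 4100, 5000,
10,000 K) × 5 illuminances (45, 90, 470, 1000, 2000 lx) = 25 stimuli and 28
observers. Stimuli are Planckian spectra rescaled to their target
illuminance (within 1e-6 relative); an optional 460 nm Gaussian component
(σ = 20 nm, amplitude per CCT as a fraction of the Planckian peak) can add
extra S/G spread, default 0 since the Planckian family already provides the
needed lever. CCT labels of boosted spectra are nominal — there is no CCT
solver here, by design.

Observer simulation: the noise-free model value of each stimulus is rescaled
multiplicatively so the anchor cell (default the coldest CCT at the highest
illuminance) sits at exactly 100 — the anchor defines the scale, as in the
real procedure. Each response is `clip(M + N(0, noise_sd), 0, 100)`;
noise is additive, Gaussian and homoscedastic (noise_sd default 5 rating
units, a plausible order for magnitude estimation rather than a measured
value), and a per-stimulus SD can be passed by simulating groups separately.
Means can fall below 100 at the anchor under noise; that is accepted, as in
real data. Everything is deterministic given the config seed.

What the generator does *not* emulate: spiky RGBW LED spectra,
inter-observer random effects, sequential adaptation dynamics, or
heteroscedastic response dispersion. Passing tests therefore demonstrate
that the pipeline recovers what it simulates — not that the model is true
of human observers.

## Fitting

(a, b) enter linearly, so they are profiled out by OLS at every candidate
nonlinear point (variable projection); consequence: after any fit the
regression of observed ratings on fitted M has slope 1 and intercept 0
(checked to 1e-9/1e-6). RMSE uses the mean over the actual number of
stimuli. If the bracket term is numerically constant the profiled solve
falls back to the intercept-only fit instead of failing, so optimizers can
traverse flat regions.

Optimizer: L-BFGS-B from Latin-hypercube starts (default 32 for the global
stage, 8 for constrained stages), seeded and fully deterministic. The
internal objective is the mean *squared* error — same argmin as the RMSE
but smooth at a perfect fit, where the square root's unbounded curvature
stalls quasi-Newton steps. Tolerances are set aggressively (ftol 1e-16) and
a Nelder–Mead polish refines the selected best point below the
finite-difference noise floor; this is what lets noise-free synthetic data
be recovered to RMSE < 1e-6 (measured ≈ 1e-14). L-BFGS-B's
"rounding-errors-dominate" stop is treated as convergence. Ties within
1e-10 RMSE are broken toward the lexicographically smallest
(γ, δ₁, δ₂, β). Bounds default to γ ∈ (0, 1.5], δ ∈ [0, 1], β ∈ [0, 2] —
generous relative to all published parameterisations.

Degeneracies are surfaced, not hidden. (α, β, a) and (cα, cβ, a/c) give
identical predictions, so the profiled RMSE depends on the weights only
through β/α — e.g. weights (0.5, 0.5) and (0.92, 0.92) give equal RMSE to
1e-9 — and the global fit pins α = 1 (overridable). As δ₁, δ₂ → 0 the
bracket degenerates toward the constant α + β and only products like
(α+β)·a remain identified; tests assert stability of the product across
seeds, never of the individual components.

The staged procedure runs: (1) the Fotios–Levermore form with only (a, b)
fitted, and the illuminance-only form with (γ, a, b); (2) a scan of nine
fixed (α, β) pairs from (1, 0) to (0, 1) with a tied exponent δ₁ = δ₂ and
free (γ, δ, a, b); (3) a δ refinement at the best pair with γ frozen;
(4) the global multistart fit. Each stage is seeded with the best feasible
point of the preceding stages (mapped onto α = 1 through the scale
degeneracy), making the step-to-step RMSE sequence non-increasing and the
global row the ledger minimum. The pure-G stage (α = 0) cannot be mapped
onto α = 1, so in principle a dataset could exist where the global stage
does not dominate it; with β free up to 2 this was never observed.

A brute-force grid oracle (exhaustive profiled evaluation over a Cartesian
parameter grid, exact argmin with the same tie-break) serves as the
independent check on the global optimizer: the multistart fit must never be
worse than the oracle on any tested dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run the 25-stimulus × 28-observer design —
the reference study's own size — with 1000-point random grids for algebraic
identities, a 6⁴ oracle grid over (β, γ, δ₁, δ₂), 200 replicates for the
standard-error contract of the simulator, and 32-start global fits; the
full suite completes in well under a minute. Recovery checks at observer
noise SD 2 land at prediction RMSE ≈ 0.1–0.3 rating units against the
noise-free truth and γ within ±0.01 of the generating 0.2629, comfortably
inside the asserted ±0.06.

## Known limitations

- The sensitivity curves are synthetic stand-ins (above); swap in official
  tabulations via a custom `SensitivityLibrary` for standards-grade EDI
  numbers.
- The packaged reference-experiment tables carry descriptors and EDIs only;
  the observer ratings were never published, so the reference study's own
  fit statistics cannot be recomputed — the pipeline's correctness is
  established on synthetic data instead.
- No uncertainty quantification on fitted parameters (none is defined for
  the procedure being mirrored); the multistart spread could be exposed if
  needed.
- The 0–100 anchored scale is treated as interval-valued; real magnitude
  estimation may violate that near the scale ends.
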