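# Methods

## Mechanistic soil–plant kinetics

The biogeochemical module treats one pollutant in a closed soil–plant
system with four pools. Soil loss and root uptake are first order in the
soil concentration *C*; the in-plant active pool is drained by first-order
metabolic transformation:

    dC/dt             = -m(t) (k + r_p) C
    dM_active/dt      =  m(t) r_p C - k_t M_active
    dM_metabolized/dt =  k_t M_active
    dM_degraded/dt    =  m(t) k C

The three processes are usually written as independent laws (decay
dC/dt = −kC, uptake M_p = r_p C, transformation rate k_t M_p); written that
way no mass balance holds and "amount removed by plants" is not a
well-defined quantity. We therefore couple them conservatively: uptake is a
flux out of the soil pool, transformation drains the tissue pool into a
cumulative metabolized pool. The static product r_p·C remains available as
`plant_uptake_amount` for the instantaneous-amount reading. The four
right-hand sides sum to zero, so ΣM = C₀ exactly; because the invariant is
linear, both integrators preserve it to machine precision and
`mass_balance_check` is a genuine integrator diagnostic, not a tautology.

Environmental dependence of the soil rates uses the standard Q10 form
times a capped-linear moisture limitation,
m = Q10^((T−T_ref)/10) · min(θ/θ_opt, 1). This is the simplest monotone
form with the right qualitative behaviour (rates roughly double per 10 °C;
dry soil slows reactions; saturation above the optimum). In-plant
transformation k_t is deliberately not environment-modified — plant
internal metabolism is buffered relative to soil processes.

Integration is fixed-step classical RK4, default dt = 0.01 h for short
oracle runs and dt = 1 h (the sampling interval) inside the scenario
generator, where rates of order 1e-3/h make the O(dt⁴) error negligible.
Forward Euler is retained solely so the convergence-order property
(error ratio ≈ 2 when dt halves, vs ≈ 16 for RK4) can be asserted.

## Synthetic monitoring scenarios

The generator emulates multi-year agricultural soil-monitoring records:
hourly timestamps; a latent pollutant trajectory from the kinetics above
driven by sinusoidal annual + daily temperature and moisture cycles with
Gaussian jitter; i.i.d. Gaussian observation noise on the pollutant
channel; i.i.d. Gaussian pH; a logistic plant-growth index whose growth is
suppressed in proportion to the remaining pollutant burden C/C₀; and MCAR
Bernoulli cell-level missingness (timestamps are never masked). All
randomness flows from a single `numpy` generator per call, so equal
configurations give byte-identical CSV output.

Default conditions: C₀ = 100 mg/kg, k = 5e-4/h, r_p = 2.5e-4/h,
k_t = 2e-3/h, observation noise 0.5 mg/kg, 5% missingness, 2000 hourly
steps. The effective decay rate k + r_p = 7.5e-4/h (half-life ≈ 38 d) was
chosen so a 2000 h record spans ≈ 1.5 half-lives: every chronological
segment — in particular the held-out test tail — still contains decay
signal rather than a flat noise floor, which is what a monitoring campaign
sized to observe remediation would look like. Observation noise of 0.5
mg/kg (0.5% of C₀) is typical of laboratory soil assays.

The survey generator draws per-plot fertility and growth values with
additive Gaussian effects (defaults ΔF = 0.15, growth gain 0.18 on a
baseline rate of 1.0, noise sd 0.01) and per-plot multinomial species
counts from fixed community weights. The baseline community is six species
with geometric-like proportions (H′ ≈ 1.53); remediation adds two species
and mixes 15% toward uniform abundances (H′ ≈ 1.69), emulating the
diversity recovery seen in restoration surveys.

What the generator does **not** emulate: spatial correlation between
plots/sites, autocorrelated sensor noise, non-random (e.g. outage-driven)
missingness, pollutant re-deposition or inputs, and pH feedback on
kinetics. Passing tests therefore demonstrate correctness of the method's
machinery and its behaviour under the assumed data-generating process, not
performance on real monitoring data.

## Preprocessing

Gap filling: linear interpolation in time for smooth drivers (temperature,
pH, moisture, growth index), nearest-neighbour for the pollutant series,
with equidistant ties resolved to the earlier observation (the causal
choice) and edge gaps held at the nearest observed value. Standardization
is Z-scoring with population (1/N) sd, fitted **only** on the rows feeding
the training windows and their targets — a train-only fit is the
non-leaky protocol even though it leaves validation/test means slightly
off zero. Windows are T = 24 steps (stride 1) with the next step's
pollutant value as target; the split is chronological 70/15/15 (floored
counts, remainder to test) to respect forecasting causality. Constant
columns are rejected by name rather than silently dropped.

## Learned modules

MLP: default 2×64 ReLU hidden layers, linear scalar head, He-style
scaled-uniform initialisation from the run seed, zero biases. Training is
minibatch MSE with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, bias-corrected)
or plain GD; defaults are learning rate 1e-3, batch 32, 100 epochs. A
small Gaussian input augmentation (sd 0.01 in standardized units) is
applied to training batches by default as a regulariser. No early stopping
by default — training runs the fixed epoch budget; per-epoch train and
validation losses are recorded so overfitting is visible.

Attention encoder: h = 4 heads of dimension d_k = 16 over the raw d input
features, softmax with max-subtraction for stability, last-time-step
pooling by default (mean optional), affine scalar head. There is no
positional encoding by default: the specified encoder contains none, which
makes it permutation-equivariant in time (a property the tests assert); a
sinusoidal encoding can be enabled where time-order sensitivity matters.
No layer norm, residuals, masking or multi-layer stacking — the encoder is
a single attention block by design. Both architectures share one training
loop and their analytic gradients are validated against central finite
differences (sigmoid activations for the MLP check, since finite
differences are undefined at ReLU kinks; attention is smooth throughout).

## Fusion and evaluation

Module predictions are combined as ŷ_t = Σ wᵢ yᵢ(t) with w on the
probability simplex, fitted by minimising validation MSE (SLSQP with
analytic gradient from the uniform start; the solution is compared against
every vertex and the better taken, making the "fusion ≤ best single
module" guarantee deterministic). If all modules predict identically the
problem is degenerate and uniform weights are returned with a warning.
Fusion operates on the standardized scale; the report also carries RMSE
mapped back to mg/kg.

The mechanistic fusion member never sees the true kinetic parameters: it
estimates the effective decay rate by OLS on log-concentration over the
training rows (concentrations floored at 1e-6 mg/kg before the log) and
forecasts each window's next step as C_last · exp(−k̂ Δt).

Metrics: MSE and RMSE as usual; accuracy is the fraction of points within
a tolerance band ε of the truth (default ε = 0.1 standardized units,
always reported alongside) because an exact-equality indicator is
degenerate for continuous predictions. Restoration indicators: ΔF =
F_after − F_before (mean over plots), PIPGR = 100·(g_after −
g_before)/g_before on mean growth rates, Shannon H′ = −Σ pᵢ ln pᵢ (natural
log) on abundances pooled over plots, zero-count species dropped before
normalisation.

## Problem sizes and numerical choices

Oracle simulations use horizon 24 h at dt = 0.01 (2401 steps); scenario
and end-to-end runs use 2000 hourly steps (1976 windows → 1383/296/297
split), 100 training epochs for both networks, and 200 survey plots of 200
individuals — sizes at which every stochastic acceptance margin holds with
a wide gap while a full run stays around a minute on one CPU. Tolerances:
1e-6 relative for integrator-vs-closed-form and mass balance, 1e-5
relative (L2, per parameter array) for gradient checks, 1e-12 for pure
linear-algebra identities.

## Known limitations

Single pollutant, single site, closed system (no inputs or transport); no
sorption/speciation or microbial dynamics; fixed-step integration (no
stiffness control — fine for the rate regimes here); single-block
attention without positional encoding cannot represent order-dependent
structure unless the optional encoding is enabled; fusion weights are
static (no time-varying or state-dependent weighting); tolerance-band
accuracy depends on the chosen ε and is reported with it.
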