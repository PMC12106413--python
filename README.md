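# biodann

Hybrid mechanistic–neural forecasting of soil pollutant dynamics during
phytoremediation, with quantitative assessment of ecological-restoration
outcomes. Intended for environmental-modelling researchers and
agricultural-monitoring engineers who want a tested, fully seeded desk-scale
implementation of the hybrid architecture on synthetic monitoring data.

## The model

Three forecasting modules produce next-step predictions of the soil
pollutant concentration from a sliding window of monitoring data
(pollutant, soil moisture, temperature, pH, plant growth index):

1. **Mechanistic kinetics.** Pollutant fate is a four-pool first-order
   system — soil concentration *C*, plant-tissue pool *M_active*,
   metabolized pool, degraded pool:

   ```
   dC/dt             = -m(t) (k + r_p) C
   dM_active/dt      =  m(t) r_p C - k_t M_active
   dM_metabolized/dt =  k_t M_active
   dM_degraded/dt    =  m(t) k C
   ```

   with soil degradation rate *k*, root uptake rate *r_p*, in-plant
   transformation rate *k_t* (all 1/h) and an environmental modifier
   *m(t) = Q10^((T−T_ref)/10) · min(θ/θ_opt, 1)*. The pools conserve the
   initial concentration *C₀*; integration is classical RK4 (Euler kept for
   convergence tests). As a forecaster, the module re-estimates the
   effective decay rate from training data by log-linear regression.

2. **Feed-forward network.** Layers *y^l = f(W^l x^{l−1} + b^l)* on the
   flattened window, trained by backpropagation with minibatch Adam or
   plain gradient descent *θ ← θ − η ∇L(θ)* (MSE loss, η = 0.001,
   batch 32, 100 epochs by default).

3. **Multi-head attention encoder.** Per head, *Q = XW^Q*, *K = XW^K*,
   *V = XW^V* and *A = softmax(QKᵀ/√d_k)V*; head outputs are concatenated
   and mapped by *W^O*, pooled over time, and fed to an affine prediction
   head. Trained with the same loop and validated against
   finite-difference gradients.

The final forecast is the convex fusion *ŷ_t = Σᵢ wᵢ yᵢ(t)* with weights
*wᵢ ≥ 0, Σwᵢ = 1* optimised on validation MSE — so the fusion can never do
worse on validation data than the best single module.

Evaluation covers forecast quality (MSE, RMSE, tolerance-band accuracy) and
restoration indicators: soil-fertility change ΔF, percentage increase in
plant growth rate (PIPGR), and Shannon diversity H′ = −Σ pᵢ ln pᵢ.

A seeded synthetic-data module generates the monitoring scenarios
(mechanistic decay under seasonal/daily forcing, observation noise, MCAR
missingness) and before/after restoration surveys, retaining ground truth
for recovery tests.

## Worked example

```bash
biodann ablate --seed 42 --steps 2000 --epochs 100 --out report.json
```

runs the full pipeline — generate a 2000-hour scenario, interpolate gaps,
Z-score on train-only statistics, window (T = 24) and split 70/15/15, train
both networks, fuse with the mechanistic forecaster, evaluate — and prints

```
modules=['biogeochem', 'dnn', 'attention'] mse=0.00096 accuracy=1.000
weights={'biogeochem': 0.695, 'dnn': 0.0, 'attention': 0.305}
```

The fused test MSE (standardized units) of 0.00096 is ~6× below the
mean-predictor baseline of 0.0056; accuracy is the fraction of test points
within ε = 0.1 standardized units of the truth; the weights show the fusion
leaning on the mechanistic forecaster with an attention correction. The
JSON report also carries the restoration indicators from the synthetic
survey (ΔF ≈ 0.15, PIPGR ≈ 18%, H′ 1.52 → 1.71), per-module test MSEs, and
both training-loss histories.

The same steps are available as individual commands (`biodann generate`,
`simulate`, `preprocess`, `train`, `evaluate`) or as library functions
(`biodann.run_experiment`, etc.); see the module docstrings.

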