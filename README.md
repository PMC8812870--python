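# ssenet

Spike-and-slab elastic net logistic classifiers with spatially structured
inclusion priors, fit by EM coordinate descent.

## The problem

Binary classification from image-like measurements — per-region cortical
thickness, tau-PET SUVR summaries, or voxel/vertex-level maps — routinely has
more predictors than subjects, strong spatial correlation among predictors,
and heavily imbalanced outcomes (often ~85% of subjects are controls).
Penalized logistic regression (ridge, lasso, elastic net) stays identifiable
in this regime and performs automatic feature selection, but treats every
predictor exchangeably: it ignores the prior knowledge that relevant
predictors tend to cluster spatially.

`ssenet` implements a family of Bayesian penalized logistic classifiers that
add that spatial knowledge to the variable-selection mechanism, together with
the cross-validation protocol, classification metrics, and a fully synthetic
2-D-lattice simulation benchmark for evaluating them.

## The model

For subjects i = 1..N with binary outcomes y_i and predictors X_i,

    logit P(y_i = 1) = β₀ + X_i β.

Each coefficient gets a spike-and-slab elastic-net mixture prior

    β_j | γ_j ~ EN(β_j | 0, S_j),    S_j = (1 − γ_j) s₀ + γ_j s₁,

where γ_j ∈ {0, 1} indicates whether predictor j is "in" the model
(slab scale s₁ > spike scale s₀ > 0) and EN blends a quadratic and an
absolute-value component with weight ξ ∈ [0, 1] (ξ = 1 lasso-type, ξ = 0
ridge-type, ξ = 0.5 elastic net).  The inclusion indicators have Bernoulli
priors with probabilities θ_j; optionally the logits ψ_j = logit(θ_j) receive
an intrinsic autoregressive (IAR) prior over a spatial adjacency graph,

    log p(ψ | τ) ∝ −(τ²/2) Σ_{(i,j) ∈ edges} (ψ_j − ψ_i)²,   τ = 1,

so that a predictor is more likely to be selected when its neighbors are.
Six variants are exposed by name: `lasso`, `en` (single penalty, no mixture),
`ssl`, `ssen` (spike-and-slab, shared θ), and `ssl-iar`, `ssen-iar`
(spike-and-slab with IAR-smoothed θ).

Fitting alternates an E-step (posterior inclusion probabilities
p_j = E[γ_j | β_j, θ_j] and effective penalties ν_j = p_j/s₁ + (1 − p_j)/s₀)
with an M-step (cyclic coordinate-descent solution of the ν-weighted
penalized logistic likelihood, then the θ update — an exact damped-Newton
maximization of the IAR-regularized Bernoulli objective in the spatial case).
Hyperparameters (s₀, s₁) are chosen by stratified k-fold cross-validation,
minimizing held-out deviance; classification at the 0.5 threshold is
summarized by accuracy, sensitivity, specificity, PPV, NPV, MCC and F1.

## Worked example

Simulate one dataset from the large-effect benchmark condition (40×40
lattice, N = 250, a disc of 49 non-zero coefficients of 0.10, predictor mean
−1, correlation 0.9^d, ~14% event rate), fit the spatially informed model,
and cross-validate it:

```python
import ssenet as ss

scenario = ss.large_effect(seed=7)
ds = ss.generate_dataset(scenario)
data = ss.DesignData.from_arrays(ds.X, ds.y)
graph = ss.lattice_adjacency(40, 40)
prior = ss.PriorSpec.from_model_name("ssen-iar", s0=0.1, s1=2.0)

fit = ss.fit_ssen(data, prior, graph)
print(f"EM iterations: {fit.n_iter}, converged: {fit.converged}")
print(f"non-zero coefficients: {int((fit.beta != 0).sum())} of {data.n_predictors}")

cv = ss.kfold_cv(data, prior, graph, k=5, seed=7)
for key in ("deviance", "auc", "mse", "sn", "sp", "mcc", "f1"):
    print(f"{key:>8}: {cv.metrics[key]:.3f}")
```

Output:

```
EM iterations: 5, converged: True
non-zero coefficients: 49 of 1600
deviance: 70.731
     auc: 0.977
     mse: 0.042
      sn: 0.552
      sp: 0.982
     mcc: 0.630
      f1: 0.653
```

The fit keeps 49 of 1600 predictors.  Held-out discrimination is high
(AUC 0.977) while sensitivity at the 0.5 threshold is moderate (0.552) — with
a ~14% event rate the classifier must be very confident before a predicted
probability crosses 0.5.  MCC (0.630) summarizes the whole confusion matrix
and is the most informative single number under this imbalance.

A command-line interface mirrors the library: `ssenet simulate`,
`ssenet fit`, `ssenet cv`, `ssenet study`, and `ssenet metrics`
(see `ssenet --help`).

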