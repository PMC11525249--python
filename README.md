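# mnrm — modeling faking and response styles in questionnaire data

`mnrm` implements the **multidimensional nominal response model (MNRM)** for
Likert-type self-report data, with latent dimensions for substantive traits,
extreme response style (ERS), and **faking** (deliberate socially desirable
responding).  It is aimed at psychometricians studying response biases in
high-stakes assessments: it provides the full simulation machinery to study
when modeling faking pays off, stochastic-approximation and quadrature
estimators for the model, MAP person scoring, and the recovery and
effect-size statistics used to evaluate them.

## The model

The probability that person *n* with latent vector **θ**\_n ∈ ℝ^D chooses
category *k* ∈ {0, …, K} on item *i* is a divide-by-total multinomial
logistic function

p(Y\_ni = k | **θ**\_n) = exp((**α**\_i ∘ **s**\_ik)′ **θ**\_n + γ\_ik) / Σ\_m exp((**α**\_i ∘ **s**\_im)′ **θ**\_n + γ\_im)

with item slopes **α**\_i, category intercepts γ\_ik (γ\_i0 = 0), and *fixed*
scoring weights s\_idk that encode how strongly category *k* expresses
dimension *d* at item *i*.  Substantive traits use equally spaced weights
(0, 1, …, 6 on a seven-point scale), ERS marks the endpoint categories
((6, 0, 0, 0, 0, 0, 6)), and the faking dimension uses item-specific
**desirability trajectories** — the shape of social desirability over the
rating scale, one of five prototypes (monotonically increasing,
nonmonotonically increasing, inverted-U, nonmonotonically decreasing,
monotonically decreasing).  The latent dimensions are multivariate normal
with mean **0** and a correlation matrix **Σ**.

Two model variants matter throughout: the model *ignoring* faking
(traits + ERS) and the model *accounting for* faking (traits + ERS + faking).
Both are fitted to the same data; their comparison quantifies what modeling
faking buys in terms of person-parameter recovery (Fisher-z correlations with
the truth) and latent trait-correlation recovery (bias and RMSE over the ten
trait pairs).

## Worked example

```python
import numpy as np
from mnrm import (SimulationCondition, simulate_dataset, make_model_spec,
                  build_weight_matrices, fit, FitOptions, score_map,
                  person_recovery, correlation_bias)

# One replication: composition 3 (mixed desirability trajectories),
# 6 items per trait, n = 1000, ERS present, high faking impact.
cond = SimulationCondition(3, 6, 1000, True, "high", replication=0)
responses, truth = simulate_dataset(cond, master_seed=1)

# Fit the model that accounts for faking (weights contaminated with noise,
# emulating pilot-study approximations of the true desirability weights).
spec = make_model_spec(6, include_ers=True, include_faking=True)
weights = build_weight_matrices(spec, trajectories=truth.trajectories,
                                noise_scale=0.5, seed=1)
result = fit(responses, spec, weights, FitOptions(seed=1, mh_draws=3))
theta = score_map(responses, result)

rec = person_recovery(theta.values[:, :5], truth.persons.values[:, :5])
print(f"person recovery r = {rec.mean_back_transformed:.3f}")
print(f"trait-correlation bias = "
      f"{correlation_bias(result.sigma, truth.latent.covariance):+.3f}")
```

Output:

```
person recovery r = 0.812
trait-correlation bias = +0.033
```

The recovery correlation of about .81 and small correlation bias are what a
model that accounts for faking achieves here; refitting without the faking
dimension (`include_faking=False`) drops recovery to .56 and inflates the
trait correlations by about +.36, the signature distortion of unmodeled
faking.

## Command-line interface

The `mnrm` command exposes the pipeline: `mnrm simulate` (one replication +
truth manifest), `mnrm fit` / `mnrm score` (estimation and MAP scoring from
CSV/JSON artifacts), `mnrm classify` (desirability-rating histograms →
trajectory types and empirical faking weights), `mnrm evaluate` (generalized
η² effect-size table from tidy results), and `mnrm run-study` (the full
factorial study from a YAML config; resumable).

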