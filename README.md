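# weakident

Weak-form input–output parameter estimation and **(e, q) practical
identifiability** for partially observed ODE models.

## The problem

Biological models are usually observed through a single state: a drug
concentration in blood (but not in tissue), an infected count (but not the
susceptible pool). Even when such a model is *structurally* identifiable —
the input–output equation obtained by eliminating the unobserved states has
an injective coefficient map — noisy, sparse data may not support reliable
estimation in practice. Assessing that *practical* identifiability by
simulation requires thousands of repeated fits, which is only feasible with
a fast estimator.

This package implements that workflow for two benchmark systems:

* **Blood–tissue diffusion** (observed blood concentration x₁):

      ẋ₁ = −k₁₂x₁ + k₂₁x₂ − Vₑx₁/(1+x₁),   ẋ₂ = k₁₂x₁ − k₂₁x₂

  whose input–output equation has identifiable coefficients
  w₁ = k₂₁Vₑ, w₂ = k₁₂+k₂₁, w₃ = k₁₂+k₂₁+Vₑ.

* **SIR epidemic** (observed infected count I): Ṡ = −βSI, İ = βSI − αI,
  Ṙ = αI, with the recovery rate α known and the transmission rate β
  estimated after substituting R(t) = α∫₀ᵗ I ds and S = N − I − R.

The input–output equation, written as ∑ᵢ dⁱ/dtⁱ[Hᵢ(y)] = (∑ᵢ dⁱ/dtⁱ[Cᵢ(y)])·w,
is integrated against compactly supported test functions φₖ; integration by
parts moves all derivatives onto the φₖ, so no derivative of noisy data is
ever taken. Discretizing the integrals yields a linear system **G**w ≈ **b**
with one row per test function. Because the same noisy data enter G and b
(an errors-in-variables problem), the solver iterates generalized least
squares with a covariance propagated analytically from the observation
noise, in the spirit of weak-form estimation of nonlinear dynamics (WENDy),
and reports Wald confidence intervals from the final covariance.

Practical identifiability is then summarized by two dimensionless ratios:

* **e** — observation error ratio: σ / RMS(Ω), noise scale over signal scale;
* **q** — estimator error ratio: √MSE(ŵᵢ) / |wᵢ|.

A model is **(e, q)-identifiable** if, for data at error ratio e, every
parameter satisfies MSE(ŵᵢ) ≤ (q·|wᵢ|)². The package computes Monte-Carlo
(e, q) maps, per-parameter relative errors and interval coverage, parameter
sweeps, and an output-error (forward-solve nonlinear least squares)
baseline for comparison.

## A worked example

```python
import numpy as np
from weakident import (
    blood_config, build_experiment, NoiseSpec, apply_noise,
    assemble, wendy_solve,
)

model, system, times, truth, tf, w_true = build_experiment(blood_config())
obs = apply_noise(truth.observed, times,
                  NoiseSpec("additive_gaussian", e=0.01, seed=7))
fit = wendy_solve(assemble(system, obs, tf), system, obs, tf)
print("w_true =", w_true)
print("w_hat  =", np.round(fit.w_hat, 3))
print("95% CI =", np.round(fit.ci_low, 3), np.round(fit.ci_high, 3))
```

prints

```
w_true = [ 6.  6. 12.]
w_hat  = [ 5.764  7.783 11.275]
95% CI = [ 4.877  5.905 10.398] [ 6.652  9.661 12.152]
```

At a 1% observation error ratio, 40 observations of the blood compartment
pin down w₁ and w₃ to a few percent while w₂ is noticeably harder — the
first sign of the identifiability loss that grows with noise. Ensemble
studies are one call away:

```python
from weakident import sir_study, min_q
summary = sir_study([0.5], d=1000, seed=0)[0]   # e = 50% additive noise
print(f"beta rel. error {summary.relative_error[0]:.2%}, "
      f"min q {min_q(summary):.2%}, coverage {summary.coverage[0]:.0%}")
# beta rel. error 0.68%, min q 0.85%, coverage 94%
```

so the SIR transmission rate remains (50, 10)-identifiable — even with
noise at half the signal's RMS the estimator error ratio stays near 1%.

The same studies run from the shell:

```bash
weakident eqmap --model sir --reps 200 --out results/sir
weakident fit --model blood_tissue --reps 500 --out results/blood
weakident compare-oe --model sir --reps 25 --out results/oe
```

Each command writes CSV tables plus a `summary.json` echoing the config,
seed and a config hash; a given (config, seed) pair reproduces identical
numbers.

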