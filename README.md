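# pombesize

Cell-size homeostasis in fission yeast: an exact stochastic simulator,
closed-form stationary size distributions, and a parameter-inference pipeline
for single-cell lineage data.

## The problem

Fission yeast (*Schizosaccharomyces pombe*) does not grow exponentially
through its cell cycle. A cycle has three phases: exponential **elongation**
at rate g₀, a **septation** plateau while the division septum forms, and a
brief, faster **reshaping** burst at rate g₁ > g₀ as the new cell ends round
off. Lineage measurements (one daughter tracked through tens of divisions,
sampled every few minutes) show a *bimodal* distribution of cell size — the
left peak is cells in elongation, the right peak cells in septation and
reshaping.

`pombesize` implements a stochastic model that captures this. A cell passes
through N effective cell-cycle stages; the first N₀ belong to elongation, the
last N₁ to reshaping, and the middle N−N₀−N₁ to septation. The stage
transition rate is size-dependent,

    k -> k+1  at rate  a·V(t)^α,

where α is the strength of size control: α→0 is a timer, α=1 an adder, α→∞ a
sizer (under symmetric division the conventional regression slope of division
size on birth size is β = 2^(1−α)). At division the tracked daughter receives
a fraction R of the mother's size: fixed at p (**model I**) or drawn from a
Beta(pν, qν) distribution with mean p (**model II**).

The key analytic fact is a scaling property: the generalized size Y = V^α
behaves as an adder, so the increment of Y over each phase is gamma
(Erlang) distributed — mean M₀ = N₀g₀α/a in elongation, M₁ = N₁g₁α/a in
reshaping — independent of birth size. This yields closed forms for

* the Laplace transform of the stationary lineage distribution of V^α,
  `F(λ) = K ∫_λ^∞ f(u) ⟨e^(−uV_d^α)⟩ du`, inverted numerically (FFT-free
  oscillatory quadrature of the characteristic-function form) to p(x);
* the birth-size transform (an infinite product of hypoexponential factors
  for model I; a recursively defined power series, analytically continued by
  a distributional fixed-point iteration, for model II);
* the N→∞ limit: a mixture of two 1/x pieces and an atom with phase weights
  (w₀, w_s, w₁) equal to the stationary fractions of time per phase;
* birth/division-size correlations: ρ(V_b^α, V_d^α) = p^α for model I, and a
  beta-moment generalization for model II.

The inference pipeline recovers the full parameter vector
(g₀, g₁, a, α, N, N₀, N₁, p, ν) from lineage time courses in five steps:
partition-ratio fit → α from correlation matching → added-size moments from
birth-size statistics → per-generation three-stage least-squares growth fits
→ stage numbers by matching the analytic size density to the data histogram,
with lineage-level bootstrap errors.

## Worked example

```python
import numpy as np
from pombesize import (reference_params, generate_dataset, GrowthModelEstimator,
                       limit_distribution, conventional_beta, alpha_to_beta,
                       extract_generations)

# fitted parameters for minimal medium at 28 C, deterministic partitioning
params = reference_params("EMM_28C", "I")

# phase weights and landmark sizes in the zero-noise limit
lim = limit_distribution(params)
print(f"w0={lim.w0:.3f} ws={lim.ws:.3f} w1={lim.w1:.3f}")
print(f"v_b={lim.v_b:.2f} v_m={lim.v_m:.2f} v_d={lim.v_d:.2f} um")

# synthetic lineage data (3-min sampling, 2% measurement noise) and a re-fit
ds = generate_dataset(params, n_lineages=200, generations=60, seed=1)
est = GrowthModelEstimator(model="I", random_state=0).fit(ds)
print(f"alpha={est.alpha_:.2f} N={est.N_:.1f} N0={est.N0_:.1f} N1={est.N1_:.2f}")
print(f"g0={est.g0_:.3f} g1={est.g1_:.3f} a={est.a_:.3f} p={est.p_:.3f}")

vb, vd = [], []
for tc in ds.lineages:
    for g in extract_generations(tc):
        vb.append(g.V_b); vd.append(g.V_d)
ctrl = conventional_beta(np.column_stack([vb, vd]))
print(f"conventional slope={ctrl.beta:.3f} (R2={ctrl.r_squared:.2f}) "
      f"vs 2^(1-alpha)={alpha_to_beta(est.alpha_):.3f}")
```

prints

```
w0=0.762 ws=0.194 w1=0.044
v_b=7.05 v_m=14.22 v_d=15.37 um
alpha=1.87 N=15.9 N0=10.4 N1=0.89
g0=0.214 g1=0.414 a=0.039 p=0.466
conventional slope=0.527 (R2=0.06) vs 2^(1-alpha)=0.547
```

Reading this: cells spend 76% of the cycle elongating, 19% in septation, 4%
reshaping; birth/septation/division lengths are ~7.1/14.2/15.4 μm. The re-fit
on 200 synthetic lineages recovers the generating parameters (α=1.87 vs 1.77,
g₀ exactly, g₁=0.41 vs 0.41), identifying sizer-like control (α ≈ 1.8). The
conventional regression gives the same qualitative verdict (slope ≈ 0.53,
near 2^(1−α)) but with R² ≈ 0.06 — which is why distribution matching, not
that regression, drives the inference.

A CLI wraps the same functionality:

```bash
pombesize generate --config params.yaml --lineages 1500 --generations 60 --seed 1 --out data.csv
pombesize fit --in data.csv --model I --seed 1 --out estimate.json
pombesize compare --in data.csv
```

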