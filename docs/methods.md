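# Methods

## Model

A cell is described by its size V (length, μm) and a discrete stage
k ∈ {1,…,N}. Within a stage the size evolves deterministically — exponential
growth dV/dt = g₀V in stages 1…N₀ (elongation), no growth in stages
N₀+1…N−N₁ (septation), exponential growth at g₁ > g₀ in the last N₁ stages
(reshaping) — and the stage advances stochastically with rate a·V^α. After
stage N the cell divides; the tracked daughter restarts at V_b′ = R·V_d with
R ≡ p (model I) or R ~ Beta(pν, (1−p)ν) (model II). The process is a
piecewise deterministic Markov process; the simulator samples it exactly
rather than integrating the master equation.

The size-dependent hazard gives the model its central scaling property:
while traversing a growing stage at rate g, the increment of the
*generalized size* Y = V^α is exponential with mean αg/a regardless of the
size at stage entry (the time-rescaling of the hazard by growth is exactly
cancelled in the Y variable). Phase increments are therefore gamma:
Δ₀ ~ Gamma(N₀, mean M₀ = N₀g₀α/a) and Δ₁ ~ Gamma(N₁, mean M₁ = N₁g₁α/a); the
septation duration, at constant size V_s, is Gamma(N−N₀−N₁, rate a·V_s^α).
This is what the fast phase-level sampler draws; the stage-level sampler
draws every stage and waiting time explicitly and is kept as a brute-force
oracle (the two agree by KS test in the suite). Stage counts are real
numbers throughout: the gamma forms generalize the integer-shape Erlang case
exactly, which matters because fitted stage numbers are fractional.

## Parameters

| name | meaning | units | typical fitted range |
|------|---------|-------|----------------------|
| g₀ | elongation growth rate | 1/h | 0.21–0.47 |
| g₁ | reshaping growth rate | 1/h | 0.38–1.67 |
| a | stage-transition rate constant | μm⁻^α/h | 0.03–1.3 |
| α | size-control strength | — | 1.1–2.1 (sizer-like) |
| N, N₀, N₁ | effective stage numbers | — | N 16–55, N₁ ≈ 1–3.4 |
| p | mean partition ratio | — | 0.46–0.48 |
| ν | partition sample size (model II) | — | ≈ 200–270 |

Reference parameter sets for seven growth conditions (two media × several
temperatures) ship in `pombesize.conditions`, together with the observed
summary statistics they were fitted to.

## Analytics

**Transforms.** With Y = V^α, the stationary lineage distribution satisfies
F(λ) = ⟨e^(−λY)⟩ = K ∫_λ^∞ f(u)·D(u) du, where f is the three-piece phase
weighting function (f(0)=1; the N₁=0, N=N₀ case reduces to the
single-phase form), D(u) = ⟨e^(−uV_d^α)⟩ = b(u)·A(u) is the division-size
transform, b the hypoexponential added-size factor, and
A(u) = ⟨e^(−uV_b^α)⟩ the birth-size transform. For model I,
A(u) = ∏_{n≥1} b(p^{αn}u), truncated at the smallest k with p^{αk} < 10⁻¹²
(a warning fires if that needs more than 500 factors). All powers, beta
functions and Pochhammer symbols go through logs.

**Model II series and its continuation.** Under beta partitioning D(u) is a
power series Σaₙuⁿ with a₀=1, aₙ = (1−cₙ)⁻¹ Σ_{m<n} a_m c_m b_{n−m}, where
bₙ are the Taylor coefficients of b and cₙ = E[R^{αn}] are beta-moment
ratios. The series has a finite radius of convergence, 1/max(A₀, A₁) (the
nearest pole of b, with A_i = M_i/N_i), while the quadrature and the Fourier
inversion need D far beyond it — and near the radius the partial sums cancel
catastrophically in double precision. The implementation therefore keeps the
series as a verified construction (it matches the continuation to ~10⁻⁶
inside the radius, and the pure-series evaluation path signals
non-convergence explicitly) and evaluates A in production by iterating the
stationary fixed point A(z) = E_R[A(zR^α)·b(zR^α)] on a ray grid (real or
imaginary axis), with the expectation over R taken by Gauss–Legendre nodes
mapped through the beta quantile function and cubic-spline interpolation
between grid points. Unrolling the iteration K_max times reproduces the
exact expectation over K_max generations of partition ratios; it reduces to
the model I infinite product as ν→∞.

**Density inversion.** Differentiating F gives
∫ y·p̃(y) e^(−iλy) dy = K f(iλ) D(iλ) ≡ G(λ), with p̃ the density of Y. The
inverse Fourier integral (1/π)∫₀^∞ Re[G(λ)e^{iλy}]dλ is evaluated by
trapezoid quadrature: the λ step obeys the Nyquist condition for the largest
grid point of y, and the cutoff grows geometrically until |G| < 10⁻¹⁰|G(0)|.
Back-transforming, p(x) = αx^{α−1}p̃(x^α). Densities are reported with their
raw trapezoid integral (no silent renormalization); an inversion whose
negative lobes exceed 10⁻³ of the peak raises instead of clipping silently.
On the suite's parameter sets the raw integral is within 10⁻³ of 1 and the
total-variation distance to 10⁶-sample simulations is ≲ 0.005.

**Zero-noise limit.** As N→∞ at fixed r₀=N₀/N, r₁=N₁/N, M₀, M₁ the cycle
becomes deterministic: v_d = ((M₀+M₁)/(1−p^α))^{1/α}, v_b = p·v_d,
v_m = ((M₀+M₁p^α)/(1−p^α))^{1/α} (this parse is the one consistent with
v_m^α − v_b^α = M₀, an identity the tests assert). Phase durations are
T₀ = (αr₀/M₀)·ln(v_m/v_b), T_s = (1−r₀−r₁)/v_m^α, T₁ = (αr₁/M₁)·ln(v_d/v_m);
the normalized durations are the phase weights w₀, w_s, w₁, and the density
is w₀/(x·ln(v_m/v_b)) on [v_b,v_m] plus an atom w_s at v_m plus
w₁/(x·ln(v_d/v_m)) on [v_m,v_d]. The atom is reported as (location, weight)
and only smoothed — with a Gaussian kernel matched to the comparison
histogram's bin width — when a plot or TV comparison requires it.

**Correlations and moments.** Model I: ρ(V_b^α, V_d^α) = p^α, independent of
the growth pattern. Model II: with X = V_b^α and Y = X + Δ (Δ independent of
X), Cov(X,Y) = Var(X), so ρ = σ_X/σ_Y; the variances follow from the
stationary recursion X =_d R^α(X+Δ) through the factors K₁ = m₁/(1−m₁),
K₂ = m₂/(1−m₂) with m_j = E[R^{jα}]:
Var(X) = [(2K₁+1)K₂−K₁²](M₀+M₁)² + K₂[M₀²/N₀+M₁²/N₁] and
Var(Y) = Var(X) + [M₀²/N₀+M₁²/N₁]. Note the direction: partition noise
*raises* the transformed-size correlation above p^α (it adds identical
variance to Cov and Var(X)) — verified against simulation — even though the
untransformed ρ(V_b, V_d) of model II sits slightly below model I's, which
the simulations also reproduce. ρ → p^α as ν → ∞ in all cases.

**Birth size.** The exact density inverts the product/fixed-point transform.
A closed-form approximation keeps only the n=1 factor (good when p^{2α} is
negligible): a generalized-gamma density in x^α times a confluent
hypergeometric factor ₁F₁(N₁, N₀+N₁, (β₀−β₁)x^α) with β₀ = N₀/(M₀p^α) and
β₁ = N₁/(M₁p^α) — the second exponent must be β₁; writing both as β₀ is a
frequent transcription slip. At α ≈ 1.8–2 the dropped factors still shift
the mean of V_b^α by p^{2α}(M₀+M₁) ≈ 0.8 sd, so the sup-norm gap to the
exact density is tens of percent of the peak; it falls below 5% only for
α ≳ 6 (or small p). Treat the closed form as a strong-control asymptotic,
not a general-purpose density.

## Synthetic data generator

`generate_dataset` emulates microfluidic lineage experiments: independent
stationary lineages (50 burn-in generations discarded), sizes sampled every
3 minutes, measurement noise multiplicative log-normal with CV 2% (the
default; the underlying model has no measurement-error term), units μm and
hours. Study-scale datasets are 1500 lineages × 60 generations with
generation times of ~1.9–4.1 h depending on condition. What it does *not*
emulate: cell death and lineage dropout, segmentation artefacts (e.g.
clipped cell tips that bias the apparent partition ratio), the area→length
conversion of image-derived data, NETO bilinearity within the elongation
phase, and any non-stationarity across the experiment. Passing recovery
tests on these data therefore demonstrate correctness of the estimators
under the model's own assumptions plus small multiplicative noise, not
robustness to those real-data artefacts.

## Inference pipeline

1. **Partition ratio**: ratios R_k = V_b(k+1)/V_d(k) from generation
   boundaries; p is their mean (model I) or, with ν, a beta maximum-likelihood
   fit started at the method-of-moments value (model II). A near-zero ratio
   variance returns the deterministic sentinel.
2. **α**: unique root (bisection after a sign-change scan over a geometric
   grid on [0.05, 10]; monotonicity is checked empirically, not assumed) of
   sample ρ(V_b^α, V_d^α) = theory(α). A root pinned at a bracket edge is
   flagged, not extrapolated.
3. **Added-size moments**: S = M₀+M₁ and B = M₀²/N₀+M₁²/N₁ by inverting the
   birth-moment formulas with the sample mean/variance of V_b^α.
4. **Growth rates**: each generation's time course is fitted to
   exponential–constant–exponential with continuity at both change points;
   the change points are searched exhaustively on the sampling grid and, for
   each pair, the fit is linear in (log V_s, g₀, g₁) and evaluated in O(1)
   by prefix sums. Ties (e.g. purely exponential generations) resolve to the
   latest change points. g₀ is the mean of the per-generation elongation
   rates over at most 5000 randomly chosen generations (seeded) — the mean
   is stable long before that.
5. **Stage numbers**: minimize Σᵢ (p(xᵢ) − p̂(xᵢ))² over (N, N₀, N₁), where
   p̂ is a 100-equal-width-bin histogram density of all sampled sizes and p
   the analytic density at the bin centers, with (a, g₁) re-derived for every
   candidate from (S, B, g₀) by solving N₀s₀+N₁s₁=S, N₀s₀²+N₁s₁²=B for
   s_i = αg_i/a (root with s₁ > s₀ > 0; infeasible candidates are skipped,
   and reported if nothing is feasible). Search: coarse lattice
   (N ∈ 2…150 step 5, N₀ step 3, N₁ step 1) → exhaustive refinement around
   the best cell (ties to smallest N, then N₀, then N₁) → one Nelder–Mead
   polish over real-valued stage numbers. The polish is on by default:
   reshaping stage numbers sit near 1, where the integer lattice quantizes
   N₁ — and through it g₁ — too coarsely (a ~±20% g₁ effect). For model II
   the coarse lattice is ranked with the cheap deterministic-partitioning
   density and the exact beta-partitioning objective scores only the top 60
   candidates plus the refinement, with a reduced-resolution fixed-point
   factor; final reported densities always use full resolution. The
   objective compares two densities, so it is invariant to the histogram
   normalization convention.
6. **Bootstrap**: 50 repetitions × 50 lineages drawn with replacement
   (lineage-level, matching how such data are collected); the SD across
   repetitions is the reported error. Repetition searches are restricted to
   ±25% around the point estimate's N to keep the cost linear.

On study-scale synthetic data (EMM 28 °C truth) the pipeline recovers α
within ~+0.08, N within ~−7%, g₁ within ~+15%. The residual bias is real
and understood: birth sizes are read at the first sample after division (up
to one 3-minute interval late) and division sizes at the last sample before
it, which inflates the apparent partition ratio by ~1.5% and propagates into
α; the 2% measurement noise broadens the histogram and pulls N slightly
down. These are properties of the data convention, shared with the
experimental setting, not of the estimator.

## Numerical choices

* Sizes in μm, rates in 1/h everywhere; the CLI takes the sampling interval
  in minutes (3 by default).
* Infinite-product truncation at p^{αk} < 10⁻¹²; fixed-point iteration depth
  equals the product truncation; series truncation stops when a term falls
  below 10⁻¹² of the partial sum and raises by order 400 otherwise.
* Fourier grids: Δλ = π/(1.15·y_max); λ-cutoff at |G| < 10⁻¹⁰|G(0)|.
* Quadrature for normalization constants: 6000-point trapezoid on [0, u*]
  with u* found by geometric growth until the integrand is below 10⁻¹⁴ of
  its origin value.
* Degenerate inputs: A₀/A₁ raise (not NaN) when the corresponding stage
  count is zero; N₁=0 reduces step 5's rate solve to one unknown and the
  reported g₁ is undefined (NaN from `estimate_rates`; a placeholder 2g₀ in
  assembled parameter sets where M₁=0 makes it inert).
* Seeds are explicit arguments everywhere; nothing touches global RNG state.

## Limitations

* The conventional-slope mapping β = 2^(1−α) is meaningful only for
  symmetric division and small size variability; the package reports it for
  comparison, never uses it for inference.
* The pure-series evaluation of the model II transform cannot cover
  realistic parameter ranges in double precision (see above); use the
  default continuation route.
* Model II recovery of (α, ν) from data is noticeably noisier than model I's
  — the correlation-matching equation conditions worse when partition noise
  and added-size noise trade off.
* Densities are tabulated on user grids; grids that clip the support
  understate the integral, which is reported rather than hidden.
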