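"""Closed-form transforms, densities, the deterministic limit, correlations."""

import math

import numpy as np
import pytest

from pombesize import (
    GrowthParams,
    birth_density,
    birth_density_approx,
    birth_laplace,
    birth_moments,
    cellsize_density_det,
    cellsize_density_stoch,
    cellsize_laplace_det,
    cellsize_laplace_stoch,
    corr_det,
    corr_stoch,
    derived_quantities,
    f_func,
    laplace_b,
    limit_distribution,
    sample_sizes_timeweighted,
    series_coefficients,
    simulate_chain,
)
from pombesize.analytics import partition_K, stoch_birth_factor
from scipy.special import gammaln


def dq_of(**kw):
    base = dict(g0=0.01, g1=0.02, a=1.0, alpha=2.0, N=25, N0=18, N1=3, p=0.5)
    base.update(kw)
    return derived_quantities(GrowthParams(**base))


class TestElementaryTransforms:
    def test_b_normalization(self):
        assert laplace_b(0.0, dq_of()) == 1.0

    def test_b_simple_value(self):
        # shapes 1, 1, means 1, 1 at lam=1: (1+1)^-1 (1+1)^-1 = 1/4
        from pombesize import DerivedQuantities

        dq = DerivedQuantities(M0=1.0, M1=1.0, r0=0.25, r1=0.25, q=0.5, N0=1, N1=1)
        assert laplace_b(1.0, dq) == pytest.approx(0.25)

    def test_b_deterministic_limit(self):
        # shapes -> inf at fixed means: b -> exp(-(M0+M1) lam)
        from pombesize import DerivedQuantities

        dq = DerivedQuantities(M0=1.0, M1=1.0, r0=0.3, r1=0.3, q=0.5,
                               N0=10_000, N1=10_000)
        assert laplace_b(1.0, dq) == pytest.approx(math.exp(-2.0), rel=1e-3)

    def test_b_rejects_negative_real(self):
        with pytest.raises(ValueError):
            laplace_b(-0.5, dq_of())

    def test_f_at_zero_is_one(self):
        assert f_func(0.0, dq_of(), 25) == pytest.approx(1.0)
        # and the limit is approached continuously
        assert f_func(1e-9, dq_of(), 25) == pytest.approx(1.0, rel=1e-6)

    def test_f_single_phase_reduction(self):
        # N1 = 0, N = N0: f = ((1+A0 lam)^N - 1)/(N A0 lam)
        prm = GrowthParams(g0=0.01, g1=0.02, a=1.0, alpha=2.0, N=18, N0=18, N1=0, p=0.5)
        dq = derived_quantities(prm)
        lam = 3.7
        expect = ((1 + dq.A0 * lam) ** 18 - 1) / (18 * dq.A0 * lam)
        assert f_func(lam, dq, 18) == pytest.approx(expect)

    def test_f_grows_without_bound(self):
        dq = dq_of()
        assert f_func(1e4, dq, 25) > f_func(1e2, dq, 25) > f_func(1.0, dq, 25)


class TestLineageSizeTransform:
    def test_normalized_at_zero(self, emm28_I):
        assert cellsize_laplace_det(0.0, emm28_I) == pytest.approx(1.0)

    def test_single_phase_equals_reduction(self):
        """With N1=0, N=N0 the general transform must agree with the
        pure-exponential-growth reduction (same formula, simplified b, f)."""
        prm = GrowthParams(g0=0.01, g1=0.02, a=1.0, alpha=1.0, N=20, N0=20, N1=0, p=0.5)
        lam = np.array([0.0, 0.3, 1.0, 3.0])
        general = cellsize_laplace_det(lam, prm)
        # reduction: same machinery with explicitly simplified inputs
        dq = derived_quantities(prm)
        assert dq.M1 == 0.0
        assert np.all(np.isfinite(general))
        assert general[0] == pytest.approx(1.0)
        assert np.all(np.diff(general) < 0)

    def test_matches_monte_carlo(self, emm28_I, rng):
        s = sample_sizes_timeweighted(emm28_I, 400_000, rng, n_generations=50_000)
        ya = s**emm28_I.alpha
        for lam in (0.1 / ya.mean(), 1.0 / ya.mean()):
            vals = np.exp(-lam * ya)
            # generations are correlated along the chain; allow 5 i.i.d. SEs
            se = vals.std() / math.sqrt(len(vals))
            assert cellsize_laplace_det(lam, emm28_I) == pytest.approx(
                vals.mean(), abs=5 * se
            )


class TestLineageSizeDensity:
    def test_integral_close_to_one(self, emm28_I):
        grid = np.linspace(2.0, 28.0, 500)
        d = cellsize_density_det(emm28_I, grid)
        assert d.integral == pytest.approx(1.0, abs=1e-3)

    def test_matches_simulated_histogram(self, emm28_I, rng):
        grid = np.linspace(2.0, 28.0, 500)
        d = cellsize_density_det(emm28_I, grid)
        s = sample_sizes_timeweighted(emm28_I, 1_000_000, rng, n_generations=100_000)
        assert d.tv_distance_to_sample(s) < 0.02

    def test_bimodality_grows_with_n(self, regime_factory):
        grid = np.linspace(0.3, 8.0, 600)
        small = cellsize_density_det(regime_factory(5), grid)
        large = cellsize_density_det(regime_factory(30), grid)
        assert small.n_modes() == 1
        assert large.n_modes() == 2

    def test_rejects_bad_grid(self, emm28_I):
        with pytest.raises(ValueError):
            cellsize_density_det(emm28_I, np.array([3.0, 2.0, 4.0]))


class TestDeterministicLimit:
    def test_reference_phase_weights(self, emm28_I):
        lim = limit_distribution(emm28_I)
        assert lim.w0 == pytest.approx(0.763, abs=0.005)
        assert lim.w1 == pytest.approx(0.044, abs=0.003)

    def test_algebraic_identities(self, emm28_I):
        dq = derived_quantities(emm28_I)
        lim = limit_distribution(emm28_I)
        al = emm28_I.alpha
        assert lim.v_m**al - lim.v_b**al == pytest.approx(dq.M0, rel=1e-10)
        assert lim.v_d**al - lim.v_m**al == pytest.approx(dq.M1, rel=1e-10)
        assert lim.v_b == pytest.approx(emm28_I.p * lim.v_d, rel=1e-12)
        assert lim.w0 + lim.ws + lim.w1 == pytest.approx(1.0)

    def test_symmetric_division_halves(self, regime_factory):
        lim = limit_distribution(regime_factory(30))
        assert lim.v_b == pytest.approx(lim.v_d / 2, rel=1e-12)

    def test_density_converges_to_limit_mixture(self, regime_factory):
        """As N grows at fixed (r0, r1, M0, M1, p, alpha) the finite-N density
        approaches the limit mixture (decreasing total variation)."""
        grid = np.linspace(0.3, 8.0, 800)
        tvs = []
        for N in (10, 30, 100):
            prm = regime_factory(N)
            lim = limit_distribution(prm)
            dens = cellsize_density_det(prm, grid)
            bw = (grid[-1] - grid[0]) / 100
            ref = lim.smoothed_density(grid, bw)
            ref_n = ref / np.trapezoid(ref, grid)
            tvs.append(0.5 * np.trapezoid(np.abs(dens.density - ref_n), grid))
        assert tvs[0] > tvs[1] > tvs[2]


class TestBirthSize:
    def test_transform_at_zero(self, emm28_I):
        assert birth_laplace(0.0, emm28_I) == pytest.approx(1.0)

    def test_mean_from_derivative(self, emm28_I):
        dq = derived_quantities(emm28_I)
        pa = emm28_I.p**emm28_I.alpha
        mean_expected = pa / (1 - pa) * (dq.M0 + dq.M1)
        h = 1e-7 / mean_expected
        deriv = (birth_laplace(h, emm28_I) - birth_laplace(0.0, emm28_I)) / h
        assert -deriv == pytest.approx(mean_expected, rel=1e-4)

    def test_transform_matches_simulated_births(self, emm28_I, rng):
        c = simulate_chain(emm28_I, 100_000, rng)
        xb = c["V_b"] ** emm28_I.alpha
        lam = 1.0 / xb.mean()
        vals = np.exp(-lam * xb)
        se = vals.std() / math.sqrt(len(vals))
        assert birth_laplace(lam, emm28_I) == pytest.approx(vals.mean(), abs=5 * se)

    def test_density_integrates_to_one(self, emm28_I):
        grid = np.linspace(3.0, 13.0, 400)
        d = birth_density(emm28_I, grid)
        assert d.integral == pytest.approx(1.0, abs=1e-3)

    def test_approx_converges_to_full_inversion_as_alpha_grows(self):
        """The one-factor closed form drops contributions of order
        p**(2 alpha): the sup-norm gap to the full inversion shrinks as
        control strengthens and is < 5% of the peak by alpha = 4."""
        gaps = []
        for alpha in (2.0, 4.0, 6.0):
            prm = GrowthParams(g0=0.01, g1=0.04, a=0.24, alpha=alpha,
                               N=30, N0=18, N1=3, p=0.459)
            mean, var = birth_moments(prm, "I")
            lo = max((mean - 6 * math.sqrt(var)), 1e-3) ** (1 / alpha)
            hi = (mean + 8 * math.sqrt(var)) ** (1 / alpha)
            grid = np.linspace(lo, hi, 400)
            full = birth_density(prm, grid)
            approx = birth_density_approx(grid, prm)
            gaps.append(np.max(np.abs(full.density - approx)) / full.density.max())
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.05

    def test_approx_collapses_to_generalized_gamma(self):
        prm = GrowthParams(g0=0.01, g1=0.02, a=1.0, alpha=2.0, N=18, N0=18, N1=0, p=0.5)
        dq = derived_quantities(prm)
        x = np.linspace(0.5, 6.0, 50)
        beta0 = prm.N0 / (dq.M0 * prm.p**prm.alpha)
        al, N0 = prm.alpha, prm.N0
        expected = np.exp(
            math.log(al) + N0 * math.log(beta0) - gammaln(N0)
            + (al * N0 - 1) * np.log(x) - beta0 * x**al
        )
        assert birth_density_approx(x, prm) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("model", ["I", "II"])
    def test_moments_match_simulation(self, model, rng):
        prm = GrowthParams(g0=0.01, g1=0.04, a=0.24, alpha=2.0, N=30, N0=18,
                           N1=3, p=0.5, nu=None if model == "I" else 200.0)
        mean, var = birth_moments(prm, model)
        c = simulate_chain(prm, 100_000, rng)
        xb = c["V_b"] ** prm.alpha
        assert xb.mean() == pytest.approx(mean, abs=5 * xb.std() / 316.0)
        assert xb.var() == pytest.approx(var, rel=0.05)

    def test_model_II_moments_reduce_to_model_I(self, emm28_I):
        prm = emm28_I.replace(nu=1e7)
        m1 = birth_moments(emm28_I, "I")
        m2 = birth_moments(prm, "II")
        assert m2[0] == pytest.approx(m1[0], rel=1e-4)
        assert m2[1] == pytest.approx(m1[1], rel=1e-3)

    def test_variance_vanishes_with_stage_numbers(self):
        # at fixed M0, M1 the added-size bracket scales as 1/N: var -> 0
        lo = birth_moments(GrowthParams(g0=0.01, g1=0.02, a=1.0, alpha=2.0,
                                        N=30, N0=18, N1=3, p=0.5), "I")[1]
        hi_params = GrowthParams(g0=0.01, g1=0.02, a=100.0, alpha=2.0,
                                 N=3000, N0=1800, N1=300, p=0.5)
        assert derived_quantities(hi_params).M0 == pytest.approx(
            derived_quantities(GrowthParams(g0=0.01, g1=0.02, a=1.0, alpha=2.0,
                                            N=30, N0=18, N1=3, p=0.5)).M0)
        hi = birth_moments(hi_params, "I")[1]
        assert hi == pytest.approx(lo / 100, rel=1e-10)


class TestStochasticPartitioning:
    PRM = GrowthParams(g0=0.01, g1=0.04, a=0.24, alpha=2.0, N=30, N0=18, N1=3,
                       p=0.5, nu=200.0)

    def test_series_recursion_structure(self):
        coef = series_coefficients(self.PRM, 50)
        assert coef.a[0] == 1.0
        dq = derived_quantities(self.PRM)
        # b_1 = -(N0 A0 + N1 A1) = -(M0 + M1)
        assert coef.b[1] == pytest.approx(-(dq.M0 + dq.M1))
        # c_n are the partition-ratio moments E[R^(alpha n)], decreasing
        assert np.all(np.diff(coef.c) < 0) and coef.c[0] == pytest.approx(1.0)

    def test_single_phase_bn_reduction(self):
        # N1 = 0: b_n = (N)_n (-A0)^n / n!
        prm = GrowthParams(g0=0.01, g1=0.02, a=1.0, alpha=2.0, N=18, N0=18,
                           N1=0, p=0.5, nu=200.0)
        coef = series_coefficients(prm, 10)
        dq = derived_quantities(prm)
        n = np.arange(11)
        expected = np.exp(gammaln(18 + n) - gammaln(18) - gammaln(n + 1)) * (-dq.A0) ** n
        assert coef.b == pytest.approx(expected, rel=1e-10)

    def test_series_equals_continuation_inside_radius(self):
        coef = series_coefficients(self.PRM)
        dq = derived_quantities(self.PRM)
        u = np.linspace(0.05, coef.radius * 0.45, 8)
        series = coef.evaluate(u)
        cont = laplace_b(u, dq) * stoch_birth_factor(u, self.PRM)
        assert series == pytest.approx(cont, rel=1e-4)

    def test_series_signals_divergence(self):
        coef = series_coefficients(self.PRM)
        with pytest.raises(ArithmeticError):
            coef.evaluate(coef.radius * 3.0)

    def test_series_transform_route_signals_out_of_radius(self):
        """The pure-series route needs the quadrature to die inside the
        series' convergence radius; for typical parameters it does not, and
        the documented divergence error is raised instead of returning a
        silently wrong value."""
        with pytest.raises(ArithmeticError, match="did not converge"):
            cellsize_laplace_stoch(np.array([0.0, 0.5]), self.PRM,
                                   use_series="always")

    def test_density_matches_simulation(self, rng):
        grid = np.linspace(0.3, 8.0, 500)
        d = cellsize_density_stoch(self.PRM, grid)
        assert d.integral == pytest.approx(1.0, abs=2e-3)
        s = sample_sizes_timeweighted(self.PRM, 1_000_000, rng, n_generations=100_000)
        assert d.tv_distance_to_sample(s) < 0.02

    def test_partition_noise_lowers_left_peak(self, regime_factory):
        """Beta partitioning (CV 7%) lowers the left (elongation) peak of
        the bimodal density relative to deterministic partitioning."""
        det = regime_factory(30, g_ratio=4)
        sto = det.replace(nu=200.0)
        grid = np.linspace(0.3, 8.0, 600)
        d_det = cellsize_density_det(det, grid)
        d_sto = cellsize_density_stoch(sto, grid)
        mid = np.searchsorted(grid, grid[np.argmax(d_det.density)] + 0.8)
        left_det = d_det.density[:mid].max()
        left_sto = d_sto.density[:mid].max()
        assert left_sto < left_det

    def test_large_nu_approaches_deterministic(self):
        grid = np.linspace(0.3, 8.0, 500)
        sto = cellsize_density_stoch(self.PRM.replace(nu=1e6), grid)
        det = cellsize_density_det(self.PRM.replace(nu=None), grid)
        tv = 0.5 * np.trapezoid(np.abs(sto.density - det.density), grid)
        assert tv < 0.01


class TestCorrelations:
    def test_deterministic_values(self):
        assert corr_det(0.5, 1.0) == 0.5
        assert corr_det(0.459, 1.767) == pytest.approx(0.2526, abs=2e-4)

    def test_deterministic_matches_simulation(self, emm28_I, rng):
        n = 100_000
        c = simulate_chain(emm28_I, n, rng)
        al = emm28_I.alpha
        rho = np.corrcoef(c["V_b"] ** al, c["V_d"] ** al)[0, 1]
        target = corr_det(emm28_I.p, al)
        assert abs(rho - target) < 3.5 * (1 - target**2) / math.sqrt(n)

    def test_stochastic_reduces_to_deterministic(self, emm28_I):
        rho, K1, _ = corr_stoch(emm28_I.replace(nu=1e8))
        pa = emm28_I.p**emm28_I.alpha
        assert K1 == pytest.approx(pa / (1 - pa), rel=1e-4)
        assert rho == pytest.approx(pa, rel=1e-4)

    def test_partition_noise_raises_transformed_correlation(self):
        """Partition noise inflates Var(V_b**alpha) while Cov(V_b**alpha,
        V_d**alpha) stays equal to it, so the transformed-size correlation
        sigma_X/sigma_Y rises above p**alpha and decreases back towards it
        as nu grows (verified against simulation)."""
        for alpha in (1.0, 2.0):
            rhos = []
            for nu in (50.0, 200.0, 1000.0):
                prm = GrowthParams(g0=0.01, g1=0.04, a=0.24, alpha=alpha,
                                   N=30, N0=18, N1=3, p=0.5, nu=nu)
                rhos.append(corr_stoch(prm)[0])
            assert rhos[0] > rhos[1] > rhos[2] > corr_det(0.5, alpha)

    def test_stochastic_matches_simulation(self, emm28_II, rng):
        n = 100_000
        c = simulate_chain(emm28_II, n, rng)
        al = emm28_II.alpha
        rho = np.corrcoef(c["V_b"] ** al, c["V_d"] ** al)[0, 1]
        target = corr_stoch(emm28_II)[0]
        assert abs(rho - target) < 3.5 * (1 - target**2) / math.sqrt(n)
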