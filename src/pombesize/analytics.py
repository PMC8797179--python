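"""Closed-form distributions and correlations for the cell-size model.

Everything here is built on the scaling property of the model: under control
strength ``alpha`` the transformed size ``Y = V**alpha`` behaves as an adder,
so its stationary lineage distribution has an explicit Laplace transform

    F(lam) = K * integral_lam^inf f(u) * A(u) du,

where ``f`` encodes the time-weighting over the three growth phases and
``A(u) = <exp(-u V_b**alpha)>`` is the birth-size transform: an infinite
product of hypoexponential factors ``b`` under deterministic partitioning,
and a power series with recursively defined coefficients under beta
partitioning.  Densities are recovered by Fourier inversion of the
characteristic-function form ``G(lam) = K f(i lam) A(i lam)``, which equals
the Fourier transform of ``y * ptilde(y)`` with ``ptilde`` the density of
``Y``; finally ``p(x) = alpha x**(alpha-1) ptilde(x**alpha)``.

All products and Pochhammer/beta ratios are computed in log space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, interpolate
from scipy import stats
from scipy.special import betaln, exp1, gammaln, hyp1f1

from .params import DerivedQuantities, GrowthParams, derived_quantities

__all__ = [
    "DensityOnGrid",
    "LimitMixture",
    "SeriesCoefficients",
    "laplace_b",
    "f_func",
    "birth_laplace",
    "birth_factor",
    "cellsize_laplace_det",
    "cellsize_density_det",
    "cellsize_laplace_stoch",
    "cellsize_density_stoch",
    "limit_distribution",
    "birth_density",
    "birth_density_approx",
    "birth_moments",
    "corr_det",
    "corr_stoch",
    "mean_cellsize",
    "calibrate_mean_size",
]

PRODUCT_TOL = 1e-12  # truncate the infinite product where p**(alpha k) < tol
SERIES_TOL = 1e-12
SERIES_NMAX = 400


# ---------------------------------------------------------------------------
# containers


@dataclass
class DensityOnGrid:
    """A probability density tabulated on a strictly increasing size grid.

    ``integral`` is the raw trapezoid integral before any renormalization;
    it should be within ~1e-3 of 1 when the grid covers the bulk of the mass.
    """

    x: np.ndarray
    density: np.ndarray
    integral: float
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        header = "; ".join(f"{k}={v}" for k, v in self.meta.items())
        arr = np.column_stack([self.x, self.density])
        np.savetxt(path, arr, delimiter=",", header=f"{header}\nsize,density", comments="# ")

    def tv_distance_to_sample(self, sample: np.ndarray, bins: int = 100) -> float:
        """Total-variation distance between this density and a sample histogram."""
        edges = np.linspace(self.x[0], self.x[-1], bins + 1)
        hist, _ = np.histogram(sample, bins=edges, density=True)
        # renormalize the histogram to the samples inside the grid range
        frac = np.mean((sample >= edges[0]) & (sample <= edges[-1]))
        hist = hist * frac
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = np.interp(centers, self.x, self.density)
        width = edges[1] - edges[0]
        return 0.5 * float(np.sum(np.abs(dens - hist)) * width)

    def n_modes(self, rel_height: float = 0.02) -> int:
        """Count local maxima exceeding ``rel_height`` of the global peak."""
        d = self.density
        peak = d.max()
        idx = np.where((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:]) & (d[1:-1] > rel_height * peak))[0]
        # merge plateau-adjacent maxima
        return int(np.sum(np.diff(idx, prepend=-10) > 1))


@dataclass(frozen=True)
class LimitMixture:
    """Zero-noise (N -> inf) limit of the lineage size distribution.

    Sizes collapse onto the deterministic cycle ``v_b -> v_m -> v_d``; the
    distribution is a mixture of a ``1/x`` part on [v_b, v_m] (elongation,
    weight w0), an atom at v_m (septation, weight ws), and a ``1/x`` part on
    [v_m, v_d] (reshaping, weight w1).  T0, Ts, T1 are proportional to the
    phase durations.
    """

    v_b: float
    v_m: float
    v_d: float
    w0: float
    ws: float
    w1: float
    T0: float
    Ts: float
    T1: float

    def continuous_density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        m0 = (x >= self.v_b) & (x <= self.v_m)
        out[m0] = self.w0 / ((math.log(self.v_m) - math.log(self.v_b)) * x[m0])
        m1 = (x >= self.v_m) & (x <= self.v_d)
        out[m1] += self.w1 / ((math.log(self.v_d) - math.log(self.v_m)) * x[m1])
        return out

    def smoothed_density(self, x, bandwidth: float) -> np.ndarray:
        """Continuous part plus the v_m atom smoothed with a Gaussian kernel
        of standard deviation ``bandwidth`` (match it to the histogram bin
        width when comparing with sampled data)."""
        x = np.asarray(x, dtype=float)
        atom = self.ws * np.exp(-0.5 * ((x - self.v_m) / bandwidth) ** 2) / (
            bandwidth * math.sqrt(2 * math.pi)
        )
        return self.continuous_density(x) + atom


@dataclass
class SeriesCoefficients:
    """Taylor coefficients of the division-size transform under beta partitioning.

    ``sum a_n z**n = <exp(-z V_d**alpha)> = b(z) A(z)``: ``a_0 = 1`` and
    ``a_n = (1/(1-c_n)) sum_{m=0}^{n-1} a_m c_m b_{n-m}``, where ``b_n`` are
    the Taylor coefficients of the hypoexponential factor ``b(lam)``
    (alternating Pochhammer sums over A0, A1) and
    ``c_n = B(alpha n + p nu, q nu)/B(p nu, q nu)`` are the moments
    ``E[R**(alpha n)]`` of the partition ratio.  The series converges only up
    to the nearest pole of ``b`` (``|z| < 1/max(A0, A1)``); beyond it the
    transform is continued by the fixed-point iteration of
    :class:`_StochBirthFactor`.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    radius: float

    @property
    def n_max(self) -> int:
        return len(self.a) - 1

    def evaluate(self, z, tol: float = SERIES_TOL):
        """Evaluate sum a_n z**n with adaptive truncation.

        Raises if the terms have not fallen below ``tol`` times the partial
        sum by the last available order (series divergence at this z).
        """
        z = np.asarray(z)
        scalar = z.ndim == 0
        z = np.atleast_1d(z)
        out = np.zeros(z.shape, dtype=complex)
        term = np.ones(z.shape, dtype=complex)
        converged = np.zeros(z.shape, dtype=bool)
        with np.errstate(over="ignore", invalid="ignore"):
            for n, an in enumerate(self.a):
                t = an * term
                out = out + t
                converged |= np.abs(t) < tol * np.maximum(np.abs(out), 1e-300)
                term = term * z
        if not converged.all():
            raise ArithmeticError(
                "series for the division-size transform did not converge at the "
                f"requested points by order {self.n_max} (|z| beyond the "
                f"convergence radius ~{self.radius:.3g})"
            )
        out = out.real if np.isrealobj(np.asarray(z)) else out
        return out[0] if scalar else out


# ---------------------------------------------------------------------------
# elementary transforms


def laplace_b(lam, dq: DerivedQuantities):
    """Laplace transform of the generalized added size over a full cycle.

    ``b(lam) = (1 + M0 lam/N0)**(-N0) * (1 + M1 lam/N1)**(-N1)``; a factor
    with zero stage count equals 1.  Accepts real (lam >= 0) or complex
    arguments; computed in log space.
    """
    lam = np.asarray(lam)
    if np.isrealobj(lam) and np.any(lam < 0):
        raise ValueError("laplace_b requires lam >= 0 on the real axis")
    out = np.zeros(lam.shape, dtype=complex if np.iscomplexobj(lam) else float)
    if dq.N0 > 0:
        out = out - dq.N0 * np.log(1 + dq.A0 * lam)
    if dq.N1 > 0:
        out = out - dq.N1 * np.log(1 + dq.A1 * lam)
    res = np.exp(out)
    return res if res.ndim else res[()]


def f_func(lam, dq: DerivedQuantities, N: float):
    inp = np.asarray(lam)
    lamc = np.atleast_1d(inp.astype(complex))
    ns_frac = (N - dq.N0 - dq.N1) / N
    small = np.abs(lamc) < 1e-14
    lam_safe = np.where(small, 1.0, lamc)
    pow1 = np.exp(dq.N1 * np.log(1 + dq.A1 * lamc)) if dq.N1 > 0 else np.ones_like(lamc)
    if dq.N0 > 0:
        pow0 = np.exp(dq.N0 * np.log(1 + dq.A0 * lamc))
        piece0 = np.where(small, dq.N0 / N, (pow0 - 1) / (N * dq.A0 * lam_safe))
    else:
        piece0 = np.zeros_like(lamc)
    out = pow1 * (piece0 + ns_frac)
    if dq.N1 > 0:
        piece1 = np.where(small, dq.N1 / N, (pow1 - 1) / (N * dq.A1 * lam_safe))
        out = out + piece1
    out = out.real if np.isrealobj(inp) else out
    return out[0] if inp.ndim == 0 else out


f_func.__doc__ = """Phase-weighting function of the lineage-size transform.

    f(lam) = (1+A1 lam)**N1 [ ((1+A0 lam)**N0 - 1)/(N A0 lam) + (N-N0-N1)/N ]
             + ((1+A1 lam)**N1 - 1)/(N A1 lam),

with a zero-stage factor replaced by its limit; f(0) = 1 (each piece tends to
its stage fraction).  With N1 = 0 and N = N0 this reduces to the
single-phase (pure exponential growth) form ((1+A0 lam)**N - 1)/(N A0 lam).
Accepts real or complex arguments.
"""


def _product_kmax(p: float, alpha: float) -> int:
    kmax = int(math.ceil(math.log(PRODUCT_TOL) / (alpha * math.log(p))))
    if kmax > 500:
        warnings.warn(f"infinite-product truncation needs K_max={kmax} > 500", stacklevel=3)
    return kmax


def birth_factor(lam, params: GrowthParams):
    """Deterministic-partitioning birth transform A(lam) = prod_{n>=1} b(p**(alpha n) lam).

    The infinite product is truncated at the smallest k with
    p**(alpha k) < 1e-12.
    """
    if params.p >= 1:
        raise ValueError("non-convergent product: need p < 1")
    dq = derived_quantities(params)
    pa = params.p**params.alpha
    kmax = _product_kmax(params.p, params.alpha)
    lam = np.asarray(lam)
    out = np.ones(np.atleast_1d(lam).shape, dtype=complex if np.iscomplexobj(lam) else float)
    scale = pa
    for _ in range(kmax):
        out = out * laplace_b(np.atleast_1d(lam) * scale, dq)
        scale *= pa
    return out[0] if lam.ndim == 0 else out


def birth_laplace(lam, params: GrowthParams):
    """Laplace transform of V_b**alpha (deterministic or beta partitioning)."""
    if params.nu is None:
        return birth_factor(lam, params)
    return stoch_birth_factor(np.asarray(lam), params)


def _full_factor(lam, params: GrowthParams):
    """prod_{k>=0} b(p**(alpha k) lam) = b(lam) * birth transform."""
    dq = derived_quantities(params)
    return laplace_b(lam, dq) * birth_factor(lam, params)


# ---------------------------------------------------------------------------
# beta-partitioning birth transform: printed series + fixed-point continuation


def series_coefficients(params: GrowthParams, n_max: int = SERIES_NMAX) -> SeriesCoefficients:
    """Recursive series coefficients for the beta-partitioning model.

    ``b_n = (-1)**n sum_m (N0)_m (N1)_{n-m} A0**m A1**(n-m) / (m! (n-m)!)``
    (the Taylor coefficients of ``b(lam)``), ``c_n = E[R**(alpha n)]`` via
    beta-function ratios, and ``a_n`` by the recursion with ``a_0 = 1``.
    Pochhammer symbols and beta functions are evaluated through log-gamma.
    """
    if params.nu is None:
        raise ValueError("series_coefficients requires finite nu (beta partitioning)")
    dq = derived_quantities(params)
    al, p, nu, q = params.alpha, params.p, params.nu, params.q
    n = np.arange(n_max + 1)

    # log Pochhammer (x)_m = Gamma(x+m)/Gamma(x); define (0)_0 = 1, (0)_m = 0 for m>0
    def log_poch(x: float, m: np.ndarray) -> np.ndarray:
        if x == 0:
            out = np.full(m.shape, -np.inf)
            out[m == 0] = 0.0
            return out
        return gammaln(x + m) - gammaln(x)

    A0 = dq.A0 if dq.N0 > 0 else 0.0
    A1 = dq.A1 if dq.N1 > 0 else 0.0
    b = np.zeros(n_max + 1)
    for k in n:
        m = np.arange(k + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = (
                log_poch(params.N0, m) + log_poch(params.N1, k - m)
                + m * (np.log(A0) if A0 > 0 else -np.inf)
                + (k - m) * (np.log(A1) if A1 > 0 else -np.inf)
                - gammaln(m + 1) - gammaln(k - m + 1)
            )
        # m*log(0) at m=0 gives 0*-inf -> nan; patch the boundary terms
        if A0 == 0.0:
            logs[m > 0] = -np.inf
            if k > 0:
                logs[0] = log_poch(params.N1, np.array([k]))[0] + k * np.log(A1) - gammaln(k + 1)
        if A1 == 0.0:
            logs[m < k] = -np.inf
            logs[k] = log_poch(params.N0, np.array([k]))[0] + (
                k * np.log(A0) if A0 > 0 else (-np.inf if k > 0 else 0.0)
            ) - gammaln(k + 1)
        finite = np.isfinite(logs)
        b[k] = ((-1.0) ** k) * np.exp(logs[finite]).sum() if finite.any() else 0.0
    c = np.exp(betaln(al * n + p * nu, q * nu) - betaln(p * nu, q * nu))
    a = np.zeros(n_max + 1)
    a[0] = 1.0
    for k in range(1, n_max + 1):
        a[k] = np.dot(a[:k] * c[:k], b[k:0:-1]) / (1.0 - c[k])
    radius = 1.0 / max(A0, A1) if max(A0, A1) > 0 else np.inf
    return SeriesCoefficients(a=a, b=b, c=c, radius=radius)


class _StochBirthFactor:
    """Birth transform A(z) = <exp(-z V_b**alpha)> under beta partitioning.

    Evaluated by iterating the stationary fixed point
    ``A(z) = E_R[A(z R**alpha) b(z R**alpha)]`` on a radial grid (separately
    along the real and imaginary axes), which analytically continues the
    printed power series beyond its convergence radius.  The expectation over
    R uses Gauss-Legendre nodes mapped through the beta quantile function.
    """

    def __init__(self, params: GrowthParams, r_max: float, n_grid: int | None = None,
                 n_nodes: int = 48):
        if params.nu is None:
            raise ValueError("finite nu required")
        self.params = params
        self.dq = derived_quantities(params)
        if n_grid is None:
            # resolve the oscillation of the characteristic function
            # (period ~ 2 pi / mean[V_b**alpha]) with ~15 points per radian
            K1, _ = partition_K(params.p, params.nu, params.alpha)
            mean_x = K1 * (self.dq.M0 + self.dq.M1)
            n_grid = int(min(3e5, max(4001, 15 * r_max * mean_x)))
        nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
        u = 0.5 * (nodes + 1)
        self.r = stats.beta.ppf(u, params.p * params.nu, params.q * params.nu)
        self.w = wts / 2.0
        self.ra = self.r**params.alpha
        self.kmax = _product_kmax(params.p, params.alpha)
        self.grid = np.linspace(0.0, r_max, n_grid)
        self._real = self._iterate(self.grid.astype(complex)).real
        self._imag = self._iterate(1j * self.grid)

    def _iterate(self, zgrid: np.ndarray) -> np.ndarray:
        A = np.ones(zgrid.shape, dtype=complex)
        t = np.abs(zgrid)
        scaled = np.multiply.outer(self.ra, zgrid)  # (nodes, grid)
        ts = np.abs(scaled)
        bvals = laplace_b(scaled, self.dq)
        for _ in range(self.kmax):
            # evaluate current A at the scaled arguments by cubic
            # interpolation on |z| (the grid is a ray from the origin)
            Av = interpolate.CubicSpline(t, A)(ts)
            A = np.tensordot(self.w, Av * bvals, axes=(0, 0))
        return A

    def __call__(self, z):
        z = np.asarray(z)
        out = np.empty(np.atleast_1d(z).shape, dtype=complex)
        zz = np.atleast_1d(z)
        re_mask = np.isreal(zz)
        if re_mask.any():
            out[re_mask] = np.interp(zz[re_mask].real, self.grid, self._real)
        if (~re_mask).any():
            zi = zz[~re_mask]
            if not np.allclose(zi.real, 0.0):
                raise ValueError("evaluation supported on the real or imaginary axis only")
            out[~re_mask] = np.interp(
                np.abs(zi.imag), self.grid, self._imag
            )
            out[~re_mask] = np.where(zi.imag < 0, np.conj(out[~re_mask]), out[~re_mask])
        if np.isrealobj(z):
            out = out.real
        return out[0] if z.ndim == 0 else out


_stoch_cache: dict[tuple, _StochBirthFactor] = {}


def _get_stoch_factor(params: GrowthParams, r_max: float) -> _StochBirthFactor:
    key = (params.g0, params.g1, params.a, params.alpha, params.N, params.N0,
           params.N1, params.p, params.nu)
    got = _stoch_cache.get(key)
    if got is None or got.grid[-1] < r_max:
        # build with headroom so adaptive range exploration rarely rebuilds
        got = _StochBirthFactor(params, r_max=r_max * 4.0)
        if len(_stoch_cache) > 32:
            _stoch_cache.clear()
        _stoch_cache[key] = got
    return got


def stoch_birth_factor(z, params: GrowthParams):
    """A(z) for the beta-partitioning model on the real or imaginary axis."""
    r_max = float(np.max(np.abs(np.atleast_1d(z)))) + 1e-9
    return _get_stoch_factor(params, r_max)(z)


# ---------------------------------------------------------------------------
# lineage-size Laplace transforms and densities


def _laplace_from_factor(lam, params: GrowthParams, factor) -> float | np.ndarray:
    """K * int_lam^inf f(u) * factor(u) du with K fixing F(0) = 1."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("need lam >= 0")
    dq = derived_quantities(params)
    u_peak = 1.0 / max(dq.M0 + dq.M1, 1e-12)

    def integrand(u):
        return f_func(u, dq, params.N) * factor(u)

    # find a cutoff where the integrand is negligible relative to its scale
    u_hi = u_peak
    ref = abs(integrand(np.array([0.0]))[0] if np.ndim(integrand(0.0)) else integrand(0.0))
    val = ref
    while val > ref * 1e-14 and u_hi < 1e8 * u_peak:
        u_hi *= 2.0
        val = abs(integrand(u_hi))
    grid = np.linspace(0.0, u_hi, 6000)
    vals = integrand(grid)
    cum = integrate.cumulative_trapezoid(vals, grid, initial=0.0)
    total = cum[-1]
    tail = total - np.interp(np.atleast_1d(lam), grid, cum)
    out = tail / total
    return out[0] if lam.ndim == 0 else out


def cellsize_laplace_det(lam, params: GrowthParams):
    """Stationary Laplace transform F(lam) = <exp(-lam V**alpha)>, model I."""
    if params.p >= 1:
        raise ValueError("need p < 1")
    return _laplace_from_factor(lam, params, lambda u: _full_factor(u, params))


def cellsize_laplace_stoch(lam, params: GrowthParams, use_series: str = "auto"):
    """Stationary F(lam) for the beta-partitioning model (model II).

    ``use_series='always'`` evaluates the printed power series with adaptive
    truncation (raises beyond its convergence radius); ``'auto'`` (default)
    uses the series where it converges and the fixed-point continuation of
    the birth transform elsewhere; ``'never'`` uses only the continuation.
    """
    if params.nu is None:
        raise ValueError("model II transform requires finite nu")
    if use_series == "always":
        coef = series_coefficients(params)
        return _laplace_from_factor(lam, params, coef.evaluate)
    dq = derived_quantities(params)
    return _laplace_from_factor(
        lam, params, lambda u: laplace_b(u, dq) * stoch_birth_factor(u, params)
    )


def _invert_char(G, y_grid: np.ndarray, lam_max_start: float, tol: float = 1e-10):
    """Fourier inversion: q(y) = (1/pi) int_0^inf Re[G(lam) e^{i lam y}] dlam.

    ``G`` must satisfy G(-lam) = conj(G(lam)).  The lam cutoff is grown until
    |G| falls below ``tol`` * |G(0)|.
    """
    lam_max = lam_max_start
    G0 = abs(G(np.array([0.0]))[0])
    for _ in range(60):
        if abs(G(np.array([lam_max]))[0]) < tol * G0:
            break
        lam_max *= 1.6
    dlam = min(math.pi / (y_grid[-1] * 1.1), lam_max / 400)
    lam = np.arange(0.0, lam_max + dlam, dlam)
    Gv = G(lam)
    wts = np.full(lam.shape, dlam)
    wts[0] = wts[-1] = dlam / 2
    phase = np.exp(1j * np.outer(y_grid, lam))
    return (phase @ (Gv * wts)).real / math.pi


def _density_from_G(params: GrowthParams, grid: np.ndarray, G, meta: dict) -> DensityOnGrid:
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise ValueError("grid must be positive and strictly increasing")
    al = params.alpha
    y = grid**al
    dq = derived_quantities(params)
    lam0 = 1.0 / (dq.M0 + dq.M1)
    yq = _invert_char(G, y, lam0)
    ptilde = yq / y
    dens = al * grid ** (al - 1) * ptilde
    neg = dens.min()
    peak = dens.max()
    if neg < -1e-3 * peak:
        raise ArithmeticError(
            f"Fourier inversion produced negative density ({neg:.3g} vs peak {peak:.3g})"
        )
    dens = np.clip(dens, 0.0, None)
    integral = float(np.trapezoid(dens, grid))
    return DensityOnGrid(x=grid, density=dens, integral=integral, meta=meta)


def cellsize_density_det(params: GrowthParams, grid) -> DensityOnGrid:
    """Stationary lineage cell-size density for model I on ``grid``.

    Inverts ``G(lam) = K f(i lam) prod_k b(p**(alpha k) i lam)`` numerically
    and maps back from ``V**alpha`` to ``V``.
    """
    dq = derived_quantities(params)

    def integrand(u):
        return f_func(u, dq, params.N) * _full_factor(u, params)

    K = _normalizer(integrand, dq)

    def G(lam):
        z = 1j * lam
        return K * f_func(z, dq, params.N) * _full_factor(z, params)

    return _density_from_G(
        params, np.asarray(grid, dtype=float), G,
        {"formula": "lineage-size, deterministic partitioning",
         "product_tol": PRODUCT_TOL},
    )


def cellsize_density_stoch(params: GrowthParams, grid) -> DensityOnGrid:
    """Stationary lineage cell-size density for model II (beta partitioning)."""
    if params.nu is None:
        raise ValueError("model II density requires finite nu")
    dq = derived_quantities(params)
    grid = np.asarray(grid, dtype=float)
    # pre-build the birth factor out to the lam range the deterministic
    # counterpart needs, so the cache is rarely regrown during inversion
    det = params.replace(nu=None)
    lam_max = 1.0 / (dq.M0 + dq.M1)
    G0 = abs(f_func(1e-12, dq, params.N) * _full_factor(1e-12, det))
    for _ in range(60):
        z = 1j * lam_max
        if abs(f_func(z, dq, params.N) * _full_factor(z, det)) < 1e-10 * G0:
            break
        lam_max *= 1.6
    _get_stoch_factor(params, lam_max * 1.7)

    def integrand(u):
        return laplace_b(u, dq) * stoch_birth_factor(u, params) * f_func(u, dq, params.N)

    K = _normalizer(integrand, dq)

    def G(lam):
        z = 1j * lam
        return K * f_func(z, dq, params.N) * laplace_b(z, dq) * stoch_birth_factor(z, params)

    return _density_from_G(
        params, grid, G,
        {"formula": "lineage-size, beta partitioning (series/fixed-point)",
         "nu": params.nu},
    )


def _normalizer(integrand, dq: DerivedQuantities) -> float:
    u_peak = 1.0 / max(dq.M0 + dq.M1, 1e-12)
    u_hi = u_peak
    ref = abs(np.atleast_1d(integrand(np.array([1e-12])))[0])
    val = ref
    while val > ref * 1e-14 and u_hi < 1e8 * u_peak:
        u_hi *= 2.0
        val = abs(np.atleast_1d(integrand(np.array([u_hi])))[0])
    grid = np.linspace(0.0, u_hi, 6000)
    vals = np.real(np.atleast_1d(integrand(grid)))
    return 1.0 / float(np.trapezoid(vals, grid))


# ---------------------------------------------------------------------------
# the deterministic (N -> inf) limit


def limit_distribution(params: GrowthParams) -> LimitMixture:
    """Zero-added-noise limit mixture (uses r0, r1, M0, M1, p, alpha only).

    ``v_d = ((M0+M1)/(1-p**alpha))**(1/alpha)``, ``v_b = p v_d``,
    ``v_m = ((M0 + M1 p**alpha)/(1-p**alpha))**(1/alpha)``; phase times
    ``T0 = (alpha r0/M0) log(v_m/v_b)``, ``Ts = (1-r0-r1)/v_m**alpha``,
    ``T1 = (alpha r1/M1) log(v_d/v_m)``; weights are normalized phase times.
    """
    dq = derived_quantities(params)
    if dq.r0 + dq.r1 > 1 + 1e-12:
        raise ValueError("need r0 + r1 <= 1")
    al, p = params.alpha, params.p
    pa = p**al
    M0, M1 = dq.M0, dq.M1
    v_d = ((M0 + M1) / (1 - pa)) ** (1 / al)
    v_b = p * v_d
    v_m = ((M0 + M1 * pa) / (1 - pa)) ** (1 / al)
    T0 = al * dq.r0 / M0 * math.log(v_m / v_b) if M0 > 0 else 0.0
    Ts = (1 - dq.r0 - dq.r1) / v_m**al
    T1 = al * dq.r1 / M1 * math.log(v_d / v_m) if M1 > 0 else 0.0
    tot = T0 + Ts + T1
    return LimitMixture(
        v_b=v_b, v_m=v_m, v_d=v_d,
        w0=T0 / tot, ws=Ts / tot, w1=T1 / tot,
        T0=T0, Ts=Ts, T1=T1,
    )


# ---------------------------------------------------------------------------
# birth-size distribution


def birth_density(params: GrowthParams, grid) -> DensityOnGrid:
    """Birth-size density by numerical inversion of the exact transform."""
    grid = np.asarray(grid, dtype=float)
    al = params.alpha
    y = grid**al
    dq = derived_quantities(params)

    def Phi(lam):
        return birth_laplace(1j * lam, params)

    lam0 = 1.0 / max((dq.M0 + dq.M1) * params.p**al, 1e-12)
    # invert the characteristic function of Y_b = V_b**alpha directly
    dens_y = _invert_char(Phi, y, lam0)
    dens = al * grid ** (al - 1) * dens_y
    neg = dens.min()
    if neg < -1e-3 * dens.max():
        raise ArithmeticError("negative density from birth-transform inversion")
    dens = np.clip(dens, 0.0, None)
    return DensityOnGrid(
        x=grid, density=dens, integral=float(np.trapezoid(dens, grid)),
        meta={"formula": "birth-size, exact transform inversion"},
    )


def birth_density_approx(x, params: GrowthParams):
    """Closed-form birth-size density under the large-alpha / small-p approximation.

    Keeps only the n=1 factor of the birth transform:
    ``p(x) = alpha beta0**N0 beta1**N1 / Gamma(N0+N1) x**(alpha(N0+N1)-1)
    exp(-beta0 x**alpha) 1F1(N1, N0+N1, (beta0-beta1) x**alpha)`` with
    ``beta0 = N0/(M0 p**alpha)`` and ``beta1 = N1/(M1 p**alpha)``.  With
    ``N1 = 0`` this collapses to a generalized gamma (Erlang in x**alpha).
    Evaluated in log space; the confluent hypergeometric factor falls back to
    a log-scaled series when scipy overflows.
    """
    x = np.asarray(x, dtype=float)
    dq = derived_quantities(params)
    al, pa = params.alpha, params.p**params.alpha
    N0, N1 = params.N0, params.N1
    beta0 = N0 / (dq.M0 * pa)
    xa = x**al
    if N1 == 0:
        logp = (
            math.log(al) + N0 * math.log(beta0) - gammaln(N0)
            + (al * N0 - 1) * np.log(x) - beta0 * xa
        )
        return np.exp(logp)
    beta1 = N1 / (dq.M1 * pa)
    logp = (
        math.log(al) + N0 * math.log(beta0) + N1 * math.log(beta1)
        - gammaln(N0 + N1) + (al * (N0 + N1) - 1) * np.log(x) - beta0 * xa
    )
    h = hyp1f1(N1, N0 + N1, (beta0 - beta1) * xa)
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.exp(logp) * h
    bad = ~np.isfinite(out)
    if np.any(bad):
        # log-scaled Kummer transform: 1F1(a,b,z) = e^z 1F1(b-a,b,-z); for
        # z -> -inf use the asymptotic 1F1(a,b,z) ~ Gamma(b)/Gamma(b-a) (-z)^-a
        z = (beta0 - beta1) * xa[bad]
        asym = np.exp(gammaln(N0 + N1) - gammaln(N0) - N1 * np.log(np.abs(z)))
        out[bad] = np.exp(logp[bad]) * np.where(z < 0, asym, np.inf)
    return out


def birth_moments(params: GrowthParams, model: str | None = None) -> tuple[float, float]:
    """Mean and variance of V_b**alpha.

    Model I: mean ``p**alpha/(1-p**alpha) (M0+M1)``, variance
    ``p**(2 alpha)/(1-p**(2 alpha)) [M0**2/N0 + M1**2/N1]``.  Model II uses
    the partition-moment factors K1, K2 (reduces to model I as nu -> inf).
    """
    dq = derived_quantities(params)
    S = dq.M0 + dq.M1
    bracket = (dq.M0**2 / params.N0 if params.N0 > 0 else 0.0) + (
        dq.M1**2 / params.N1 if params.N1 > 0 else 0.0
    )
    if model is None:
        model = "II" if params.nu is not None else "I"
    if model.upper() == "I":
        pa = params.p**params.alpha
        return pa / (1 - pa) * S, pa**2 / (1 - pa**2) * bracket
    if params.nu is None:
        raise ValueError("model II moments require finite nu")
    K1, K2 = partition_K(params.p, params.nu, params.alpha)
    mean = K1 * S
    var = ((2 * K1 + 1) * K2 - K1**2) * S**2 + K2 * bracket
    return mean, var


# ---------------------------------------------------------------------------
# birth-division correlations


def corr_det(p: float, alpha: float) -> float:
    """Correlation of (V_b**alpha, V_d**alpha) under deterministic partitioning.

    Equals ``p**alpha`` regardless of the growth pattern (the phase structure
    cancels: the generalized added size is independent of the birth size).
    """
    if not (0 < p < 1) or alpha <= 0:
        raise ValueError("need 0 < p < 1 and alpha > 0")
    return p**alpha


def partition_K(p: float, nu: float, alpha: float) -> tuple[float, float]:
    """Moment factors K1 = m1/(1-m1), K2 = m2/(1-m2) with m_j = E[R**(j alpha)]."""
    q = 1 - p
    m1 = math.exp(betaln(alpha + p * nu, q * nu) - betaln(p * nu, q * nu))
    m2 = math.exp(betaln(2 * alpha + p * nu, q * nu) - betaln(p * nu, q * nu))
    return m1 / (1 - m1), m2 / (1 - m2)


def corr_stoch(params: GrowthParams) -> tuple[float, float, float]:
    """Correlation of (V_b**alpha, V_d**alpha) under beta partitioning.

    Returns ``(rho, K1, K2)``.  From the stationary recursion
    ``X =d R**alpha (X + Delta)``: Cov(X, Y) = Var(X) with Y = X + Delta, so
    rho = sqrt(Var(X)/Var(Y)); the variance ratio is the closed-form
    expression in M0, M1, N0, N1, K1, K2.  As nu -> inf, K1 -> p**alpha /
    (1-p**alpha) and rho -> p**alpha.  Always <= the deterministic value.
    """
    if params.nu is None:
        raise ValueError("corr_stoch requires finite nu")
    dq = derived_quantities(params)
    S = dq.M0 + dq.M1
    bracket = (dq.M0**2 / params.N0 if params.N0 > 0 else 0.0) + (
        dq.M1**2 / params.N1 if params.N1 > 0 else 0.0
    )
    K1, K2 = partition_K(params.p, params.nu, params.alpha)
    coef = (2 * K1 + 1) * K2 - K1**2
    num = coef * S**2 + K2 * bracket
    den = coef * S**2 + (K2 + 1) * bracket
    return math.sqrt(num / den), K1, K2


# ---------------------------------------------------------------------------
# helpers


def mean_cellsize(params: GrowthParams, n_grid: int = 800) -> float:
    """Mean lineage cell size from the analytic density."""
    lim = limit_distribution(params)
    lo = max(lim.v_b * 0.2, 1e-6)
    hi = lim.v_d * 2.5
    grid = np.linspace(lo, hi, n_grid)
    dens = (
        cellsize_density_det(params, grid)
        if params.nu is None
        else cellsize_density_stoch(params, grid)
    )
    return float(np.trapezoid(grid * dens.density, grid) / dens.integral)


def calibrate_mean_size(params: GrowthParams, target_mean: float) -> GrowthParams:
    """Rescale ``a`` so that the stationary mean cell size equals ``target_mean``.

    Sizes scale as ``a**(-1/alpha)``, so a single exact update suffices:
    ``a <- a * (mean/target)**alpha``.
    """
    m = mean_cellsize(params)
    return params.replace(a=params.a * (m / target_mean) ** params.alpha)
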