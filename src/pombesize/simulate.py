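"""Exact stochastic simulation of the cell-size process along a lineage.

The process is piecewise deterministic: size grows exponentially (or stays
flat in septation) within each effective cell-cycle stage, and stage
transitions fire with rate ``a V(t)**alpha``.  Because the hazard is a power
of size, the increment of ``V**alpha`` accumulated while traversing a growing
stage is exponentially distributed with mean ``alpha*g/a``, independent of the
size at stage entry; summed over a phase this gives the gamma (Erlang for
integer shape) phase increments used by the fast phase-level sampler.  The
stage-level sampler draws every stage explicitly and serves as the brute-force
oracle for the phase-level one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import GrowthParams, sample_partition

__all__ = [
    "GenerationSummary",
    "LineageTimecourse",
    "simulate_generation_phase",
    "simulate_generation_stage",
    "simulate_chain",
    "simulate_lineage",
    "sample_timecourse",
    "sample_sizes_timeweighted",
]

DEFAULT_BURN_IN = 50


@dataclass(frozen=True)
class GenerationSummary:
    """Observables of one generation.

    ``Delta0 = V_s**alpha - V_b**alpha`` and ``Delta1 = V_d**alpha -
    V_s**alpha`` are the generalized added sizes of the elongation and
    reshaping phases; ``R`` is the partition ratio applied at the division
    that ends this generation, so the next birth size is ``R * V_d``.
    """

    V_b: float
    V_s: float
    V_d: float
    T: float
    T_elong: float
    T_sept: float
    T_reshape: float
    Delta0: float
    Delta1: float
    R: float


@dataclass
class LineageTimecourse:
    """Regularly sampled (time, size) series for one lineage.

    ``generation_index`` labels the generation each sample belongs to and
    ``division_times`` are the absolute times of division events (generation
    boundaries).  Sizes are micrometres, times hours.
    """

    time_h: np.ndarray
    size_um: np.ndarray
    generation_index: np.ndarray
    division_times: np.ndarray
    lineage_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("sample times must be strictly increasing")


def _gamma_or_zero(shape: float, scale: float, rng: np.random.Generator, size=None):
    if shape == 0:
        return 0.0 if size is None else np.zeros(size)
    return rng.gamma(shape, scale, size)


def simulate_generation_phase(
    params: GrowthParams, V_b: float, rng: np.random.Generator
) -> GenerationSummary:
    """Sample one generation using phase-level gamma increments.

    ``Delta0 ~ Gamma(N0, mean M0)``, ``Delta1 ~ Gamma(N1, mean M1)``, and the
    septation duration is ``Gamma(N - N0 - N1, rate a V_s**alpha)``.
    """
    if V_b <= 0:
        raise ValueError("birth size must be positive")
    al, a = params.alpha, params.a
    d0 = float(_gamma_or_zero(params.N0, params.g0 * al / a, rng))
    d1 = float(_gamma_or_zero(params.N1, params.g1 * al / a, rng))
    xb = V_b**al
    V_s = (xb + d0) ** (1 / al)
    V_d = (xb + d0 + d1) ** (1 / al)
    T_elong = math.log(V_s / V_b) / params.g0
    T_reshape = math.log(V_d / V_s) / params.g1
    ns = params.N_sept
    T_sept = float(_gamma_or_zero(ns, 1.0, rng)) / (a * V_s**al) if ns > 0 else 0.0
    R = float(sample_partition(params, 1, rng)[0])
    return GenerationSummary(
        V_b=V_b, V_s=float(V_s), V_d=float(V_d),
        T=T_elong + T_sept + T_reshape,
        T_elong=T_elong, T_sept=T_sept, T_reshape=T_reshape,
        Delta0=d0, Delta1=d1, R=R,
    )


def simulate_generation_stage(
    params: GrowthParams, V_b: float, rng: np.random.Generator
) -> GenerationSummary:
    """Sample one generation stage by stage (integer stage counts only).

    Within a growing stage at rate ``g`` entered at generalized size ``x``,
    the stage increment of ``V**alpha`` is ``(alpha*g/a) * E`` with
    ``E ~ Exp(1)`` and the stage duration is ``log(1 + inc/x)/(alpha*g)``.
    Within septation the duration is ``E/(a V_s**alpha)``.  Brute-force
    oracle for :func:`simulate_generation_phase`.
    """
    if V_b <= 0:
        raise ValueError("birth size must be positive")
    for name in ("N", "N0", "N1"):
        v = getattr(params, name)
        if v != int(v):
            raise ValueError(f"stage-level sampler needs integer {name}, got {v}")
    n0, n1 = int(params.N0), int(params.N1)
    ns = int(params.N) - n0 - n1
    if ns < 0:
        raise ValueError("need N >= N0 + N1")
    al, a = params.alpha, params.a
    x = V_b**al
    T_elong = 0.0
    for _ in range(n0):
        inc = (al * params.g0 / a) * rng.exponential()
        T_elong += math.log1p(inc / x) / (al * params.g0)
        x += inc
    V_s = x ** (1 / al)
    d0 = x - V_b**al
    T_sept = sum(rng.exponential() / (a * x) for _ in range(ns))
    T_reshape = 0.0
    for _ in range(n1):
        inc = (al * params.g1 / a) * rng.exponential()
        T_reshape += math.log1p(inc / x) / (al * params.g1)
        x += inc
    V_d = x ** (1 / al)
    R = float(sample_partition(params, 1, rng)[0])
    return GenerationSummary(
        V_b=V_b, V_s=float(V_s), V_d=float(V_d),
        T=T_elong + T_sept + T_reshape,
        T_elong=T_elong, T_sept=T_sept, T_reshape=T_reshape,
        Delta0=d0, Delta1=x - V_s**al, R=R,
    )


def _stationary_guess(params: GrowthParams) -> float:
    """Mean of V_b**alpha under deterministic partitioning, as a start size."""
    from .params import derived_quantities

    dq = derived_quantities(params)
    pa = params.p**params.alpha
    x = pa * (dq.M0 + dq.M1) / (1 - pa)
    return x ** (1 / params.alpha)


def simulate_chain(
    params: GrowthParams,
    n_generations: int,
    rng: np.random.Generator,
    burn_in: int = DEFAULT_BURN_IN,
    V_b0: float | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized lineage chain; returns arrays of per-generation observables.

    Generations are chained through ``V_b(k+1) = R(k) * V_d(k)``; the first
    ``burn_in`` generations are discarded.  Keys: ``V_b, V_s, V_d, T, T_elong,
    T_sept, T_reshape, Delta0, Delta1, R``.
    """
    if n_generations < 1:
        raise ValueError("need n_generations >= 1")
    n = n_generations + burn_in
    al, a = params.alpha, params.a
    d0 = np.asarray(_gamma_or_zero(params.N0, params.g0 * al / a, rng, n), dtype=float)
    d1 = np.asarray(_gamma_or_zero(params.N1, params.g1 * al / a, rng, n), dtype=float)
    R = sample_partition(params, n, rng)
    Ra = R**al
    x0 = (V_b0 if V_b0 is not None else _stationary_guess(params)) ** al
    xb = np.empty(n)
    x = x0
    dtot = d0 + d1
    for k in range(n):
        xb[k] = x
        x = Ra[k] * (x + dtot[k])
    xs = xb + d0
    xd = xb + dtot
    V_b = xb ** (1 / al)
    V_s = xs ** (1 / al)
    V_d = xd ** (1 / al)
    T_elong = np.log(V_s / V_b) / params.g0
    T_reshape = np.log(V_d / V_s) / params.g1
    ns = params.N_sept
    if ns > 0:
        T_sept = np.asarray(_gamma_or_zero(ns, 1.0, rng, n), dtype=float) / (a * xs)
    else:
        T_sept = np.zeros(n)
    sl = slice(burn_in, None)
    return {
        "V_b": V_b[sl], "V_s": V_s[sl], "V_d": V_d[sl],
        "T": (T_elong + T_sept + T_reshape)[sl],
        "T_elong": T_elong[sl], "T_sept": T_sept[sl], "T_reshape": T_reshape[sl],
        "Delta0": d0[sl], "Delta1": d1[sl], "R": R[sl],
    }


def simulate_lineage(
    params: GrowthParams,
    n_generations: int,
    rng: np.random.Generator,
    burn_in: int = DEFAULT_BURN_IN,
    V_b0: float | None = None,
) -> list[GenerationSummary]:
    """Chained generations after burn-in, as :class:`GenerationSummary` list."""
    c = simulate_chain(params, n_generations, rng, burn_in=burn_in, V_b0=V_b0)
    return [
        GenerationSummary(
            V_b=c["V_b"][k], V_s=c["V_s"][k], V_d=c["V_d"][k], T=c["T"][k],
            T_elong=c["T_elong"][k], T_sept=c["T_sept"][k],
            T_reshape=c["T_reshape"][k],
            Delta0=c["Delta0"][k], Delta1=c["Delta1"][k], R=c["R"][k],
        )
        for k in range(len(c["V_b"]))
    ]


def _size_at(gen: GenerationSummary, u: float) -> float:
    """Size at local time ``u`` within a generation (piecewise exponential)."""
    if u < gen.T_elong:
        return gen.V_b * math.exp(0 if gen.T_elong == 0 else u * math.log(gen.V_s / gen.V_b) / gen.T_elong)
    if u < gen.T_elong + gen.T_sept:
        return gen.V_s
    u1 = u - gen.T_elong - gen.T_sept
    if gen.T_reshape == 0:
        return gen.V_d
    return gen.V_s * math.exp(u1 * math.log(gen.V_d / gen.V_s) / gen.T_reshape)


def sample_timecourse(
    generations: list[GenerationSummary],
    dt: float,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    lineage_id: int = 0,
) -> LineageTimecourse:
    """Sample chained generations on a regular time grid of spacing ``dt`` (h).

    Optional multiplicative log-normal measurement noise with coefficient of
    variation ``noise_cv`` (mean-preserving).  With ``noise_cv=0`` samples lie
    exactly on the deterministic growth curves.
    """
    if dt <= 0:
        raise ValueError("need dt > 0")
    durations = np.array([g.T for g in generations])
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    total = starts[-1]
    times = np.arange(0.0, total, dt)
    gen_idx = np.minimum(np.searchsorted(starts, times, side="right") - 1, len(generations) - 1)
    sizes = np.array(
        [_size_at(generations[g], t - starts[g]) for g, t in zip(gen_idx, times)]
    )
    if noise_cv > 0:
        if rng is None:
            raise ValueError("rng required when noise_cv > 0")
        sigma = math.sqrt(math.log(1 + noise_cv**2))
        sizes = sizes * rng.lognormal(-0.5 * sigma**2, sigma, size=sizes.shape)
    return LineageTimecourse(
        time_h=times, size_um=sizes, generation_index=gen_idx.astype(int),
        division_times=starts[1:], lineage_id=lineage_id,
    )


def sample_sizes_timeweighted(
    params: GrowthParams,
    n_samples: int,
    rng: np.random.Generator,
    n_generations: int = 20_000,
    burn_in: int = DEFAULT_BURN_IN,
) -> np.ndarray:
    """Sizes observed at uniform random times along a simulated lineage.

    This is the simulation estimate of the lineage (time-weighted) cell-size
    distribution: a generation is picked with probability proportional to its
    duration, then the size at a uniform time within it is returned.
    Vectorized; used as the oracle for the analytic size densities.
    """
    c = simulate_chain(params, n_generations, rng, burn_in=burn_in)
    T = c["T"]
    edges = np.concatenate([[0.0], np.cumsum(T)])
    u = rng.uniform(0.0, edges[-1], n_samples)
    k = np.searchsorted(edges, u, side="right") - 1
    loc = u - edges[k]
    te, ts = c["T_elong"][k], c["T_sept"][k]
    vb, vs, vd = c["V_b"][k], c["V_s"][k], c["V_d"][k]
    out = np.where(loc < te, vb * np.exp(params.g0 * loc), vs)
    in_reshape = loc >= te + ts
    u1 = np.clip(loc - te - ts, 0.0, None)
    out = np.where(in_reshape, vs * np.exp(params.g1 * u1), out)
    return out
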