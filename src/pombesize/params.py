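"""Model parameters, derived quantities, and the division-partition distribution.

The model describes fission-yeast cell-size dynamics across a lineage.  Within a
cell cycle the cell passes through ``N`` effective stages with size-dependent
transition rate ``a * V(t)**alpha``; the first ``N0`` stages grow exponentially
at rate ``g0`` (elongation), the middle ``N - N0 - N1`` stages do not grow
(septation), and the last ``N1`` stages grow exponentially at the faster rate
``g1`` (reshaping of the new cell ends).  At division the tracked daughter
receives a fraction ``R`` of the mother's size, either fixed at ``p`` (model I)
or drawn from a Beta distribution with mean ``p`` and sample-size parameter
``nu`` (model II).

Sizes are cell lengths in micrometres, rates are per hour.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "GrowthParams",
    "DerivedQuantities",
    "ConventionalControl",
    "derived_quantities",
    "partition_density",
    "sample_partition",
    "alpha_to_beta",
    "conventional_beta",
]


@dataclass(frozen=True)
class GrowthParams:
    """Full parameter vector of the cell-size model.

    Parameters
    ----------
    g0, g1 : float
        Exponential growth rates (1/h) in the elongation and reshaping phases;
        ``g1 > g0 > 0``.
    a : float
        Proportionality constant of the stage-transition rate
        (units size**(-alpha) per hour).
    alpha : float
        Size-control strength: ``alpha -> 0`` timer, ``alpha = 1`` adder,
        ``alpha -> inf`` sizer.
    N, N0, N1 : float
        Total / elongation / reshaping effective stage numbers.  Real values
        are allowed (gamma generalization of the Erlang stage sums); the
        integer case is recovered exactly for integer shapes.
    p : float
        Mean partition ratio of the tracked daughter, ``0 < p < 1``.
    nu : float or None
        Beta sample-size parameter of the partition ratio.  ``None`` is the
        deterministic-partitioning sentinel (model I); a positive float
        selects stochastic partitioning (model II).
    """

    g0: float
    g1: float
    a: float
    alpha: float
    N: float
    N0: float
    N1: float
    p: float
    nu: float | None = None

    def __post_init__(self) -> None:
        if not (self.g0 > 0 and self.g1 > self.g0):
            raise ValueError(f"need g1 > g0 > 0, got g0={self.g0}, g1={self.g1}")
        if self.a <= 0:
            raise ValueError(f"need a > 0, got {self.a}")
        if self.alpha <= 0:
            raise ValueError(f"need alpha > 0, got {self.alpha}")
        if self.N0 < 0 or self.N1 < 0 or self.N < 1:
            raise ValueError("need N >= 1, N0 >= 0, N1 >= 0")
        # tiny tolerance: fitted stage numbers are rounded to 3 decimals
        if self.N0 + self.N1 > self.N * (1 + 1e-9) + 1e-9:
            raise ValueError(f"need N >= N0 + N1, got N={self.N}, N0={self.N0}, N1={self.N1}")
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"need 0 < p < 1, got {self.p}")
        if self.nu is not None and self.nu <= 0:
            raise ValueError(f"need nu > 0 (or None for deterministic), got {self.nu}")

    @property
    def stochastic_partition(self) -> bool:
        return self.nu is not None

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def N_sept(self) -> float:
        """Number of septation-phase stages, ``N - N0 - N1``."""
        return max(self.N - self.N0 - self.N1, 0.0)

    def replace(self, **kwargs) -> "GrowthParams":
        return dataclasses.replace(self, **kwargs)

    # -- flat key:value config (YAML dialect; keys g0, g1, a, alpha, N, N0, N1, p, nu)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["nu"] is None:
            d["nu"] = "deterministic"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParams":
        d = dict(d)
        nu = d.get("nu", "deterministic")
        if isinstance(nu, str):
            if nu.lower() != "deterministic":
                raise ValueError(f"nu must be a positive number or 'deterministic', got {nu!r}")
            d["nu"] = None
        return cls(**{k: d[k] if k == "nu" else float(d[k]) for k in
                      ("g0", "g1", "a", "alpha", "N", "N0", "N1", "p", "nu")})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "GrowthParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class DerivedQuantities:
    """Quantities derived from :class:`GrowthParams`.

    ``M0 = N0 g0 alpha / a`` and ``M1 = N1 g1 alpha / a`` are the mean
    generalized added sizes (increments of V**alpha) in the elongation and
    reshaping phases; ``r0 = N0/N`` and ``r1 = N1/N`` are stage fractions.
    ``A0``/``A1`` are per-stage means ``M0/N0``/``M1/N1`` and are undefined
    (raise) when the corresponding stage count is zero.
    """

    M0: float
    M1: float
    r0: float
    r1: float
    q: float
    N0: float
    N1: float

    @property
    def A0(self) -> float:
        if self.N0 == 0:
            raise ZeroDivisionError("A0 undefined: N0 = 0 (no elongation stages)")
        return self.M0 / self.N0

    @property
    def A1(self) -> float:
        if self.N1 == 0:
            raise ZeroDivisionError("A1 undefined: N1 = 0 (no reshaping stages)")
        return self.M1 / self.N1


def derived_quantities(params: GrowthParams) -> DerivedQuantities:
    """Mean generalized added sizes and stage fractions for ``params``."""
    M0 = params.N0 * params.g0 * params.alpha / params.a
    M1 = params.N1 * params.g1 * params.alpha / params.a
    return DerivedQuantities(
        M0=M0, M1=M1,
        r0=params.N0 / params.N, r1=params.N1 / params.N,
        q=params.q, N0=params.N0, N1=params.N1,
    )


def partition_density(r, p: float, nu: float):
    """Beta density of the partition ratio, mean ``p``, variance ``p q/(nu+1)``.

    ``h(r) = r**(p nu - 1) (1-r)**(q nu - 1) / B(p nu, q nu)`` on (0, 1).
    """
    if nu is None or nu <= 0:
        raise ValueError("partition_density requires a finite nu > 0")
    if not (0.0 < p < 1.0):
        raise ValueError(f"need 0 < p < 1, got {p}")
    r = np.asarray(r, dtype=float)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("partition ratio r must lie strictly inside (0, 1)")
    out = stats.beta.pdf(r, p * nu, (1.0 - p) * nu)
    return float(out) if out.ndim == 0 else out


def sample_partition(params: GrowthParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw partition ratios: constant ``p`` (model I) or Beta (model II)."""
    if params.nu is None:
        return np.full(size, params.p)
    return rng.beta(params.p * params.nu, params.q * params.nu, size)


def alpha_to_beta(alpha: float) -> float:
    """Map control strength ``alpha`` to the conventional regression slope.

    ``beta = 2**(1 - alpha)``: 2 for a timer (alpha=0), 1 for an adder
    (alpha=1), -> 0 for a sizer (alpha -> inf).  The mapping assumes symmetric
    division and small size variability; outside that regime the regression
    slope of division on birth size is only loosely related to alpha.
    """
    if alpha < 0:
        raise ValueError(f"need alpha >= 0, got {alpha}")
    return 2.0 ** (1.0 - alpha)


@dataclass(frozen=True)
class ConventionalControl:
    """OLS fit of division size on birth size, ``V_d = beta V_b + gamma + eps``."""

    beta: float
    gamma: float
    residual_sd: float
    r_squared: float


def conventional_beta(pairs: Iterable[Sequence[float]] | np.ndarray) -> ConventionalControl:
    """Ordinary least squares of division size on birth size.

    ``beta`` in [0, 2] is the interpretable range (0 sizer, 1 adder, 2 timer);
    values outside it are reported with a warning rather than rejected.
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (V_b, V_d) pairs")
    vb, vd = arr[:, 0], arr[:, 1]
    if np.any(vb <= 0) or np.any(vd <= 0):
        raise ValueError("sizes must be positive")
    if np.ptp(vb) == 0:
        raise ValueError("degenerate regression: all birth sizes identical")
    res = stats.linregress(vb, vd)
    resid = vd - (res.slope * vb + res.intercept)
    sd = float(np.std(resid, ddof=2)) if len(vb) > 2 else 0.0
    if not (0.0 <= res.slope <= 2.0):
        import warnings

        warnings.warn(
            f"regression slope {res.slope:.3f} outside the interpretable [0, 2] range",
            stacklevel=2,
        )
    return ConventionalControl(
        beta=float(res.slope), gamma=float(res.intercept),
        residual_sd=sd, r_squared=float(res.rvalue**2),
    )
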