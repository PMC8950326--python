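"""Entropic free-energy barrier of polymer translocation.

A chain of ``N`` segments threads a nanopore in an impenetrable membrane.
With ``m`` segments on the trans side the chain pays an entropic price on
both sides of the wall (the tethered-chain partition sum scales as
``Z_m ~ m**(gamma - 1)``) plus a chemical-potential bias ``m * delta_mu``:

    beta F(m) = (1 - gamma1) ln(N - m) + (1 - gamma2) ln(m) + m beta delta_mu

which for equal partition exponents on the two sides reduces to

    F(m) = (1 - gamma) kT ln[m (N - m)] + m delta_mu.

``delta_mu = mu_cis - mu_trans``; negative values lower the barrier at large
``m`` and favour translocation.  For ``gamma < 1`` the log terms diverge at
the endpoints, so continuous evaluation is restricted to ``[delta, N-delta]``
(default ``delta = 1e-6 N``); integer monomer counts use ``m in {1..N-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "ChainStatistics",
    "TranslocationBarrier",
    "ParabolicBarrier",
    "NoInteriorMaximumError",
    "entropic_free_energy",
    "barrier_maximum",
    "fit_parabola",
    "parabolic_difference",
]

#: partition exponent gamma by chain statistics: 0.5 for ideal (Gaussian)
#: chains, ~0.69 for self-avoiding chains, 1 for rod-like chains.
GAMMA_PRESETS = {"gaussian": 0.5, "self_avoiding": 0.69, "rodlike": 1.0}


class NoInteriorMaximumError(ValueError):
    """F(m) is linear in m (gamma1 = gamma2 = 1): no interior barrier top."""


@dataclass(frozen=True)
class ChainStatistics:
    """Partition exponents ``gamma1`` (cis side) and ``gamma2`` (trans side).

    Construct from a preset name (``gaussian``, ``self_avoiding``,
    ``rodlike``) or explicit custom values in ``(0, 1]``.
    """

    gamma1: float = 0.5
    gamma2: float = 0.5
    preset: str = "custom"

    def __post_init__(self) -> None:
        for g in (self.gamma1, self.gamma2):
            if not (0.0 < g <= 1.0):
                raise ValueError(f"partition exponent must lie in (0, 1], got {g}")

    @classmethod
    def from_preset(cls, name: str) -> "ChainStatistics":
        try:
            g = GAMMA_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown chain-statistics preset {name!r}; "
                f"choose from {sorted(GAMMA_PRESETS)}"
            ) from None
        return cls(gamma1=g, gamma2=g, preset=name)


@dataclass(frozen=True)
class TranslocationBarrier:
    """Free-energy barrier parameters F(m) for an N-segment chain.

    Parameters
    ----------
    N : int
        Number of chain segments (>= 2).
    delta_mu : float
        Chemical-potential difference per segment, cis minus trans, in the
        same energy units as ``kT``.  Negative values drive translocation.
    kT : float
        Thermal energy (> 0); ``beta = 1/kT``.
    chain_stats : ChainStatistics
        Partition exponents of the two membrane sides.
    endpoint_delta_frac : float
        Continuous evaluation is clamped to ``[delta, N - delta]`` with
        ``delta = endpoint_delta_frac * N``, avoiding the log singularities.
    """

    N: int
    delta_mu: float = 0.0
    kT: float = 1.0
    chain_stats: ChainStatistics = field(default_factory=ChainStatistics)
    endpoint_delta_frac: float = 1e-6

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"need at least N=2 segments, got N={self.N}")
        if self.kT <= 0:
            raise ValueError(f"kT must be positive, got {self.kT}")

    @property
    def beta(self) -> float:
        return 1.0 / self.kT

    @property
    def delta(self) -> float:
        return self.endpoint_delta_frac * self.N


@dataclass(frozen=True)
class ParabolicBarrier:
    """Parabolic barrier surrogate ``F(m) = -b1 m**2 + b2 m + b3``, b1 > 0.

    ``b3`` is a gauge constant: no observable (flux, barrier differences)
    depends on it, it is kept only so fitted curves overlay the original.
    The degenerate flat case ``b1 = 0`` is representable (the quadrature
    flux route accepts it) but the erf closed form requires ``b1 > 0``.
    """

    b1: float
    b2: float
    b3: float = 0.0
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.b1 < 0:
            raise ValueError(f"parabolic barrier requires b1 >= 0, got b1={self.b1}")

    def __call__(self, m):
        m = np.asarray(m, dtype=float)
        out = -self.b1 * m**2 + self.b2 * m + self.b3
        return out if out.ndim else float(out)

    @property
    def vertex(self) -> float:
        """Location of the parabola's maximum, b2/(2 b1)."""
        return self.b2 / (2.0 * self.b1)


def entropic_free_energy(m, barrier: TranslocationBarrier, *, clamp: bool = False):
    """Free energy F(m) of a chain with ``m`` segments translocated.

    Evaluates ``kT [(1-gamma1) ln(N-m) + (1-gamma2) ln m] + m delta_mu``.
    Scalar or array ``m``; values must lie in the open interval ``(0, N)``
    unless ``clamp=True``, which snaps them to ``[delta, N-delta]`` first.
    """
    arr = np.asarray(m, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr).astype(float)
    if np.any(arr < 0) or np.any(arr > barrier.N):
        raise ValueError(f"m must lie in [0, N={barrier.N}]")
    if clamp:
        arr = np.clip(arr, barrier.delta, barrier.N - barrier.delta)
    elif np.any(arr <= 0) or np.any(arr >= barrier.N):
        raise ValueError(
            "m on the domain boundary: F diverges at m in {0, N} for gamma < 1; "
            "pass clamp=True to evaluate at the clamped endpoints"
        )
    g1, g2 = barrier.chain_stats.gamma1, barrier.chain_stats.gamma2
    F = barrier.kT * ((1.0 - g1) * np.log(barrier.N - arr) + (1.0 - g2) * np.log(arr))
    F = F + arr * barrier.delta_mu
    return float(F[0]) if scalar else F


def barrier_maximum(barrier: TranslocationBarrier, *, xtol: float = 1e-12):
    """Interior maximum (m*, F*) of the free-energy barrier.

    Solves dF/dm = 0 by bracketed root finding.  Requires at least one of
    the partition exponents below 1; for gamma1 = gamma2 = 1 the profile is
    linear in m and :class:`NoInteriorMaximumError` is raised.
    """
    g1, g2 = barrier.chain_stats.gamma1, barrier.chain_stats.gamma2
    if g1 == 1.0 and g2 == 1.0:
        raise NoInteriorMaximumError(
            "no interior maximum: F(m) is linear in m when gamma1 = gamma2 = 1"
        )

    N, kT, dmu = barrier.N, barrier.kT, barrier.delta_mu

    def dF(m: float) -> float:
        return kT * (-(1.0 - g1) / (N - m) + (1.0 - g2) / m) + dmu

    lo, hi = barrier.delta, N - barrier.delta
    flo, fhi = dF(lo), dF(hi)
    if flo <= 0.0 or fhi >= 0.0:
        # dF does not change sign downward inside the domain: the maximum
        # sits on (the clamped) boundary, which we treat as "no interior top".
        raise NoInteriorMaximumError(
            "dF/dm does not cross zero inside (0, N); barrier is monotone"
        )
    m_star = brentq(dF, lo, hi, xtol=xtol * N)
    return m_star, entropic_free_energy(m_star, barrier)


def fit_parabola(
    barrier: TranslocationBarrier,
    m_lo: float | None = None,
    m_hi: float | None = None,
    n_samples: int = 81,
) -> ParabolicBarrier:
    """Least-squares parabolic surrogate of the entropic barrier.

    Samples F(m) at ``n_samples`` uniform points on ``[m_lo, m_hi]``
    (default window ``[0.1 N, 0.9 N]``, which skirts the log singularities)
    and fits ``F(m) = -b1 m**2 + b2 m + b3`` with the concavity constraint
    ``b1 > 0`` enforced.
    """
    N = barrier.N
    if m_lo is None:
        m_lo = 0.1 * N
    if m_hi is None:
        m_hi = 0.9 * N
    if not (0.0 < m_lo < m_hi < N):
        raise ValueError(f"require 0 < m_lo < m_hi < N, got [{m_lo}, {m_hi}]")
    if n_samples < 3:
        raise ValueError("parabola fit needs at least 3 samples")
    m = np.linspace(m_lo, m_hi, n_samples)
    F = entropic_free_energy(m, barrier)
    return fit_parabola_to_samples(m, F)


def fit_parabola_to_samples(m, F) -> ParabolicBarrier:
    """Fit ``F = -b1 m**2 + b2 m + b3`` to sampled points, b1 > 0 enforced."""
    m = np.asarray(m, dtype=float)
    F = np.asarray(F, dtype=float)
    if m.size < 3:
        raise ValueError("parabola fit needs at least 3 samples")
    # unconstrained normal-equation solution first; fall back to a bounded
    # solver only if it lands on the wrong (convex) branch
    A = np.column_stack([-(m**2), m, np.ones_like(m)])
    coef, *_ = np.linalg.lstsq(A, F, rcond=None)
    if coef[0] <= 0:
        res = least_squares(
            lambda c: (-c[0] * m**2 + c[1] * m + c[2]) - F,
            x0=[1e-8, coef[1], coef[2]],
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        )
        coef = res.x
        if coef[0] <= 1e-10:
            raise ValueError(
                "barrier is not concave on the requested window (fitted b1 <= 0)"
            )
    resid = float(np.linalg.norm(A @ coef - F))
    return ParabolicBarrier(b1=float(coef[0]), b2=float(coef[1]), b3=float(coef[2]),
                            residual_norm=resid)


def parabolic_difference(m, pb: ParabolicBarrier):
    """Barrier rise from the inlet, ``F(m) - F(0) = -b1 m**2 + b2 m``.

    Independent of the gauge constant b3.
    """
    m = np.asarray(m, dtype=float)
    out = -pb.b1 * m**2 + pb.b2 * m
    return out if out.ndim else float(out)
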