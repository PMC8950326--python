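"""Steady-state polymer flux through a nanopore.

With a linear friction profile ``C(m) = c1 m + c2`` and a parabolic barrier
``F(m) - F(0) = -b1 m**2 + b2 m`` (b1 > 0), the stationary drift-diffusion
flux through the pore is

    J = P0 / f(N),      f(N) = a**2 beta * Integral_0^N C(m) e^{beta [F(m)-F(0)]} dm

where ``P0`` is the probability that the chain end sits at the pore inlet,
``a`` the monomer size and ``beta = 1/kT``.  The integral has a closed form.
Writing ``alpha = beta b1`` and ``lam = beta b2``, the antiderivative of
``(c1 m + c2) e^{-alpha m**2 + lam m}`` is assembled step by step:

1. complete the square:  -alpha m**2 + lam m
       = -(sqrt(alpha) m - lam/(2 sqrt(alpha)))**2 + lam**2/(4 alpha);
2. Integral e^{-alpha m**2 + lam m} dm
       = (1/2) sqrt(pi/alpha) e^{lam**2/(4 alpha)}
         * erf(sqrt(alpha) m - lam/(2 sqrt(alpha)));
3. Integral m e^{-alpha m**2 + lam m} dm
       = -(1/(2 alpha)) e^{-alpha m**2 + lam m}
         + (lam/(2 alpha)) * [integral from step 2];
4. collect, with alpha = beta b1 and lam = beta b2:

    I(m) = -(c1 / (2 beta b1)) e^{beta(-b1 m**2 + b2 m)}
           + (2 c2 b1 + c1 b2) / (4 b1**1.5) * sqrt(pi/beta)
             * e^{beta b2**2/(4 b1)}
             * erf( sqrt(beta b1) m - sqrt(beta) b2 / (2 sqrt(b1)) )

and ``f(N) = a**2 beta [I(N) - I(0)]``,  ``J = P0 / f(N)``.

Sharp barriers make ``e^{beta b2**2/(4 b1)}`` overflow double precision, so
both the closed form and the adaptive-quadrature oracle are also carried as
``log f(N)`` (peak-scaled), using the scaled complementary error function
``erfcx`` for the product ``e^{z**2} erf(z)``.  The closed form is gated
against quadrature: a relative disagreement in ``log f`` beyond 1e-6 raises
:class:`ClosedFormConsistencyError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

from .free_energy import ParabolicBarrier

__all__ = [
    "FrictionModel",
    "FluxInputs",
    "FluxResult",
    "ClosedFormConsistencyError",
    "barrier_integrand",
    "f_of_N_quadrature",
    "log_f_of_N_quadrature",
    "I_closed_form",
    "f_of_N_closed_form",
    "log_f_of_N_closed_form",
    "flux",
]

_LOG_MAX = math.log(np.finfo(float).max)  # ~709.78


class ClosedFormConsistencyError(ArithmeticError):
    """Closed-form f(N) disagrees with the quadrature oracle beyond tolerance."""


@dataclass(frozen=True)
class FrictionModel:
    """Linear friction profile ``C(m) = c1 m + c2``.

    ``c1`` is the friction per monomer threaded through the pore, ``c2``
    the offset (pore/entry) friction.  ``C`` must stay positive over the
    chain; positivity at both ends of ``[0, N]`` is checked when the model
    is combined with a chain length in :class:`FluxInputs`.
    """

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.c1 < 0:
            raise ValueError(f"per-monomer friction c1 must be >= 0, got {self.c1}")

    def __call__(self, m):
        m = np.asarray(m, dtype=float)
        out = self.c1 * m + self.c2
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class FluxInputs:
    """Everything the stationary flux needs.

    Parameters
    ----------
    pb : ParabolicBarrier
        Barrier coefficients (b1, b2, b3); only b1, b2 enter the flux.
    friction : FrictionModel
        C(m) = c1 m + c2, positive on [0, N].
    N : float
        Number of chain segments.
    beta : float
        Inverse thermal energy 1/kT.
    a : float
        Monomer size (the lattice parameter); chain length l = N a.
    P0 : float
        Probability that the chain end sits at the pore inlet, in [0, 1].
    """

    pb: ParabolicBarrier
    friction: FrictionModel
    N: float
    beta: float = 1.0
    a: float = 1.0
    P0: float = 1.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"need N >= 1, got {self.N}")
        if self.beta <= 0 or self.a <= 0:
            raise ValueError("beta and a must be positive")
        if not (0.0 <= self.P0 <= 1.0):
            raise ValueError(f"inlet probability P0 must lie in [0, 1], got {self.P0}")
        if self.friction(0.0) < 0 or self.friction(self.N) <= 0:
            raise ValueError("friction C(m) must be non-negative on [0, N] "
                             "and positive at m = N")


@dataclass(frozen=True)
class FluxResult:
    """Stationary flux and the barrier integral behind it."""

    J: float
    fN: float            # may be inf when f(N) exceeds double range; see log_fN
    log_fN: float
    method: str          # "closed_form" or "quadrature"
    relative_disagreement: float = field(default=float("nan"))
    inputs: FluxInputs | None = None


def _phi(m, inputs: FluxInputs):
    """Dimensionless barrier rise beta [F(m) - F(0)] = -alpha m^2 + lam m."""
    b = inputs.pb
    return inputs.beta * (-b.b1 * np.asarray(m, dtype=float) ** 2 + b.b2 * np.asarray(m, dtype=float))


def barrier_integrand(m, inputs: FluxInputs):
    """Integrand of f(N): ``C(m) e^{beta[F(m)-F(0)]}``.

    Raises :class:`OverflowError` if the value exceeds double range (use the
    log-space routines for sharp barriers).
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0) or np.any(m_arr > inputs.N):
        raise ValueError("m must lie in [0, N]")
    expo = _phi(m_arr, inputs)
    if np.any(expo > _LOG_MAX):
        raise OverflowError(
            "barrier integrand overflows double precision; "
            "use log_f_of_N_quadrature / log_f_of_N_closed_form"
        )
    out = inputs.friction(m_arr) * np.exp(expo)
    return out if out.ndim else float(out)


def _peak_exponent(inputs: FluxInputs) -> tuple[float, float]:
    """(m_peak, S): maximizer and maximum of phi(m) on [0, N]."""
    b = inputs.pb
    if b.b1 > 0:
        m_peak = min(max(b.b2 / (2.0 * b.b1), 0.0), inputs.N)
    else:  # linear exponent
        m_peak = inputs.N if b.b2 > 0 else 0.0
    return m_peak, float(_phi(m_peak, inputs))


def log_f_of_N_quadrature(inputs: FluxInputs, *, epsrel: float = 1e-12) -> float:
    """log f(N) by peak-scaled adaptive quadrature of the exact integrand."""
    m_peak, S = _peak_exponent(inputs)

    def scaled(m: float) -> float:
        return inputs.friction(m) * math.exp(float(_phi(m, inputs)) - S)

    pts = [m_peak] if 0.0 < m_peak < inputs.N else None
    val, err = integrate.quad(scaled, 0.0, inputs.N, points=pts,
                              limit=400, epsabs=0.0, epsrel=epsrel)
    if not np.isfinite(val) or val <= 0 or (err > 1e-8 * abs(val)):
        raise ArithmeticError(
            f"quadrature of the barrier integral did not converge "
            f"(value={val}, abs error estimate={err})"
        )
    return S + math.log(inputs.a**2 * inputs.beta * val)


def f_of_N_quadrature(inputs: FluxInputs, *, epsrel: float = 1e-12) -> float:
    """Barrier integral f(N) by adaptive quadrature (the module's oracle)."""
    log_f = log_f_of_N_quadrature(inputs, epsrel=epsrel)
    return math.exp(log_f) if log_f <= _LOG_MAX else math.inf


def I_closed_form(m, inputs: FluxInputs):
    """Antiderivative I(m) of the flux integrand (derivation in module docstring).

    Requires b1 > 0 and directly representable exponentials; f(N) itself is
    better obtained from :func:`f_of_N_closed_form`, which subtracts the two
    endpoint evaluations stably.
    """
    b, c = inputs.pb, inputs.friction
    if b.b1 <= 0:
        raise ValueError("closed form requires b1 > 0; use quadrature")
    beta = inputs.beta
    alpha = beta * b.b1
    lam = beta * b.b2
    m = np.asarray(m, dtype=float)
    gauss_peak = lam**2 / (4.0 * alpha)
    if gauss_peak > _LOG_MAX:
        raise OverflowError("e^{beta b2^2/(4 b1)} overflows; use log_f_of_N_closed_form")
    z = np.sqrt(alpha) * m - lam / (2.0 * np.sqrt(alpha))
    term_exp = -(c.c1 / (2.0 * beta * b.b1)) * np.exp(_phi(m, inputs))
    coef = (2.0 * c.c2 * b.b1 + c.c1 * b.b2) / (4.0 * b.b1**1.5) * math.sqrt(math.pi / beta)
    term_erf = coef * math.exp(gauss_peak) * special.erf(z)
    out = term_exp + term_erf
    return out if out.ndim else float(out)


def _log_gauss_erf_diff(alpha: float, lam: float, N: float) -> float:
    """log of G = e^{lam^2/(4 alpha)} [erf(zN) - erf(z0)], evaluated stably.

    z0 = -lam/(2 sqrt(alpha)), zN = sqrt(alpha) N + z0, so zN > z0 and G > 0.
    Uses erfcx(z) = e^{z^2} erfc(z) so no intermediate overflows for the
    one-sided cases; in the straddling case (z0 < 0 < zN) the erf sum is
    O(1) and only the log of the Gaussian peak enters.
    """
    sqa = math.sqrt(alpha)
    z0 = -lam / (2.0 * sqa)
    zN = sqa * N + z0
    if z0 >= 0.0:
        # both tails on the right: G = erfcx(z0) - e^{z0^2-zN^2} erfcx(zN)
        log_lead = math.log(special.erfcx(z0))
        d = (z0 - zN) * (z0 + zN)          # z0^2 - zN^2 <= 0
        r = math.exp(d + math.log(special.erfcx(zN)) - log_lead)
        return log_lead + math.log1p(-r)
    if zN <= 0.0:
        # mirror case via erf(-z) = -erf(z)
        log_lead = (z0 - zN) * (z0 + zN) + math.log(special.erfcx(-zN))  # z0^2-zN^2 >= 0
        r = math.exp(math.log(special.erfcx(-z0)) - log_lead)
        return log_lead + math.log1p(-r)
    # peak inside (0, N): erf(zN) + erf(-z0) is O(1)
    return z0 * z0 + math.log(special.erf(zN) + special.erf(-z0))


def log_f_of_N_closed_form(inputs: FluxInputs) -> float:
    """log f(N) from the erf antiderivative, assembled in signed log space."""
    b, c = inputs.pb, inputs.friction
    if b.b1 <= 0:
        raise ValueError("closed form requires b1 > 0; use quadrature")
    beta = inputs.beta
    alpha = beta * b.b1
    lam = beta * b.b2

    logs: list[float] = []
    signs: list[float] = []

    # exponential term of I(N) - I(0):  (c1/(2 beta b1)) (1 - e^{phi(N)})
    if c.c1 > 0:
        phi_N = float(_phi(inputs.N, inputs))
        log_pref = math.log(c.c1 / (2.0 * beta * b.b1))
        if phi_N < 0.0:
            logs.append(log_pref + math.log1p(-math.exp(phi_N)))
            signs.append(1.0)
        elif phi_N > 0.0:
            logs.append(log_pref + phi_N + math.log1p(-math.exp(-phi_N)))
            signs.append(-1.0)
        # phi_N == 0: term vanishes

    # erf term: (2 c2 b1 + c1 b2)/(4 b1^{3/2}) sqrt(pi/beta) * G
    coef = 2.0 * c.c2 * b.b1 + c.c1 * b.b2
    if coef != 0.0:
        logs.append(
            math.log(abs(coef)) - math.log(4.0 * b.b1**1.5)
            + 0.5 * math.log(math.pi / beta)
            + _log_gauss_erf_diff(alpha, lam, inputs.N)
        )
        signs.append(math.copysign(1.0, coef))

    if not logs:
        raise ArithmeticError("degenerate flux inputs: both closed-form terms vanish")
    total, sign = special.logsumexp(logs, b=signs, return_sign=True)
    if sign <= 0:
        raise ClosedFormConsistencyError(
            "closed-form f(N) evaluated non-positive; inputs outside the "
            "validated domain (quadrature fallback recommended)"
        )
    return math.log(inputs.a**2 * inputs.beta) + float(total)


def f_of_N_closed_form(inputs: FluxInputs, *, check: bool = True,
                       check_tol: float = 1e-6) -> float:
    """Barrier integral f(N) via the erf closed form.

    With ``check=True`` (default) the value is gated against the quadrature
    oracle at relative tolerance ``check_tol`` on log f(N), guarding the
    reconstructed antiderivative.
    """
    log_f = log_f_of_N_closed_form(inputs)
    if check:
        log_q = log_f_of_N_quadrature(inputs)
        scale = max(1.0, abs(log_q))
        if abs(log_f - log_q) > check_tol * scale:
            raise ClosedFormConsistencyError(
                f"closed form log f(N)={log_f:.12g} vs quadrature {log_q:.12g}: "
                f"relative disagreement {abs(log_f - log_q) / scale:.3g}"
            )
    return math.exp(log_f) if log_f <= _LOG_MAX else math.inf


def flux(inputs: FluxInputs, method: str = "auto",
         inlet_probability=None, max_fixed_point_iter: int = 50) -> FluxResult:
    """Stationary polymer flux J = P0 / f(N).

    Parameters
    ----------
    method : {"auto", "closed_form", "quadrature"}
        "auto" uses the closed form when b1 > 0, quadrature otherwise.
    inlet_probability : callable, optional
        Hook for a flux-dependent inlet probability P0(J); iterated to a
        fixed point.  Default (None) is the flux-independent case.

    The result records f(N) both linearly and as log f(N), and — when the
    closed form is used — its relative disagreement with quadrature.
    """
    if method not in ("auto", "closed_form", "quadrature"):
        raise ValueError(f"unknown method {method!r}")
    use_closed = method == "closed_form" or (method == "auto" and inputs.pb.b1 > 0)
    if use_closed:
        log_f = log_f_of_N_closed_form(inputs)
        log_q = log_f_of_N_quadrature(inputs)
        disagreement = abs(log_f - log_q) / max(1.0, abs(log_q))
        if disagreement > 1e-6:
            raise ClosedFormConsistencyError(
                f"closed form vs quadrature log f(N) disagree by {disagreement:.3g}"
            )
        chosen = "closed_form"
    else:
        log_f = log_f_of_N_quadrature(inputs)
        disagreement = float("nan")
        chosen = "quadrature"

    fN = math.exp(log_f) if log_f <= _LOG_MAX else math.inf
    P0 = inputs.P0
    if inlet_probability is not None:
        J = P0 * math.exp(-log_f)
        for _ in range(max_fixed_point_iter):
            P0_new = float(inlet_probability(J))
            if not (0.0 <= P0_new <= 1.0):
                raise ValueError("inlet_probability hook returned P0 outside [0, 1]")
            J_new = P0_new * math.exp(-log_f)
            if abs(J_new - J) <= 1e-14 * max(abs(J), abs(J_new), 1e-300):
                P0, J = P0_new, J_new
                break
            P0, J = P0_new, J_new
    J = P0 * math.exp(-log_f) if P0 > 0 else 0.0
    return FluxResult(J=J, fN=fN, log_fN=log_f, method=chosen,
                      relative_disagreement=disagreement, inputs=inputs)
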