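"""Continuous-time receiver relaxation under a fixed source message.

While a source message x is held, the receiver position performs a
continuous-time Markov jump process whose rates obey local detailed balance
with respect to the landscape U_x:

    r(s'|s, x) / r(s|s', x) = exp( beta [U_x(s) - U_x(s')] ),

so the unique stationary law is the canonical column q(.|x).  We take a fully
connected position graph with unit attempt rates and either Metropolis
(``r = min(1, e^{-beta dU})``) or Glauber (``r = 1/(1 + e^{beta dU})``)
acceptance; both satisfy local detailed balance exactly, and the long-time
kernel ``K = lim_{tau -> inf} exp(G tau)`` is rule-independent.  Holding each
message "long enough" means the receiver re-equilibrates every step, which is
what makes the coarse-grained transition kernel k(y'|y, x) = q(y'|x)
independent of the previous position y.  Timescales here are arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .channel import PotentialTable, _as_prob_vector, channel_from_potentials
from .errors import ConvergenceError, ValidationError

RATE_RULES = ("metropolis", "glauber")


@dataclass(frozen=True)
class RateMatrix:
    """Generator G of the receiver jump process under a fixed source message.

    Off-diagonal ``G[s', s]`` is the rate s -> s'; columns sum to zero, so
    ``u_tau = expm(G tau) @ u0`` conserves probability.
    """

    G: np.ndarray
    source: int
    rule: str

    def __post_init__(self):
        G = np.asarray(self.G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValidationError("rate matrix must be square")
        off = G - np.diag(np.diag(G))
        if np.any(off < 0):
            raise ValidationError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(G.sum(axis=0))) > 1e-10:
            raise ValidationError("rate-matrix columns must sum to zero")
        object.__setattr__(self, "G", G)

    @property
    def n_positions(self) -> int:
        return self.G.shape[0]


@dataclass(frozen=True)
class CoarseGrainedKernel:
    """Long-time transition kernel K with the relaxation time at which the
    column spread dropped below tolerance."""

    K: np.ndarray
    tau_star: float

    def column_spread(self) -> float:
        """Sup-norm spread between kernel columns; ~0 once memory of the
        initial position is lost."""
        return float(np.max(self.K.max(axis=1) - self.K.min(axis=1)))


def build_rate_matrix(
    potentials: PotentialTable, x: int, rule: str = "metropolis"
) -> RateMatrix:
    """Local-detailed-balance rates for the landscape of source message x.

    Fully connected positions, unit attempt rate.  The stationary
    distribution is the canonical column q(.|x) for either rule.
    """
    if rule not in RATE_RULES:
        raise ValidationError(f"unknown rate rule {rule!r}; choose from {RATE_RULES}")
    U = potentials.U[:, x]
    b = potentials.beta
    dU = U[:, None] - U[None, :]  # dU[s', s] = U(s') - U(s)
    if rule == "metropolis":
        R = np.minimum(1.0, np.exp(-b * dU))
    else:
        R = 1.0 / (1.0 + np.exp(b * dU))
    np.fill_diagonal(R, 0.0)
    G = R - np.diag(R.sum(axis=0))
    return RateMatrix(G, source=x, rule=rule)


def relax(rates: RateMatrix, u0, tau: float) -> np.ndarray:
    """Propagate a position distribution: u_tau = expm(G tau) @ u0."""
    if tau < 0:
        raise ValidationError("relaxation time must be nonnegative")
    u0 = _as_prob_vector(u0, "initial distribution")
    if u0.size != rates.n_positions:
        raise ValidationError("initial distribution has wrong length")
    return expm(rates.G * tau) @ u0


def coarse_grained_kernel(
    rates: RateMatrix, tol: float = 1e-10, max_doublings: int = 60
) -> CoarseGrainedKernel:
    """K = lim_{tau -> inf} expm(G tau), by adaptive tau-doubling.

    Doubles tau (by squaring the propagator) until every column agrees with
    every other in sup norm within ``tol``; an irreducible generator always
    converges, so hitting ``max_doublings`` signals a reducible graph.
    """
    tau = 1.0
    K = expm(rates.G * tau)
    for _ in range(max_doublings):
        spread = float(np.max(K.max(axis=1) - K.min(axis=1)))
        if spread < tol:
            return CoarseGrainedKernel(K, tau_star=tau)
        K = K @ K
        tau *= 2.0
    raise ConvergenceError(
        f"kernel failed to converge within tau = {tau:g}; is the generator reducible?"
    )


def stationary_matches_canonical(
    potentials: PotentialTable, x: int, rule: str = "metropolis", tol: float = 1e-10
) -> bool:
    """Check that the long-time kernel reproduces the canonical channel column."""
    K = coarse_grained_kernel(build_rate_matrix(potentials, x, rule), tol=tol)
    target = channel_from_potentials(potentials).column(x)
    return bool(np.max(np.abs(K.K - target[:, None])) < 10 * tol)
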