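"""Priors, receiver potentials, and noisy channels.

A noisy channel is a column-stochastic matrix ``q[y, x] = P(received y | sent x)``
— columns index source messages, rows index received messages.  Channels arise
physically from a receiver that equilibrates in a potential landscape ``U_x(y)``
selected by the current source message ``x``: after relaxation the receiver
position follows the canonical (Boltzmann) distribution

    q(y | x) = exp(beta * (F_x - U_x(y))),
    F_x = -(1/beta) * log( sum_y exp(-beta * U_x(y)) ),

with ``beta`` the inverse temperature and ``F_x`` the free energy of the
landscape for source message ``x``.  Alphabet sizes may differ: a channel with
``n_src`` source messages and ``n_rcv`` receiver positions is ``n_rcv x n_src``.

All message labels in this API are 0-based; file formats (see :mod:`.io`) use
1-based labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .errors import UndefinedPosteriorError, ValidationError

#: drift below which a probability vector is accepted as-is
NORM_TOL = 1e-9
#: drift below which it is renormalized with a warning; beyond this, hard error
RENORM_TOL = 1e-6


def _as_prob_vector(probs, name: str = "probability vector") -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1:
        raise ValidationError(f"{name} must be 1-dimensional, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValidationError(f"{name} contains non-finite entries")
    if np.any(p < 0):
        raise ValidationError(f"{name} contains negative entries")
    drift = abs(p.sum() - 1.0)
    if drift > RENORM_TOL:
        raise ValidationError(f"{name} sums to {p.sum():.12g}, not 1 (drift {drift:.3g})")
    if drift > NORM_TOL:
        warnings.warn(
            f"{name} sum drifted by {drift:.3g}; renormalizing", stacklevel=3
        )
        p = p / p.sum()
    return p


@dataclass(frozen=True)
class Prior:
    """A priori distribution P_X over source messages.

    Parameters
    ----------
    probs : array-like
        Probabilities over source messages, length >= 2, summing to 1
        (tolerance 1e-9; drift up to 1e-6 is renormalized with a warning).
    """

    probs: np.ndarray

    def __post_init__(self):
        p = _as_prob_vector(self.probs, "prior")
        if p.size < 2:
            raise ValidationError("prior needs at least 2 source messages")
        object.__setattr__(self, "probs", p)

    @classmethod
    def two_point(cls, p: float) -> "Prior":
        """Two-source prior (p, 1-p); ``p = P_X(0)``."""
        return cls(np.array([p, 1.0 - p]))

    @classmethod
    def uniform(cls, n: int) -> "Prior":
        return cls(np.full(n, 1.0 / n))

    def __len__(self) -> int:
        return self.probs.size

    def __getitem__(self, x: int) -> float:
        return float(self.probs[x])


@dataclass(frozen=True)
class PotentialTable:
    """Receiver potential landscapes, one column per source message.

    ``U[y, x]`` is the potential energy of receiver position ``y`` under the
    landscape selected by source message ``x``; ``beta`` is the inverse
    temperature (reciprocal energy units).
    """

    U: np.ndarray
    beta: float = 1.0

    def __post_init__(self):
        U = np.asarray(self.U, dtype=float)
        if U.ndim != 2:
            raise ValidationError(f"potential table must be 2-d, got shape {U.shape}")
        if not np.all(np.isfinite(U)):
            raise ValidationError("potential table contains non-finite entries")
        if U.shape[0] < 2:
            raise ValidationError("need at least 2 receiver positions")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValidationError(f"beta must be positive and finite, got {self.beta}")
        object.__setattr__(self, "U", U)

    @property
    def n_src(self) -> int:
        return self.U.shape[1]

    @property
    def n_rcv(self) -> int:
        return self.U.shape[0]

    @classmethod
    def two_well(cls, height: float, beta: float = 1.0) -> "PotentialTable":
        """Two positions, two sources: each source lifts the opposite well by
        ``height`` above its own (the textbook double-well caricature)."""
        return cls(np.array([[0.0, height], [height, 0.0]]), beta=beta)


@dataclass(frozen=True)
class Channel:
    """Column-stochastic channel matrix ``q[y, x] = P(y | x)``.

    Columns are source messages, rows are received messages; each column sums
    to 1 (tolerance 1e-9 on input; drift up to 1e-6 renormalized with a
    warning, beyond that a :class:`ValidationError`).
    """

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2:
            raise ValidationError(f"channel must be 2-d, got shape {q.shape}")
        if not np.all(np.isfinite(q)):
            raise ValidationError("channel contains non-finite entries")
        if np.any(q < 0):
            raise ValidationError("channel contains negative entries")
        if q.shape[1] < 2:
            raise ValidationError("channel needs at least 2 source messages")
        sums = q.sum(axis=0)
        drift = np.abs(sums - 1.0)
        if np.any(drift > RENORM_TOL):
            bad = int(np.argmax(drift))
            raise ValidationError(
                f"channel column {bad} sums to {sums[bad]:.12g}, not 1"
            )
        if np.any(drift > NORM_TOL):
            warnings.warn("channel column sums drifted; renormalizing", stacklevel=3)
            q = q / sums
        object.__setattr__(self, "q", q)

    @property
    def n_src(self) -> int:
        return self.q.shape[1]

    @property
    def n_rcv(self) -> int:
        return self.q.shape[0]

    def column(self, x: int) -> np.ndarray:
        """The conditional distribution q(. | x) over received messages."""
        return self.q[:, x].copy()

    @property
    def strictly_positive(self) -> bool:
        return bool(np.all(self.q > 0))


def free_energies(potentials: PotentialTable) -> np.ndarray:
    """Free energy F_x = -(1/beta) log sum_y exp(-beta U_x(y)) per source.

    Computed with max-shifted exponentials (``logsumexp``), so large
    ``beta * U`` ranges do not overflow.  Shifting a landscape by a constant
    shifts its free energy by the same constant.
    """
    b = potentials.beta
    return -logsumexp(-b * potentials.U, axis=0) / b


def channel_from_potentials(potentials: PotentialTable) -> Channel:
    """Canonical channel q(y|x) = exp(beta (F_x - U_x(y))).

    Every entry is strictly positive and columns are normalized exactly (the
    softmax of ``-beta U`` per column); the map is gauge invariant — adding a
    constant to any landscape leaves its column unchanged.
    """
    q = softmax(-potentials.beta * potentials.U, axis=0)
    # softmax columns sum to 1 only up to rounding; pin them down
    return Channel(q / q.sum(axis=0))


def potentials_from_channel(
    channel: Channel, beta: float = 1.0, offsets=None
) -> PotentialTable:
    """A potential table realizing ``channel``: U[y, x] = -(1/beta) log q[y, x]
    (+ an arbitrary per-column gauge constant ``offsets[x]``).

    Requires a strictly positive channel.
    """
    if not channel.strictly_positive:
        raise ValidationError("only strictly positive channels admit finite potentials")
    U = -np.log(channel.q) / beta
    if offsets is not None:
        U = U + np.asarray(offsets, dtype=float)[None, :]
    return PotentialTable(U, beta=beta)


def output_distribution(channel: Channel, prior: Prior) -> np.ndarray:
    """Marginal P_Y = q @ P_X over received messages."""
    if channel.n_src != len(prior):
        raise ValidationError(
            f"channel has {channel.n_src} sources but prior has {len(prior)}"
        )
    return channel.q @ prior.probs


def posterior(channel: Channel, prior: Prior, y: int) -> np.ndarray:
    """Bayes posterior P(x | y) = q[y, x] P_X(x) / P_Y(y) over sources."""
    py = output_distribution(channel, prior)
    if py[y] <= 0.0:
        raise UndefinedPosteriorError(
            f"received message {y} has zero marginal probability"
        )
    return channel.q[y, :] * prior.probs / py[y]
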