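"""Decision rules and the recoverability / mutual-information calculus.

Given a received message y, a decoder must decide which source message was
sent.  The maximum-likelihood (ML) rule picks ``argmax_x q(y|x)``; the maximum
a posteriori (MAP) rule picks ``argmax_x q(y|x) P_X(x)``.  The pointwise
quantity underlying both is the log-likelihood ratio

    l_y(x, x') = log q(y|x) / q(y|x'),

which splits exactly into a stochastic mutual-information term
``i(x, y) = log q(y|x)/P_Y(y)`` and a stochastic error-information term
``i_e(x', y) = -log q(y|x')/P_Y(y)``.

The *recoverability* R is the ensemble average of l over x ~ P_X, an
independent alternative x' ~ P_X, and y ~ q(.|x):

    R = sum_{x, x', y} P_X(x) P_X(x') q(y|x) log[ q(y|x) / q(y|x') ]  >= 0.

Averaging the pointwise split gives the exact decomposition R = I + I_e with
I the mutual information between source and received messages and I_e the
average spurious correlation between the received message and an independently
drawn source message.  All quantities are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import rel_entr

from .channel import Channel, Prior, output_distribution
from .errors import UndefinedPosteriorError, UndefinedRatioError, ValidationError


class Decision(NamedTuple):
    """A decoded source label plus a flag marking an argmax tie.

    Ties are broken toward the lowest label so decisions are deterministic.
    """

    label: int
    tie: bool


def _log_ratio(num: float, den: float) -> float:
    if num == 0.0 and den == 0.0:
        raise UndefinedRatioError("log ratio 0/0 is undefined")
    if den == 0.0:
        return math.inf
    if num == 0.0:
        return -math.inf
    return math.log(num / den)


def log_likelihood_ratio(channel: Channel, y: int, x: int, x_alt: int) -> float:
    """l_y(x, x') = log q(y|x) / q(y|x') in nats.

    Returns +inf (-inf) when exactly the denominator (numerator) vanishes;
    raises :class:`UndefinedRatioError` if both do.
    """
    return _log_ratio(channel.q[y, x], channel.q[y, x_alt])


def prior_log_ratio(prior: Prior, x: int, x_alt: int) -> float:
    """gamma = log P_X(x) / P_X(x'), the prior's contribution to the MAP ratio."""
    return _log_ratio(prior[x], prior[x_alt])


def map_log_ratio(channel: Channel, prior: Prior, y: int, x: int, x_alt: int) -> float:
    """Log posterior ratio r_y(x, x') = l_y(x, x') + gamma.

    Requires strictly positive prior mass on both messages (the MAP rule is
    undefined outside the prior's support).
    """
    if prior[x] <= 0.0 or prior[x_alt] <= 0.0:
        raise ValidationError("MAP log ratio needs positive prior on both messages")
    return log_likelihood_ratio(channel, y, x, x_alt) + prior_log_ratio(
        prior, x, x_alt
    )


def stochastic_mutual_information(
    channel: Channel, prior: Prior, x: int, y: int
) -> float:
    """i(x, y) = log q(y|x)/P_Y(y): the useful information of x carried by y."""
    py = output_distribution(channel, prior)[y]
    return _log_ratio(channel.q[y, x], py)


def stochastic_error_information(
    channel: Channel, prior: Prior, x_alt: int, y: int
) -> float:
    """i_e(x', y) = -log q(y|x')/P_Y(y): spurious correlation of y with x'."""
    py = output_distribution(channel, prior)[y]
    return -_log_ratio(channel.q[y, x_alt], py)


def decide_ml(channel: Channel, y: int) -> Decision:
    """Maximum-likelihood decoding of a received message."""
    col = channel.q[y, :]
    best = int(np.argmax(col))
    tie = bool(np.sum(col == col[best]) > 1)
    return Decision(best, tie)


def decide_map(channel: Channel, prior: Prior, y: int) -> Decision:
    """Maximum a posteriori decoding of a received message."""
    py = output_distribution(channel, prior)[y]
    if py <= 0.0:
        raise UndefinedPosteriorError(
            f"received message {y} has zero marginal probability"
        )
    score = channel.q[y, :] * prior.probs
    best = int(np.argmax(score))
    tie = bool(np.sum(score == score[best]) > 1)
    return Decision(best, tie)


def _pair_weights(channel: Channel, prior: Prior) -> np.ndarray:
    """Weights P_X(x) P_X(x') q(y|x) on the (y, x, x') grid."""
    p = prior.probs
    return channel.q[:, :, None] * (p[None, :, None] * p[None, None, :])


def recoverability(channel: Channel, prior: Prior) -> float:
    """Ensemble-averaged log-likelihood ratio R, in nats.

    Sums over all ordered source pairs including x = x' (those terms vanish),
    which makes R coincide term-by-term with the entropy production of the
    sequential transfer process under an i.i.d. source.  Returns +inf when a
    weighted log ratio diverges (some q(y|x) > 0 against q(y|x') = 0); zeros
    inside the weight contribute nothing (0 log 0 := 0).
    """
    if channel.n_src != len(prior):
        raise ValidationError("channel/prior size mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.log(channel.q)
        lratio = logq[:, :, None] - logq[:, None, :]
        w = _pair_weights(channel, prior)
        terms = np.where(w > 0, w * lratio, 0.0)
    if np.any(np.isnan(terms)):  # w > 0 against a 0/0 ratio cannot happen; guard anyway
        raise UndefinedRatioError("undefined log ratio with positive weight")
    return float(np.einsum("yxz->", terms))


def mutual_information(channel: Channel, prior: Prior) -> float:
    """I = sum_{x,y} P_X(x) q(y|x) log[q(y|x)/P_Y(y)] >= 0, in nats.

    The Kullback–Leibler divergence of the joint from the product of
    marginals; 0 log 0 := 0, so any valid channel gives a finite value.
    """
    py = output_distribution(channel, prior)
    per_source = rel_entr(channel.q, py[:, None]).sum(axis=0)
    return float(per_source @ prior.probs)


def error_information(channel: Channel, prior: Prior) -> float:
    """I_e = sum_x P_X(x) KL(P_Y || q(.|x)) >= 0, in nats.

    Diverges (+inf) when some column has a zero where P_Y is positive; this
    never happens for canonical (Boltzmann) channels, which are strictly
    positive.
    """
    py = output_distribution(channel, prior)
    per_source = rel_entr(py[:, None], channel.q).sum(axis=0)
    return float(per_source @ prior.probs)


@dataclass(frozen=True)
class InfoSummary:
    """The information budget of a (channel, prior) pair, in nats.

    ``R = I + Ie`` exactly: recoverability splits into useful mutual
    information and error information.
    """

    R: float
    I: float
    Ie: float

    @classmethod
    def from_channel(cls, channel: Channel, prior: Prior) -> "InfoSummary":
        return cls(
            R=recoverability(channel, prior),
            I=mutual_information(channel, prior),
            Ie=error_information(channel, prior),
        )
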