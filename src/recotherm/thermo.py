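"""Entropy production, work accounting, and the generalized Landauer bound.

Receiving a new source message switches the receiver's potential landscape
from U_{x_prev} to U_{x_next} at the currently held position y.  That switch
costs stochastic work ``w = U_{x_next}(y) - U_{x_prev}(y)``, of which the free
energy change ``dF = F_{x_next} - F_{x_prev}`` would be the reversible part;
the dissipated remainder is the stochastic entropy production

    sigma = beta (w - dF) = log q(y | x_prev) / q(y | x_next),

in nats.  Pointwise sigma = i + i_e (useful plus error information), and its
average over an i.i.d. source,

    Sigma = sum_{x_prev, x_next, y} P(x_prev) P(x_next) q(y|x_prev)
            log[ q(y|x_prev) / q(y|x_next) ]  >= 0,

is exactly the recoverability R of the channel: retrieving information has an
unavoidable thermodynamic price.  The averaged work W = Sigma / beta obeys the
generalized Landauer bound W >= I / beta, with gap I_e / beta >= 0; the
averaged free-energy difference vanishes for any i.i.d. source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import rel_entr

from .channel import (
    Channel,
    PotentialTable,
    Prior,
    channel_from_potentials,
    free_energies,
    potentials_from_channel,
)
from .errors import ValidationError
from .recovery import (
    error_information,
    log_likelihood_ratio,
    mutual_information,
)


def stochastic_entropy_production(
    channel: Channel, x_prev: int, x_next: int, y: int
) -> float:
    """sigma = log q(y|x_prev)/q(y|x_next), antisymmetric in the source pair."""
    return log_likelihood_ratio(channel, y, x_prev, x_next)


class WorkRecord(NamedTuple):
    """Work, free-energy difference, and dissipation for one message switch."""

    w: float
    dF: float
    sigma: float


def stochastic_work(
    potentials: PotentialTable, x_prev: int, x_next: int, y: int
) -> WorkRecord:
    """Account the energetics of switching landscapes at held position y.

    ``dF`` is final minus initial free energy, F_{x_next} - F_{x_prev} (the
    reversible part of the switch), so that ``sigma = beta (w - dF)`` agrees
    with the channel log-ratio of the canonical channel generated by the
    same potentials and vanishes when the new landscape is the old one plus
    a constant.
    """
    F = free_energies(potentials)
    w = potentials.U[y, x_next] - potentials.U[y, x_prev]
    dF = F[x_next] - F[x_prev]
    return WorkRecord(float(w), float(dF), float(potentials.beta * (w - dF)))


def entropy_production(channel: Channel, prior: Prior) -> float:
    """Averaged entropy production Sigma, in nats.

    Computed as the prior-pair-weighted sum of Kullback–Leibler divergences
    between channel columns,

        Sigma = sum_{x, x'} P(x) P(x') KL( q(.|x) || q(.|x') ),

    a different summation route from :func:`~recotherm.recovery.recoverability`
    (which averages the log-ratio tensor); the two agree to machine precision.
    Returns +inf when a column pair has disjoint support under positive prior
    weight.
    """
    if channel.n_src != len(prior):
        raise ValidationError("channel/prior size mismatch")
    p = prior.probs
    total = 0.0
    for a in range(channel.n_src):
        if p[a] == 0.0:
            continue
        for b in range(channel.n_src):
            if b == a or p[b] == 0.0:
                continue
            total += p[a] * p[b] * float(
                rel_entr(channel.q[:, a], channel.q[:, b]).sum()
            )
    return float(total)


@dataclass(frozen=True)
class ThermoSummary:
    """Averaged thermodynamics of one information-transfer step.

    Sigma is in nats; W, dF_avg and landauer_margin are in energy units
    (1/beta).  ``landauer_margin = W - I/beta = Ie/beta >= 0``.
    """

    Sigma: float
    W: float
    dF_avg: float
    landauer_margin: float
    beta: float
    I: float
    Ie: float


def average_free_energy_difference(
    potentials: PotentialTable, prior: Prior
) -> float:
    """<dF> = sum_{x, x'} P(x) P(x') (F_x - F_{x'}).

    Vanishes identically for an i.i.d. source (the summand is antisymmetric
    under swapping x and x'); computed explicitly rather than assumed.
    """
    F = free_energies(potentials)
    p = prior.probs
    if F.size != p.size:
        raise ValidationError("potentials/prior size mismatch")
    return float(np.sum(p[:, None] * p[None, :] * (F[:, None] - F[None, :])))


def thermo_summary(
    source, prior: Prior, beta: float | None = None
) -> ThermoSummary:
    """Full thermodynamic summary for a channel or a potential table.

    ``source`` may be a :class:`Channel` (beta defaults to 1; Sigma, I, Ie
    are beta-free given the channel) or a :class:`PotentialTable`, whose
    beta is used and whose free energies supply <dF> directly.
    """
    if isinstance(source, PotentialTable):
        potentials = source
        channel = channel_from_potentials(potentials)
        b = potentials.beta if beta is None else beta
        dF_avg = average_free_energy_difference(potentials, prior)
    elif isinstance(source, Channel):
        channel = source
        b = 1.0 if beta is None else beta
        # <dF> is gauge-independent, so any potential realization will do;
        # channels with zero entries admit no finite realization
        if channel.strictly_positive:
            dF_avg = average_free_energy_difference(
                potentials_from_channel(channel, beta=b), prior
            )
        else:
            dF_avg = float("nan")
    else:
        raise ValidationError(f"expected Channel or PotentialTable, got {type(source)}")
    if b <= 0:
        raise ValidationError("beta must be positive")
    Sigma = entropy_production(channel, prior)
    I = mutual_information(channel, prior)
    Ie = error_information(channel, prior)
    W = Sigma / b
    return ThermoSummary(
        Sigma=Sigma,
        W=W,
        dF_avg=dF_avg,
        landauer_margin=W - I / b,
        beta=b,
        I=I,
        Ie=Ie,
    )
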