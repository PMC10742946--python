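"""Equilibrium / nonequilibrium strength decomposition of a channel.

Any two channel columns split into a half-sum and a half-difference,

    m_y(x, x') = [q(y|x) + q(y|x')] / 2      (equilibrium strength),
    d_y(x, x') = [q(y|x) - q(y|x')] / 2      (nonequilibrium strength),

so q(.|x) = m + d and q(.|x') = m - d.  The point d = 0 is the equilibrium
point: the two source messages produce identical conditionals and cannot be
distinguished by any decoder.  Column normalization forces

    m_y >= 0,  sum_y m_y = 1,  sum_y d_y = 0,
    -m_y <= d_y <= m_y        if m_y <  1/2,
    m_y - 1 <= d_y <= 1 - m_y if m_y >= 1/2.

For a two-source prior (p, 1-p) on a three-outcome channel composed from
(m, d), the mutual information and recoverability have closed forms

    I = p sum_y (m_y + d_y) log[(m_y + d_y) / (m_y + (2p-1) d_y)]
      + (1-p) sum_y (m_y - d_y) log[(m_y - d_y) / (m_y + (2p-1) d_y)],
    R = 2 p (1-p) sum_y d_y log[(m_y + d_y) / (m_y - d_y)],

where m_y + (2p-1) d_y is the output marginal P_Y(y).  Both are convex in d
and vanish iff d = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .channel import Channel, Prior
from .errors import InfeasibleStrengthsError, ValidationError

_FEAS_TOL = 1e-12


@dataclass(frozen=True)
class StrengthDecomposition:
    """The (m, d) split of channel columns ``pair = (x, x')``.

    ``m`` is probability-like (nonnegative, sums to 1); ``d`` is signed and
    sums to 0.  Swapping the pair negates ``d`` and fixes ``m``.
    """

    m: np.ndarray
    d: np.ndarray
    pair: tuple[int, int] = (0, 1)

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if m.shape != d.shape or m.ndim != 1:
            raise ValidationError("m and d must be 1-d vectors of equal length")
        if np.any(m < -_FEAS_TOL):
            raise ValidationError("equilibrium strength m must be nonnegative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValidationError(f"m must sum to 1, got {m.sum():.12g}")
        if abs(d.sum()) > 1e-9:
            raise ValidationError(f"d must sum to 0, got {d.sum():.12g}")
        lo, hi = feasible_interval(m)
        if np.any(d < lo - _FEAS_TOL) or np.any(d > hi + _FEAS_TOL):
            raise InfeasibleStrengthsError(
                f"d={d} outside the feasible box for m={m}"
            )
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "d", d)

    def swapped(self) -> "StrengthDecomposition":
        return StrengthDecomposition(self.m, -self.d, (self.pair[1], self.pair[0]))

    @property
    def at_equilibrium(self) -> bool:
        return bool(np.all(self.d == 0.0))

    @property
    def boundary(self) -> bool:
        """True when a composed column entry vanishes (|d_y| = m_y somewhere)."""
        return bool(np.any(np.isclose(np.abs(self.d), self.m, atol=_FEAS_TOL))
                    or np.any(self.m + np.abs(self.d) >= 1.0 - _FEAS_TOL))


def decompose(channel: Channel, x: int, x_alt: int) -> StrengthDecomposition:
    """Split columns x and x' of a channel into (m, d)."""
    cx, cz = channel.q[:, x], channel.q[:, x_alt]
    return StrengthDecomposition((cx + cz) / 2.0, (cx - cz) / 2.0, (x, x_alt))


def compose(decomp: StrengthDecomposition) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the two channel columns (m + d, m - d).

    The decomposition's constructor validates feasibility, so infeasible
    (m, d) never reach this point; boundary cases (a zero entry) are legal
    and flagged on the decomposition itself.
    """
    a = np.clip(decomp.m + decomp.d, 0.0, None)
    b = np.clip(decomp.m - decomp.d, 0.0, None)
    return a, b


def compose_channel(decomp: StrengthDecomposition) -> Channel:
    """The two-source channel whose columns are (m + d, m - d)."""
    a, b = compose(decomp)
    return Channel(np.column_stack([a, b]))


def feasible_interval(m) -> tuple[np.ndarray, np.ndarray]:
    """Per-component bounds (lo, hi) on d for a given m.

    ``d_y in [-m_y, m_y]`` when ``m_y < 1/2``, else ``[m_y - 1, 1 - m_y]``;
    on top of the box there is the linear constraint ``sum_y d_y = 0``.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
        raise ValidationError("m must be a probability vector")
    half = np.minimum(m, 1.0 - m)
    return -half, half


def closed_form_I_R(p: float, m, d) -> tuple[float, float]:
    """Closed-form (I, R) in nats for the two-source family.

    ``p`` is the prior weight of the first source; (m, d) must be feasible.
    At the boundary (a zero composed entry) R diverges and is returned as
    +inf; I stays finite (0 log 0 := 0).
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    sd = StrengthDecomposition(np.asarray(m, float), np.asarray(d, float))
    m, d = sd.m, sd.d
    py = m + (2.0 * p - 1.0) * d  # output marginal
    a, b = m + d, m - d
    with np.errstate(divide="ignore", invalid="ignore"):
        I = float(
            p * (xlogy(a, a) - xlogy(a, py)).sum()
            + (1.0 - p) * (xlogy(b, b) - xlogy(b, py)).sum()
        )
        terms = np.where(d == 0.0, 0.0, d * (np.log(a) - np.log(b)))
    R = float(2.0 * p * (1.0 - p) * terms.sum())
    return I, R


def sweep_surface(
    p: float,
    m=(1 / 3, 1 / 3, 1 / 3),
    grid_resolution: int = 201,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Tabulate I(d1, d2) and R(d1, d2) over the feasible region.

    For three received messages, d3 = -d1 - d2 is implied by the zero-sum
    constraint, so the free coordinates are (d1, d2).  The grid spans the
    bounding box of the feasible set; points outside feasibility (shrunk by
    ``eps`` to dodge the log divergence of R at the boundary) carry NaN and
    ``feasible=False``.

    Returns a long-format frame with columns d1, d2, I_nats, R_nats, feasible.
    """
    m = np.asarray(m, dtype=float)
    if m.size != 3:
        raise ValidationError("the surface sweep is defined for 3 received messages")
    lo, hi = feasible_interval(m)
    d1 = np.linspace(lo[0], hi[0], grid_resolution)
    d2 = np.linspace(lo[1], hi[1], grid_resolution)
    D1, D2 = np.meshgrid(d1, d2, indexing="ij")
    D3 = -D1 - D2
    feas = (
        (D1 >= lo[0] + eps) & (D1 <= hi[0] - eps)
        & (D2 >= lo[1] + eps) & (D2 <= hi[1] - eps)
        & (D3 >= lo[2] + eps) & (D3 <= hi[2] - eps)
    )
    # vectorized closed forms over the whole grid
    I = np.full(D1.shape, np.nan)
    R = np.full(D1.shape, np.nan)
    ds = np.stack([D1, D2, D3], axis=-1)
    a = m + ds
    b = m - ds
    py = m + (2.0 * p - 1.0) * ds
    with np.errstate(divide="ignore", invalid="ignore"):
        Iall = (
            p * (xlogy(a, a) - xlogy(a, py)).sum(axis=-1)
            + (1 - p) * (xlogy(b, b) - xlogy(b, py)).sum(axis=-1)
        )
        Rall = 2.0 * p * (1.0 - p) * np.where(
            ds == 0.0, 0.0, ds * (np.log(a) - np.log(b))
        ).sum(axis=-1)
    I[feas] = Iall[feas]
    R[feas] = Rall[feas]
    return pd.DataFrame(
        {
            "d1": D1.ravel(),
            "d2": D2.ravel(),
            "I_nats": I.ravel(),
            "R_nats": R.ravel(),
            "feasible": feas.ravel(),
        }
    )
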