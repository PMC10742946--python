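"""Stochastic message sequences and trajectory estimators of R and Sigma.

A transfer trajectory is Z = {(X_1, Y_2), ..., (X_t, Y_{t+1})} with the
source drawn i.i.d. from the prior and each received message drawn from the
channel column of the concurrent source message, so
P(Z) = prod_i P_X(X_i) q(Y_{i+1} | X_i).

Two time-average estimators recover the ensemble quantities:

* ``R' = (1/t) log P(Z)/P(Z')`` where Z' keeps the received sequence but
  randomly permutes the source sequence — the prior factors cancel (the
  permutation preserves the multiset of sources), leaving an average of
  channel log-likelihood ratios that converges to the recoverability R.
* ``Sigma' = (1/t) sum_{i=2..t} log q(Y_i|X_{i-1}) / q(Y_i|X_i)`` — the time
  average of the stochastic entropy production along the same trajectory,
  converging to the ensemble entropy production Sigma = R.

Both estimators are unbiased per increment and their fluctuations shrink as
1/sqrt(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel import Channel, Prior
from .errors import ValidationError

# fixed offsets carving independent streams out of one master seed
_SOURCE_STREAM, _CHANNEL_STREAM, _SHUFFLE_STREAM = 0, 1, 2
_SEED_MOD = 2**31 - 1


def _stream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) * 3 + offset) % _SEED_MOD)


@dataclass(frozen=True)
class Trajectory:
    """An ordered sequence of (source, received) pairs.

    ``x[i]`` and ``y[i]`` hold the i-th pair (X_{i+1}, Y_{i+2}) in 0-based
    storage; labels are 0-based.
    """

    x: np.ndarray
    y: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.int64)
        y = np.asarray(self.y, dtype=np.int64)
        if x.shape != y.shape or x.ndim != 1:
            raise ValidationError("x and y must be 1-d arrays of equal length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class EstimatorTrace:
    """Running average of a trajectory estimator at checkpoint steps."""

    steps: np.ndarray
    values: np.ndarray
    final: float
    #: standard error of the final value from the empirical increment variance
    se_final: float


def _checkpoints(t: int, n: int = 60) -> np.ndarray:
    pts = np.unique(np.geomspace(1, t, num=min(n, t)).astype(np.int64))
    pts[-1] = t
    return pts


def sample_sequences(channel: Channel, prior: Prior, t: int, seed: int) -> Trajectory:
    """Draw a length-t trajectory: X i.i.d. from the prior, Y from q(.|X)."""
    if t < 1:
        raise ValidationError("trajectory length must be at least 1")
    if channel.n_src != len(prior):
        raise ValidationError("channel/prior size mismatch")
    rng_x = _stream(seed, _SOURCE_STREAM)
    rng_y = _stream(seed, _CHANNEL_STREAM)
    x = rng_x.choice(channel.n_src, size=t, p=prior.probs)
    # inverse-CDF sampling of Y against the column of the concurrent source
    cdf = np.cumsum(channel.q, axis=0)
    u = rng_y.random(t)
    y = np.empty(t, dtype=np.int64)
    for lbl in range(channel.n_src):
        mask = x == lbl
        y[mask] = np.searchsorted(cdf[:, lbl], u[mask], side="right")
    np.clip(y, 0, channel.n_rcv - 1, out=y)
    return Trajectory(x=x, y=y, seed=seed)


def shuffle_sources(traj: Trajectory, seed: int) -> Trajectory:
    """The surrogate Z': same received sequence, sources uniformly permuted."""
    rng = _stream(seed, _SHUFFLE_STREAM)
    perm = rng.permutation(len(traj))
    return Trajectory(x=traj.x[perm], y=traj.y.copy(), seed=seed)


def _trace(increments: np.ndarray, t: int) -> EstimatorTrace:
    cum = np.cumsum(increments)
    steps = _checkpoints(t)
    values = cum[np.minimum(steps, increments.size) - 1] / steps
    final = float(cum[-1] / t)
    n = increments.size
    if n > 2 and np.all(np.isfinite(increments)):
        # consecutive increments share a source draw, so include the lag-1
        # autocovariance (Bartlett) in the variance of the mean
        mu = increments.mean()
        v = increments.var(ddof=1)
        c1 = float(np.mean((increments[:-1] - mu) * (increments[1:] - mu)))
        se = float(np.sqrt(max(v + 2.0 * c1, 0.0) / n))
    else:
        se = float("nan")
    return EstimatorTrace(steps=steps, values=values, final=final, se_final=se)


def recoverability_estimator(
    traj: Trajectory, shuffled: Trajectory, channel: Channel, prior: Prior
) -> EstimatorTrace:
    """R'_t = (1/t) [log P(Z) - log P(Z')].

    Computed from the full product-form log-probabilities; the prior terms
    cancel because the shuffle preserves the source multiset, so the
    increments reduce to per-step channel log-likelihood ratios (asserted).
    """
    if not np.array_equal(traj.y, shuffled.y):
        raise ValidationError("surrogate must share the received sequence")
    with np.errstate(divide="ignore"):
        logp = np.log(prior.probs)
        logq = np.log(channel.q)
    inc_full = (logp[traj.x] + logq[traj.y, traj.x]) - (
        logp[shuffled.x] + logq[shuffled.y, shuffled.x]
    )
    inc_channel = logq[traj.y, traj.x] - logq[shuffled.y, shuffled.x]
    if np.all(np.isfinite(inc_full)):
        assert abs(inc_full.sum() - inc_channel.sum()) <= 1e-8 * max(
            1.0, abs(inc_channel).sum()
        ), "prior terms failed to cancel across the shuffle"
    return _trace(inc_channel, len(traj))


def entropy_production_estimator(traj: Trajectory, channel: Channel) -> EstimatorTrace:
    """Sigma'_t = (1/t) sum_{i=2..t} log q(Y_i|X_{i-1}) / q(Y_i|X_i).

    Uses consecutive pairs of the same trajectory: the received message of
    step i-1 is scored under the source that generated it and under the next
    source.  The (t-1)-term sum is divided by t, matching R' normalization.
    """
    t = len(traj)
    if t < 2:
        raise ValidationError("entropy-production estimator needs t >= 2")
    with np.errstate(divide="ignore"):
        logq = np.log(channel.q)
    y_mid = traj.y[:-1]  # Y_i for i = 2..t
    inc = logq[y_mid, traj.x[:-1]] - logq[y_mid, traj.x[1:]]
    return _trace(inc, t)
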