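"""File formats, bundled fixtures, and the random-fixture generator.

Channels are CSV with a header row of 1-based source labels and a first
column of 1-based received labels::

    y,1,2,3
    1,0.4410,0.5558,0.1562
    2,0.4903,0.3848,0.3067
    3,0.0687,0.0594,0.5371

Priors are two-column CSV (``x,prob``) or a JSON label->probability map.
Potential tables use the channel layout preceded by a ``# beta=...``
metadata line.  All writes use 17 significant digits, so write->read
roundtrips are lossless for doubles.  Labels are 1-based in files, 0-based
in the API.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .channel import Channel, PotentialTable, Prior
from .errors import ValidationError

_FMT = "%.17g"


@dataclass(frozen=True)
class FixtureBundle:
    """A named (channel, prior) pair with a provenance note."""

    name: str
    channel: Channel
    prior: Prior
    provenance: str


# ---------------------------------------------------------------- fixtures

#: the worked three-message example used throughout the docs and tests
EXAMPLE_PRIOR = (0.4610, 0.0753, 0.4637)
EXAMPLE_CHANNEL = (
    (0.4410, 0.5558, 0.1562),
    (0.4903, 0.3848, 0.3067),
    (0.0687, 0.0594, 0.5371),
)

#: two-source prior weights p = P_X(1) for the strength-sweep presets
SWEEP_PRESETS = {"a": 0.8212, "b": 0.0154, "c": 0.0430, "d": 0.1690}


def example_bundle() -> FixtureBundle:
    """The bundled worked example: a 3x3 strictly positive channel and its
    non-uniform prior, chosen so that ML and MAP decoding disagree on the
    first received message."""
    return FixtureBundle(
        name="worked-example-3x3",
        channel=Channel(np.array(EXAMPLE_CHANNEL)),
        prior=Prior(np.array(EXAMPLE_PRIOR)),
        provenance="bundled worked example of the package documentation",
    )


def generate_random_fixture(
    n_src: int, n_rcv: int, seed: int, concentration: float = 1.0
) -> FixtureBundle:
    """A strictly positive random (channel, prior) pair, deterministic per seed.

    Channel columns and the prior are independent symmetric Dirichlet draws;
    large ``concentration`` concentrates them near uniform.  Interior
    positivity is enforced by flooring at 1e-12 and renormalizing.
    """
    if n_src < 2 or n_rcv < 2:
        raise ValidationError("need at least 2 source and 2 received messages")
    rng = np.random.default_rng(int(seed) % (2**31 - 1))
    q = rng.dirichlet(np.full(n_rcv, concentration), size=n_src).T
    q = np.clip(q, 1e-12, None)
    q /= q.sum(axis=0)
    p = np.clip(rng.dirichlet(np.full(n_src, concentration)), 1e-12, None)
    p /= p.sum()
    return FixtureBundle(
        name=f"random-{n_src}x{n_rcv}-seed{seed}",
        channel=Channel(q),
        prior=Prior(p),
        provenance=f"synthetic Dirichlet draw (seed={seed}, "
        f"concentration={concentration})",
    )


# ---------------------------------------------------------------- channels


def write_channel(channel: Channel, path) -> None:
    df = pd.DataFrame(
        channel.q,
        index=pd.Index(range(1, channel.n_rcv + 1), name="y"),
        columns=[str(x) for x in range(1, channel.n_src + 1)],
    )
    df.to_csv(path, float_format=_FMT)


def read_channel(path) -> Channel:
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        q = df.to_numpy(dtype=float)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValidationError(f"malformed channel file {path}: {exc}") from exc
    return Channel(q)


# ------------------------------------------------------------------ priors


def write_prior(prior: Prior, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {str(x + 1): float(p) for x, p in enumerate(prior.probs)}
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        pd.DataFrame(
            {"x": range(1, len(prior) + 1), "prob": prior.probs}
        ).to_csv(path, index=False, float_format=_FMT)


def read_prior(path) -> Prior:
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            payload = json.loads(path.read_text())
            labels = sorted(payload, key=int)
            probs = np.array([float(payload[k]) for k in labels])
        else:
            df = pd.read_csv(path, float_precision="round_trip")
            df = df.sort_values(df.columns[0])
            probs = df.iloc[:, 1].to_numpy(dtype=float)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"malformed prior file {path}: {exc}") from exc
    return Prior(probs)


# -------------------------------------------------------------- potentials


def write_potentials(potentials: PotentialTable, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        potentials.U,
        index=pd.Index(range(1, potentials.n_rcv + 1), name="y"),
        columns=[str(x) for x in range(1, potentials.n_src + 1)],
    )
    body = df.to_csv(float_format=_FMT)
    path.write_text(f"# beta={potentials.beta:.17g}\n" + body)


def read_potentials(path) -> PotentialTable:
    path = Path(path)
    lines = path.read_text().splitlines()
    beta = None
    data_lines = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln.lstrip("# ").partition("=")
            if key.strip() == "beta":
                beta = float(val)
        elif ln.strip():
            data_lines.append(ln)
    if beta is None:
        raise ValidationError(f"potentials file {path} lacks a '# beta=' line")
    from io import StringIO

    try:
        df = pd.read_csv(StringIO("\n".join(data_lines)), index_col=0,
                         float_precision="round_trip")
        U = df.to_numpy(dtype=float)
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"malformed potentials file {path}: {exc}") from exc
    return PotentialTable(U, beta=beta)
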