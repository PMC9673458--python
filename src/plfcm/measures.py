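"""Distance and similarity measures between PLTSs.

The distance is a probabilistic linguistic Euclidean distance: after
normalization and zero-probability padding to a common length ``l``, each
aligned position is scalarized as (g-transformed membership) x (probability)
and the root-mean-square difference of the position values is taken.  Both
coordinates live in [0, 1], so the distance does too.

A similarity degree is obtained from the distance through a decreasing
Z-mapping recalibration::

    S(a, b) = (Z(d(a, b)) - Z(1)) / (Z(0) - Z(1))

Four standard Z forms are provided (linear, rational, exponential,
quadratic).  Every form yields S in [0, 1], S = 1 exactly at d = 0 and S = 0
exactly at d = 1 (which for single-term extreme PLTSs is the complement
relation).
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

from .plts import PLTS, PLTSError, g_transform, pad_pair

#: The four Z-mapping recalibrations, keyed by the names used throughout the
#: package (CLI, reports, sensitivity tables).
Z_FORMS: dict[str, Callable[[float], float]] = {
    "linear": lambda t: 1 - t,
    "rational": lambda t: (1 - t) / (1 + t),
    "exponential": lambda t: 1 - t * math.exp(t - 1),
    "quadratic": lambda t: 1 - t * t,
}


def _position_values(plts: PLTS) -> list[float]:
    tau = plts.scale.tau
    return [((t + tau) / (2 * tau)) * p for t, p in plts.entries]


def plts_distance(a: PLTS, b: PLTS) -> float:
    """Probabilistic linguistic Euclidean distance in [0, 1].

    Operands are normalized, padded to the common length
    ``l = max(len(a), len(b))`` and aligned position by position in ascending
    term order; position value = g(term) * probability.
    """
    if a.scale != b.scale:
        raise PLTSError("distance requires a common scale")
    a, b = pad_pair(a.normalize(), b.normalize())
    va, vb = _position_values(a), _position_values(b)
    sq = sum((x - y) ** 2 for x, y in zip(va, vb)) / len(va)
    return math.sqrt(sq)


def values_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Root-mean-square distance between two equal-length [0,1] vectors.

    Used by the degenerate map variants: the hesitant baseline compares raw
    membership vectors (probabilities dropped), the crisp baseline compares
    scalar activations (length-1 vectors).
    """
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    sq = sum((x - y) ** 2 for x, y in zip(a, b)) / len(a)
    return math.sqrt(sq)


def similarity_from_distance(d: float, z_form: str = "rational") -> float:
    """Recalibrate a distance in [0, 1] into a similarity via a Z mapping."""
    try:
        z = Z_FORMS[z_form]
    except KeyError:
        raise ValueError(
            f"unknown Z form {z_form!r}; choose from {sorted(Z_FORMS)}"
        ) from None
    d = min(max(d, 0.0), 1.0)
    return (z(d) - z(1.0)) / (z(0.0) - z(1.0))


def plts_similarity(a: PLTS, b: PLTS, z_form: str = "rational") -> float:
    """Similarity degree between two PLTSs under the chosen Z form."""
    return similarity_from_distance(plts_distance(a, b), z_form)
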