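"""Probabilistic linguistic term sets (PLTS).

A PLTS attaches a probability to each linguistic term an assessor hesitates
over, e.g. ``{s-3:0.5, s0:0.3, s3:0.2}`` — "50% very poor, 30% average, 20%
very good".  It is the universal value type of this package: both concept
states and edge weights of a probabilistic linguistic fuzzy cognitive map
are PLTSs.

All arithmetic is carried out in membership space through the equivalent
transformation ``g(alpha) = (alpha + tau) / (2 tau)`` which maps term indices
``[-tau, tau]`` onto ``[0, 1]``, and its inverse ``g^-1(eta) = (2 eta - 1) tau``.
The t-norm/t-conorm pair used on memberships is the algebraic product and the
probabilistic sum; probabilities combine multiplicatively over the Cartesian
pairing of entries.

Tolerances: probability sums are checked at 1e-9; transformation round trips
hold to 1e-12.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .scales import LinguisticScale

PROB_TOL = 1e-9
ROUND_TRIP_TOL = 1e-12
#: decimal places used to merge duplicate memberships produced by the
#: Cartesian operators (see merge rationale in docs/methods.md)
_MERGE_DECIMALS = 12


class PLTSError(ValueError):
    """Invalid PLTS construction or operation."""


def _fmt_num(x: float) -> str:
    """Compact exact formatting: integers without a decimal point."""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


@dataclass(frozen=True)
class PLTS:
    """A probabilistic linguistic term set on a given scale.

    ``entries`` is an ascending-term tuple of ``(term_index, probability)``
    pairs.  Term indices supplied by users are integers and pairwise distinct
    (the parser and the pooling operation merge duplicates); PLTSs produced
    by map iteration may carry continuous (real-valued) indices, because the
    inverse transformation of an iterated membership generally falls between
    scale terms, and coincident indices, because distinct aligned positions
    can saturate to the same value.  Entries therefore only need to be in
    ascending term order here.
    """

    entries: tuple[tuple[float, float], ...]
    scale: LinguisticScale

    def __post_init__(self) -> None:
        entries = tuple((float(t), float(p)) for t, p in self.entries)
        object.__setattr__(self, "entries", entries)
        if not entries:
            raise PLTSError("a PLTS needs at least one entry")
        total = 0.0
        prev = -math.inf
        for term, prob in entries:
            if not self.scale.contains(term):
                raise PLTSError(
                    f"term index {term} outside scale range "
                    f"[-{self.scale.tau}, {self.scale.tau}]"
                )
            if not (-PROB_TOL <= prob <= 1 + PROB_TOL):
                raise PLTSError(f"probability {prob} outside [0, 1]")
            # rounding in the iteration can disturb saturated neighbouring
            # positions by an ulp; anything beyond noise level is a real error
            if term < prev - 1e-9:
                raise PLTSError("entries must be in ascending term order")
            prev = term
            total += prob
        if total > 1 + PROB_TOL:
            raise PLTSError(f"probabilities sum to {total} > 1")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[float, float]], scale: LinguisticScale
    ) -> "PLTS":
        """Build from unordered ``(term, probability)`` pairs.

        Duplicate terms are merged by summing probabilities and the result is
        sorted into ascending term order.
        """
        acc: dict[float, float] = {}
        for term, prob in pairs:
            acc[float(term)] = acc.get(float(term), 0.0) + float(prob)
        if not acc:
            raise PLTSError("a PLTS needs at least one entry")
        return cls(tuple(sorted(acc.items())), scale)

    # -- basic views ----------------------------------------------------------

    @property
    def terms(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.entries)

    @property
    def probabilities(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __str__(self) -> str:
        body = ", ".join(f"s{_fmt_num(t)}:{_fmt_num(p)}" for t, p in self.entries)
        return "{" + body + "}"

    # -- operations -----------------------------------------------------------

    def normalize(self) -> "PLTS":
        """Rescale probabilities to sum to one (the standard PLTS form).

        Idempotent; term indices, zero-probability entries and order are
        preserved.  Raises :class:`PLTSError` when all probabilities are zero.
        """
        total = sum(self.probabilities)
        if total <= 0:
            raise PLTSError("cannot normalize a PLTS with all-zero probabilities")
        if abs(total - 1) <= PROB_TOL:
            return self
        return PLTS(tuple((t, p / total) for t, p in self.entries), self.scale)

    def score(self) -> float:
        """Probability-weighted expectation of the term indices.

        Computed on the normalized probabilities; lies in ``[-tau, tau]``.
        """
        norm = self.normalize()
        return sum(t * p for t, p in norm.entries)

    def complement(self) -> "PLTS":
        """Mirror the PLTS about the neutral term (negate term indices)."""
        return PLTS(
            tuple((-t, p) for t, p in reversed(self.entries)), self.scale
        )


@dataclass(frozen=True)
class TransformedPLTS:
    """A PLTS carried into membership space by the g transformation.

    Entries are ``(membership, probability)`` pairs with both coordinates in
    ``[0, 1]``, in ascending membership order; ``scale`` remembers where the
    memberships came from so the inverse transformation can restore term
    indices exactly.
    """

    entries: tuple[tuple[float, float], ...]
    scale: LinguisticScale

    def __post_init__(self) -> None:
        entries = tuple((float(m), float(p)) for m, p in self.entries)
        object.__setattr__(self, "entries", entries)
        if not entries:
            raise PLTSError("a transformed PLTS needs at least one entry")
        for m, p in entries:
            if not (-PROB_TOL <= m <= 1 + PROB_TOL):
                raise PLTSError(f"membership {m} outside [0, 1]")
            if not (-PROB_TOL <= p <= 1 + PROB_TOL):
                raise PLTSError(f"probability {p} outside [0, 1]")

    @property
    def memberships(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.entries)

    @property
    def probabilities(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# -- equivalent transformations ----------------------------------------------


def g_transform(x: "PLTS | float", scale: LinguisticScale | None = None):
    """Map term indices to unit-interval memberships, ``(alpha + tau) / (2 tau)``.

    Accepts either a PLTS (its scale is used; probabilities are carried
    through unchanged) or a bare term index together with ``scale``.
    """
    if isinstance(x, PLTS):
        tau = x.scale.tau
        return TransformedPLTS(
            tuple(((t + tau) / (2 * tau), p) for t, p in x.entries), x.scale
        )
    if scale is None:
        raise TypeError("g_transform of a bare term index requires a scale")
    if not scale.contains(x):
        raise PLTSError(f"term index {x} outside [-{scale.tau}, {scale.tau}]")
    return (float(x) + scale.tau) / (2 * scale.tau)


def g_inverse(t: "TransformedPLTS | float", scale: LinguisticScale | None = None):
    """Inverse transformation, membership -> term index ``(2 eta - 1) tau``.

    The result of iterating a map is generally a non-integer term index;
    such continuous indices are valid PLTS terms here.
    """
    if isinstance(t, TransformedPLTS):
        tau = t.scale.tau
        return PLTS(
            tuple(((2 * m - 1) * tau, p) for m, p in t.entries), t.scale
        )
    if scale is None:
        raise TypeError("g_inverse of a bare membership requires a scale")
    m = float(t)
    if not (-PROB_TOL <= m <= 1 + PROB_TOL):
        raise PLTSError(f"membership {m} outside [0, 1]")
    return (2 * m - 1) * scale.tau


# -- length padding ------------------------------------------------------------


def pad_pair(a: PLTS, b: PLTS) -> tuple[PLTS, PLTS]:
    """Pad the shorter PLTS with zero-probability terms to a common length.

    The added entries repeat the shorter set's smallest term index with
    probability zero, so original entries are unchanged and the padded pair
    can be compared position by position.
    """
    if a.scale != b.scale:
        raise PLTSError("cannot pad PLTSs on different scales")
    la, lb = len(a), len(b)
    if la == lb:
        return a, b

    def _pad(x: PLTS, k: int) -> PLTS:
        fill = ((x.entries[0][0], 0.0),) * k
        return PLTS(fill + x.entries, x.scale)

    if la < lb:
        return _pad(a, lb - la), b
    return a, _pad(b, la - lb)


# -- Cartesian operators --------------------------------------------------------


def _combine(
    a: PLTS, b: PLTS, op
) -> PLTS:
    """Cartesian pairing of two PLTSs under a membership-space operator.

    Every entry of ``a`` is paired with every entry of ``b``; memberships are
    combined by ``op`` and probabilities multiply.  Duplicate resulting
    memberships are merged by summing their probabilities, and the result is
    returned in ascending membership order (hence ascending term order).
    """
    if a.scale != b.scale:
        raise PLTSError("operands must share a scale")
    ga, gb = g_transform(a), g_transform(b)
    acc: dict[float, float] = {}
    for m1, p1 in ga.entries:
        for m2, p2 in gb.entries:
            m = op(m1, m2)
            key = round(m, _MERGE_DECIMALS)
            acc[key] = acc.get(key, 0.0) + p1 * p2
    entries = tuple(sorted(acc.items()))
    return g_inverse(TransformedPLTS(entries, a.scale))


def plts_add(a: PLTS, b: PLTS) -> PLTS:
    """Probabilistic-sum aggregation: memberships combine as ``x + y - xy``."""
    return _combine(a, b, lambda x, y: x + y - x * y)


def plts_mult(a: PLTS, b: PLTS) -> PLTS:
    """Product aggregation: memberships combine as ``x * y``."""
    return _combine(a, b, lambda x, y: x * y)


def scalar_mult(c: float, a: PLTS) -> PLTS:
    """Scalar multiple: each membership becomes ``1 - (1 - eta)^c``."""
    if c <= 0:
        raise PLTSError(f"scalar must be positive, got {c}")
    ga = g_transform(a)
    entries = tuple(sorted((1 - (1 - m) ** c, p) for m, p in ga.entries))
    return g_inverse(TransformedPLTS(entries, a.scale))


def plts_power(a: PLTS, c: float) -> PLTS:
    """Power: each membership becomes ``eta^c``."""
    if c <= 0:
        raise PLTSError(f"exponent must be positive, got {c}")
    ga = g_transform(a)
    entries = tuple(sorted((m**c, p) for m, p in ga.entries))
    return g_inverse(TransformedPLTS(entries, a.scale))


# -- expert pooling --------------------------------------------------------------


def aggregate_expert_opinions(
    opinions: Sequence[PLTS], weights: Sequence[float] | None = None
) -> PLTS:
    """Pool several experts' PLTS judgements into one group PLTS.

    The pooled probability of each linguistic term is the weighted mean of
    that term's probability across experts (experts not mentioning a term
    contribute zero).  Equal weights by default; the result is normalized.
    """
    if not opinions:
        raise PLTSError("need at least one opinion")
    scale = opinions[0].scale
    if any(o.scale != scale for o in opinions):
        raise PLTSError("all opinions must share a scale")
    n = len(opinions)
    if weights is None:
        weights = [1.0 / n] * n
    if len(weights) != n:
        raise PLTSError(f"{n} opinions but {len(weights)} weights")
    if any(w < 0 for w in weights):
        raise PLTSError("weights must be nonnegative")
    if abs(sum(weights) - 1) > PROB_TOL:
        raise PLTSError(f"weights must sum to 1, got {sum(weights)}")
    acc: dict[float, float] = {}
    for opinion, w in zip(opinions, weights):
        for term, prob in opinion.entries:
            acc[term] = acc.get(term, 0.0) + w * prob
    return PLTS.from_pairs(acc.items(), scale).normalize()


# -- text syntax ------------------------------------------------------------------

_ENTRY_RE = re.compile(r"s\s*(-?\d+(?:\.\d+)?)\s*:\s*([0-9.eE+-]+)")


def parse_plts(
    text: str, scale: LinguisticScale, integer_terms: bool = False
) -> PLTS:
    """Parse the ``{s-3:0.5, s0:0.3, s3:0.2}`` syntax into a PLTS.

    Entries may appear in any order; duplicates are merged.  With
    ``integer_terms`` the parser refuses continuous term indices (the rule
    for user-supplied model and matrix files).
    """
    body = text.strip()
    if body.startswith("{") and body.endswith("}"):
        body = body[1:-1]
    if not body.strip():
        raise PLTSError("empty PLTS string")
    pairs: list[tuple[float, float]] = []
    consumed = 0
    for match in _ENTRY_RE.finditer(body):
        term = float(match.group(1))
        try:
            prob = float(match.group(2))
        except ValueError as exc:
            raise PLTSError(f"bad probability in {text!r}") from exc
        if integer_terms and not term.is_integer():
            raise PLTSError(f"non-integer term index s{match.group(1)} in {text!r}")
        pairs.append((term, prob))
        consumed += 1
    leftover = _ENTRY_RE.sub("", body).replace(",", "").strip()
    if consumed == 0 or leftover:
        raise PLTSError(f"cannot parse PLTS from {text!r}")
    return PLTS.from_pairs(pairs, scale)


def format_plts(plts: PLTS) -> str:
    """Canonical text form: ascending terms, compact probabilities."""
    return str(plts)
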