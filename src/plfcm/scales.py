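"""Symmetric linguistic term scales.

A linguistic scale is an ordered set of 2*tau + 1 terms ``s_-tau .. s_tau``
centred on a neutral term ``s_0``.  Term indices are the working currency of
every probabilistic linguistic term set (PLTS); the scale fixes the affine
bijection g between term indices and unit-interval memberships.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LinguisticScale:
    """A symmetric term scale ``s_-tau .. s_tau``.

    Parameters
    ----------
    tau : int
        Granularity parameter; the scale has ``2 * tau + 1`` terms.
    labels : tuple of str, optional
        Human-readable names for the terms, ordered from ``s_-tau`` up to
        ``s_tau``.  If given, exactly ``2 * tau + 1`` labels are required.
    """

    tau: int
    labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.tau, int) or self.tau < 1:
            raise ValueError(f"tau must be a positive integer, got {self.tau!r}")
        if self.labels is not None:
            labels = tuple(self.labels)
            object.__setattr__(self, "labels", labels)
            if len(labels) != 2 * self.tau + 1:
                raise ValueError(
                    f"expected {2 * self.tau + 1} labels for tau={self.tau}, "
                    f"got {len(labels)}"
                )

    @property
    def n_terms(self) -> int:
        return 2 * self.tau + 1

    def contains(self, index: float) -> bool:
        """Whether a (possibly non-integer) term index lies on the scale."""
        return -self.tau <= index <= self.tau

    def label(self, index: int) -> str:
        """Readable name of an integer term index (falls back to ``s<i>``)."""
        if not float(index).is_integer() or not self.contains(index):
            raise ValueError(f"no label for term index {index!r} on {self}")
        if self.labels is None:
            return f"s{int(index)}"
        return self.labels[int(index) + self.tau]

    def __repr__(self) -> str:  # compact: labels rarely matter in debugging
        return f"LinguisticScale(tau={self.tau})"


#: Default scale for concept states (11 terms, s_-5 .. s_5).
STATE_SCALE = LinguisticScale(tau=5)

#: Default scale for edge weights (7 terms, s_-3 .. s_3), from
#: "very strong negative impact" up to "very strong positive impact".
WEIGHT_SCALE = LinguisticScale(
    tau=3,
    labels=(
        "very strong negative",
        "strong negative",
        "weak negative",
        "undetermined",
        "weak positive",
        "strong positive",
        "very strong positive",
    ),
)
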