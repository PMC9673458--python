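"""Two-channel iteration of a probabilistic linguistic fuzzy cognitive map.

The map is first aligned on a canonical position template: the ascending
union of all term indices appearing in any state or weight.  State PLTSs are
expanded onto the template with probability zero at absent positions; weight
PLTSs are padded positionally to the template length (zero-probability copies
of their smallest term).  After alignment the model is a pair of node-by-position matrices
(memberships H and probabilities P) plus, per edge, a position-wise weight
membership and weight probability vector.

Each step updates the two channels independently, position by position:

* membership channel:  ``a_i^k = 1 - prod_{j -> i} (1 - H[j,k] * wm[j,i,k])``
  then ``H'[i,k] = f(H[i,k] + a - H[i,k] * a)`` with ``f(x) = tanh(lam * x)``;
* probability channel: the same probabilistic-sum aggregation on P with the
  edge probabilities, followed by ``f`` and a per-node renormalization so
  every probability row keeps summing to one.

The membership channel never reads probabilities, so two maps differing only
in probabilities have identical membership trajectories — the mechanism by
which the hesitant (probability-free) variant reproduces the membership
results exactly.

Iteration stops at a fixed point (max-norm change over both channels below
``tol``), at a limit cycle (the state recurs within a sliding window), or at
the iteration cap (classified chaotic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import PLFCModel
from .plts import PLTS, PROB_TOL

Status = str  # "fixed_point" | "limit_cycle" | "chaotic"


class ConvergenceError(RuntimeError):
    """The map did not reach a fixed point."""


def threshold(x, lam: float = 1.0):
    """Hyperbolic-tangent squashing ``tanh(lam * x)``; odd and increasing."""
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    return np.tanh(lam * np.asarray(x, dtype=float)) if np.ndim(x) else math.tanh(
        lam * x
    )


@dataclass(frozen=True)
class IterationSettings:
    """Knobs of the iteration.

    lam
        Steepness of the tanh threshold (> 0).  Larger values saturate the
        activations faster and compress differences between nodes.
    tol
        Fixed-point / recurrence tolerance in max norm.
    max_iter
        Iteration cap; hitting it without convergence is classified chaotic.
        The probability channel contracts slowly near its fixed point, so the
        cap is generous relative to typical convergence times (several
        hundred steps at lam = 1).
    cycle_window
        How many recent states are scanned for recurrence (limit cycles).
    threshold_fn
        Optional replacement squashing hook ``f(array, lam) -> array`` with
        values in [0, 1]; the default is ``tanh(lam * x)``.
    prob_apply_threshold
        Whether the squashing is applied to the probability channel before
        renormalization (default) or skipped there.
    """

    lam: float = 1.0
    tol: float = 1e-6
    max_iter: int = 2000
    cycle_window: int = 50
    threshold_fn: Callable[[np.ndarray, float], np.ndarray] | None = None
    prob_apply_threshold: bool = True

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def squash(self, x: np.ndarray) -> np.ndarray:
        f = self.threshold_fn
        out = np.tanh(self.lam * x) if f is None else np.asarray(f(x, self.lam))
        if np.any(out < -PROB_TOL) or np.any(out > 1 + PROB_TOL):
            raise ValueError("threshold function left [0, 1]")
        return np.clip(out, 0.0, 1.0)


@dataclass
class AlignedModel:
    """A map expanded onto the canonical position template."""

    node_ids: list[str]
    template: tuple[float, ...]
    h0: np.ndarray  # (n, l) initial memberships
    p0: np.ndarray  # (n, l) initial probabilities (rows sum to 1)
    adj: np.ndarray  # (n, n) bool, adj[j, i] = edge j -> i
    wm: np.ndarray  # (n, n, l) edge weight memberships (0 where no edge)
    wp: np.ndarray  # (n, n, l) edge weight probabilities (0 where no edge)


def canonical_align(model: PLFCModel) -> AlignedModel:
    """Expand states and weights onto the global ascending term template.

    The template is the sorted union of term indices appearing in any state
    or weight.  States are term-aligned on the template (probability zero at
    absent positions) and g-transformed on the state scale, so every node
    shares the same initial membership row.  Weights are padded positionally
    to the template length by repeating their smallest term with probability
    zero (the standard zero-probability padding), then g-transformed on the
    weight scale: position k of an edge weight pairs with position k of the
    source state, and its membership is that of the expert-elicited term
    itself.  A singleton "very strong positive" weight therefore exerts full
    influence at every position rather than only at the position whose
    template term happens to coincide with it.
    """
    if not model.nodes:
        raise ValueError("empty model")
    terms: set[float] = set()
    for node in model.nodes:
        terms.update(node.initial_state.terms)
    for weight in model.edges.values():
        terms.update(weight.terms)
    template = tuple(sorted(terms))
    l = len(template)
    n = len(model.nodes)
    ids = model.node_ids
    index = {nid: i for i, nid in enumerate(ids)}

    def expand_probs(plts: PLTS) -> np.ndarray:
        norm = plts.normalize()
        lookup = {t: p for t, p in norm.entries}
        return np.array([lookup.get(t, 0.0) for t in template])

    tau_s = model.state_scale.tau
    tau_w = model.weight_scale.tau
    h_template = np.array([(t + tau_s) / (2 * tau_s) for t in template])

    def pad_weight(weight: PLTS) -> tuple[np.ndarray, np.ndarray]:
        norm = weight.normalize()
        fill = l - len(norm)
        terms = [norm.entries[0][0]] * fill + [t for t, _ in norm.entries]
        probs = [0.0] * fill + [p for _, p in norm.entries]
        memberships = np.array([(t + tau_w) / (2 * tau_w) for t in terms])
        return memberships, np.array(probs)

    h0 = np.tile(h_template, (n, 1))
    p0 = np.stack([expand_probs(node.initial_state) for node in model.nodes])
    adj = np.zeros((n, n), dtype=bool)
    wm = np.zeros((n, n, l))
    wp = np.zeros((n, n, l))
    for (src, dst), weight in model.edges.items():
        j, i = index[src], index[dst]
        adj[j, i] = True
        wm[j, i], wp[j, i] = pad_weight(weight)
    return AlignedModel(
        node_ids=list(ids), template=template, h0=h0, p0=p0, adj=adj, wm=wm, wp=wp
    )


def iterate_step(
    h: np.ndarray,
    p: np.ndarray,
    aligned: AlignedModel,
    settings: IterationSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """One synchronous update of both channels.

    Returns the next (membership, probability) matrices; probability rows are
    renormalized to sum to one.
    """
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(p))):
        raise ValueError("non-finite state")
    adj = aligned.adj[:, :, None]  # (j, i, 1)
    # probabilistic-sum aggregation over incoming edges, per position
    factors_m = np.where(adj, 1.0 - h[:, None, :] * aligned.wm, 1.0)
    factors_p = np.where(adj, 1.0 - p[:, None, :] * aligned.wp, 1.0)
    a = 1.0 - np.prod(factors_m, axis=0)  # (i, k)
    b = 1.0 - np.prod(factors_p, axis=0)
    h_next = settings.squash(h + a - h * a)
    q = p + b - p * b
    if settings.prob_apply_threshold:
        q = settings.squash(q)
    row_sums = q.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("probability row collapsed to zero")
    return h_next, q / row_sums


@dataclass
class IterationTrace:
    """Per-step state history with terminal classification.

    ``membership_history`` and ``probability_history`` include the initial
    state as step 0; ``n_iter`` counts the update steps actually applied.
    """

    node_ids: list[str]
    template: tuple[float, ...]
    membership_history: list[np.ndarray]
    probability_history: list[np.ndarray]
    status: Status
    n_iter: int
    cycle_length: int | None = None
    settings: IterationSettings = field(default_factory=IterationSettings)

    @property
    def final_memberships(self) -> np.ndarray:
        return self.membership_history[-1]

    @property
    def final_probabilities(self) -> np.ndarray:
        return self.probability_history[-1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: step, node, position, term, membership, probability."""
        rows = []
        for step, (hm, pm) in enumerate(
            zip(self.membership_history, self.probability_history)
        ):
            for i, nid in enumerate(self.node_ids):
                for k, term in enumerate(self.template):
                    rows.append(
                        (step, nid, k, term, hm[i, k], pm[i, k])
                    )
        return pd.DataFrame(
            rows,
            columns=["step", "node", "position", "term", "membership", "probability"],
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _max_change(h1, p1, h2, p2) -> float:
    return max(np.abs(h1 - h2).max(), np.abs(p1 - p2).max())


def run(model: PLFCModel, settings: IterationSettings | None = None) -> IterationTrace:
    """Iterate the map to a terminal state.

    Stops when the max-norm change over both channels drops below ``tol``
    (fixed point), when the state recurs within ``cycle_window`` steps (limit
    cycle, with the recurrence distance as ``cycle_length``), or at
    ``max_iter`` (chaotic).
    """
    if settings is None:
        settings = IterationSettings()
    aligned = canonical_align(model)
    h, p = aligned.h0.copy(), aligned.p0.copy()
    hs, ps = [h], [p]
    status: Status = "chaotic"
    cycle_length = None
    n_iter = 0
    for step in range(settings.max_iter):
        h_next, p_next = iterate_step(h, p, aligned, settings)
        hs.append(h_next)
        ps.append(p_next)
        n_iter = step + 1
        if _max_change(h_next, p_next, h, p) <= settings.tol:
            status = "fixed_point"
            break
        # scan the sliding window for a recurrence (cycle length >= 2)
        lo = max(0, len(hs) - 1 - settings.cycle_window)
        for back in range(len(hs) - 3, lo - 1, -1):
            if _max_change(h_next, p_next, hs[back], ps[back]) <= settings.tol:
                status = "limit_cycle"
                cycle_length = (len(hs) - 1) - back
                break
        if status == "limit_cycle":
            break
        h, p = h_next, p_next
    return IterationTrace(
        node_ids=aligned.node_ids,
        template=aligned.template,
        membership_history=hs,
        probability_history=ps,
        status=status,
        n_iter=n_iter,
        cycle_length=cycle_length,
        settings=settings,
    )


def steady_state_plts(trace: IterationTrace, model: PLFCModel) -> dict[str, PLTS]:
    """Back-transform the converged state into one PLTS per node.

    Memberships are mapped through the inverse transformation on the state
    scale (term indices are continuous); probabilities come from the final
    probability channel.  All template positions are kept — coincident term
    values are not merged, so every node's steady PLTS has the same length
    and positions stay aligned for distance computation.
    """
    if trace.status != "fixed_point":
        raise ConvergenceError(
            f"steady state requires a fixed point, got status {trace.status!r}"
        )
    tau = model.state_scale.tau
    out: dict[str, PLTS] = {}
    h, p = trace.final_memberships, trace.final_probabilities
    for i, nid in enumerate(trace.node_ids):
        # memberships are weakly ascending in template order (the update is
        # monotone position-wise), so entries are already term-sorted; keeping
        # template order leaves tied saturated positions aligned across nodes
        pairs = tuple(
            ((2 * h[i, k] - 1) * tau, p[i, k]) for k in range(len(trace.template))
        )
        out[nid] = PLTS(pairs, model.state_scale)
    return out
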