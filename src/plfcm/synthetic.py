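"""Seeded random map generator for property testing.

Generated maps mimic the shape of expert-elicited health maps: a handful of
factor nodes plus one outcome node, three-term PLTS states on the tau=5
scale, and PLTS edge weights on the tau=3 scale whose probability mass leans
toward negative or positive terms according to a configurable sign mix.
They are *not* calibrated to any survey — their role is to exercise the
engine and the ranking pipeline over many structures, deterministically per
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ConceptNode, PLFCModel
from .plts import PLTS
from .scales import LinguisticScale


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random map draw.

    n_nodes counts all concepts including the single outcome node; the
    directed edge density is the probability of each ordered non-self pair
    carrying an edge; sign_mix is the share of negative-leaning weights;
    concentration is the Dirichlet parameter for probability vectors (1 =
    uniform over the simplex, larger = more even probabilities).
    """

    n_nodes: int = 8
    edge_density: float = 0.3
    sign_mix: float = 0.3
    term_template: tuple[int, ...] = (-3, 0, 3)
    concentration: float = 1.0
    seed: int = 0
    state_tau: int = 5
    weight_tau: int = 3

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes (one factor and the outcome)")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")
        if not (0 <= self.sign_mix <= 1):
            raise ValueError("sign_mix must be in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if len(self.term_template) < 1:
            raise ValueError("term template cannot be empty")


def generate_synthetic(spec: SyntheticSpec) -> PLFCModel:
    """Draw a random map; identical output for identical specs.

    States are PLTSs over the full term template with Dirichlet-distributed
    probabilities (mimicking survey proportions).  Edge weights mimic pooled
    expert judgements: a contiguous run of one to three terms on one side of
    the weight scale (negative-leaning runs within ``[-tau_w, 0]``, positive
    within ``[0, tau_w]``).  Every node is guaranteed at least one incoming
    positive-leaning edge, as in elicited causal maps where each concept has
    at least one reinforcing driver.
    """
    rng = np.random.default_rng(spec.seed)
    state_scale = LinguisticScale(spec.state_tau)
    weight_scale = LinguisticScale(spec.weight_tau)
    template = tuple(sorted(spec.term_template))
    alpha = np.full(len(template), spec.concentration)
    tau_w = spec.weight_tau

    def draw_state() -> PLTS:
        return PLTS(tuple(zip(template, rng.dirichlet(alpha))), state_scale)

    def draw_weight(leaning: str) -> PLTS:
        k = int(rng.integers(1, min(3, tau_w) + 1))
        if leaning == "negative":
            start = int(rng.integers(-tau_w, 1 - k + 1))
        else:
            start = int(rng.integers(0, tau_w - k + 2))
        terms = range(start, start + k)
        probs = rng.dirichlet(np.full(k, spec.concentration))
        return PLTS(tuple(zip(terms, probs)), weight_scale)

    ids = [f"F{i}" for i in range(1, spec.n_nodes)] + ["R"]
    nodes = [
        ConceptNode(
            id=nid,
            initial_state=draw_state(),
            role="outcome" if nid == "R" else "factor",
            group="" if nid == "R" else f"G{(i % 3) + 1}",
        )
        for i, nid in enumerate(ids)
    ]
    edges: dict[tuple[str, str], PLTS] = {}
    leanings: dict[tuple[str, str], str] = {}
    for src in ids:
        for dst in ids:
            if src == dst:
                continue
            if rng.random() < spec.edge_density:
                leaning = "negative" if rng.random() < spec.sign_mix else "positive"
                edges[(src, dst)] = draw_weight(leaning)
                leanings[(src, dst)] = leaning
    for dst in ids:  # ensure at least one positive-leaning driver per node
        has_positive = any(
            leanings.get((src, dst)) == "positive" for src in ids if src != dst
        )
        if not has_positive:
            others = [s for s in ids if s != dst]
            src = others[int(rng.integers(0, len(others)))]
            edges[(src, dst)] = draw_weight("positive")
            leanings[(src, dst)] = "positive"
    return PLFCModel(
        nodes=nodes, edges=edges, state_scale=state_scale, weight_scale=weight_scale
    )
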