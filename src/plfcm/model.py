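"""The probabilistic linguistic fuzzy cognitive map model and its file formats.

A map is a directed graph whose concept nodes carry PLTS-valued initial
states (on the state scale, default tau=5) and whose edges carry PLTS-valued
influence weights (on the weight scale, default tau=3).  Exactly one node
plays the outcome role; every other node is a candidate causal factor.

Two text formats are supported:

* a YAML model file with ``scale_state`` / ``scale_weight`` / ``nodes`` /
  ``edges`` blocks, round-tripping bit-exactly through
  :func:`load_model` / :func:`save_model`;
* a delimited connection-matrix table (rows = source, columns = target,
  cells = PLTS strings or blank for "no edge") for transcribing externally
  supplied weight matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .plts import PLTS, PLTSError, format_plts, parse_plts
from .scales import LinguisticScale

VALID_ROLES = ("factor", "outcome")


class ModelError(ValueError):
    """Structurally invalid map or unreadable model file."""


@dataclass(frozen=True)
class ConceptNode:
    """A concept (system variable) of the map."""

    id: str
    initial_state: PLTS
    label: str = ""
    group: str = ""
    role: str = "factor"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ModelError(f"role must be one of {VALID_ROLES}, got {self.role!r}")
        self.initial_state.normalize()  # raises if degenerate


@dataclass
class PLFCModel:
    """Concept nodes plus a PLTS-valued directed weight matrix."""

    nodes: list[ConceptNode]
    edges: dict[tuple[str, str], PLTS] = field(default_factory=dict)
    state_scale: LinguisticScale = field(default_factory=lambda: LinguisticScale(5))
    weight_scale: LinguisticScale = field(default_factory=lambda: LinguisticScale(3))

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate node ids")
        outcomes = [n.id for n in self.nodes if n.role == "outcome"]
        if len(outcomes) != 1:
            raise ModelError(
                f"exactly one outcome node required, found {len(outcomes)}"
            )
        known = set(ids)
        for (src, dst), weight in self.edges.items():
            if src == dst:
                raise ModelError(f"self-edge on {src!r} is not allowed")
            if src not in known or dst not in known:
                raise ModelError(f"edge ({src!r}, {dst!r}) references unknown node")
            weight.normalize()
        for node in self.nodes:
            if node.initial_state.scale != self.state_scale:
                raise ModelError(
                    f"node {node.id!r} initial state is not on the state scale"
                )
        for key, weight in self.edges.items():
            if weight.scale != self.weight_scale:
                raise ModelError(f"edge {key!r} weight is not on the weight scale")

    # -- lookups ---------------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    @property
    def outcome_id(self) -> str:
        return next(n.id for n in self.nodes if n.role == "outcome")

    @property
    def factor_ids(self) -> list[str]:
        return [n.id for n in self.nodes if n.role != "outcome"]

    def node(self, node_id: str) -> ConceptNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def groups(self) -> dict[str, list[str]]:
        """Factor ids per first-level group (ungrouped factors are skipped)."""
        out: dict[str, list[str]] = {}
        for n in self.nodes:
            if n.role == "outcome" or not n.group:
                continue
            out.setdefault(n.group, []).append(n.id)
        return out

    def with_edges(self, edges: dict[tuple[str, str], PLTS]) -> "PLFCModel":
        return PLFCModel(
            nodes=list(self.nodes),
            edges=dict(edges),
            state_scale=self.state_scale,
            weight_scale=self.weight_scale,
        )


# -- YAML model files ------------------------------------------------------------


def load_model(path: str | Path) -> PLFCModel:
    """Read a model file (see :func:`save_model` for the layout)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ModelError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ModelError(f"{path}: expected a mapping at top level")
    try:
        state_scale = LinguisticScale(int(raw["scale_state"]["tau"]))
        weight_scale = LinguisticScale(int(raw["scale_weight"]["tau"]))
        nodes = []
        for spec in raw["nodes"]:
            nodes.append(
                ConceptNode(
                    id=str(spec["id"]),
                    label=str(spec.get("label", "")),
                    group=str(spec.get("group", "")),
                    role=str(spec.get("role", "factor")),
                    initial_state=parse_plts(
                        spec["initial"], state_scale, integer_terms=True
                    ),
                )
            )
        edges: dict[tuple[str, str], PLTS] = {}
        for spec in raw.get("edges") or []:
            key = (str(spec["from"]), str(spec["to"]))
            edges[key] = parse_plts(spec["weight"], weight_scale, integer_terms=True)
    except (KeyError, TypeError, PLTSError) as exc:
        raise ModelError(f"{path}: {exc}") from exc
    return PLFCModel(
        nodes=nodes, edges=edges, state_scale=state_scale, weight_scale=weight_scale
    )


def model_to_dict(model: PLFCModel) -> dict:
    doc: dict = {
        "scale_state": {"tau": model.state_scale.tau},
        "scale_weight": {"tau": model.weight_scale.tau},
        "nodes": [
            {
                "id": n.id,
                "label": n.label,
                "group": n.group,
                "role": n.role,
                "initial": format_plts(n.initial_state),
            }
            for n in model.nodes
        ],
        "edges": [
            {"from": src, "to": dst, "weight": format_plts(w)}
            for (src, dst), w in sorted(model.edges.items())
        ],
    }
    return doc


def save_model(model: PLFCModel, path: str | Path) -> None:
    """Write the canonical YAML form (deterministic key and edge order)."""
    text = yaml.safe_dump(
        model_to_dict(model), sort_keys=False, default_flow_style=False, width=100
    )
    Path(path).write_text(text)


def dumps_model(model: PLFCModel) -> str:
    return yaml.safe_dump(
        model_to_dict(model), sort_keys=False, default_flow_style=False, width=100
    )


# -- connection-matrix tables ------------------------------------------------------


def read_matrix(
    path: str | Path, weight_scale: LinguisticScale | None = None
) -> dict[tuple[str, str], PLTS]:
    """Read a delimited connection matrix of PLTS cells.

    Rows are source nodes, columns target nodes; blank cells mean "no edge".
    Malformed cells are reported with their row and column labels.
    """
    if weight_scale is None:
        weight_scale = LinguisticScale(3)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    edges: dict[tuple[str, str], PLTS] = {}
    for src in df.index:
        for dst in df.columns:
            cell = str(df.loc[src, dst]).strip()
            if not cell or cell == "0":
                continue
            if src == dst:
                raise ModelError(
                    f"{path}: self-edge weight at row {src!r}, column {dst!r}"
                )
            try:
                edges[(src, dst)] = parse_plts(
                    cell, weight_scale, integer_terms=True
                )
            except PLTSError as exc:
                raise ModelError(
                    f"{path}: bad PLTS at row {src!r}, column {dst!r}: {exc}"
                ) from exc
    return edges


def write_matrix_template(
    node_ids: list[str], path: str | Path,
    edges: dict[tuple[str, str], PLTS] | None = None,
) -> None:
    """Write a connection-matrix table (blank template unless edges given)."""
    data = {
        dst: [
            format_plts(edges[(src, dst)])
            if edges and (src, dst) in edges
            else ""
            for src in node_ids
        ]
        for dst in node_ids
    }
    df = pd.DataFrame(data, index=node_ids)
    df.index.name = "node"
    df.to_csv(path)
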