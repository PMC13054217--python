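"""Safety-first decision engine: wound state -> treatment recommendation.

The clinical logic lives in a JSON decision tree (shipped as package data,
``data/decision_tree.json``), not in code: each internal node tests one
wound attribute and branches on its value; each leaf carries exactly one
(ointment, dressing) pair.  The engine here is a generic, auditable
interpreter for such trees plus an exhaustive validator.

The default tree encodes guideline-derived wound-bed-preparation logic
with a strict safety layer: an occlusive (moisture-retaining) dressing is
never recommended when the wound is infected or when an undermined pocket
contains necrotic tissue, because sealing such wounds risks abscess
formation.  Rule precedence on the chronic branch is therefore
infection > pocket > necrosis > (wound bed x exudate).  Leaves covering
wound states beyond the ten calibration scenarios are marked
``"extension": true`` in the JSON so the generalized rules are auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .state import (
    DRESSINGS,
    OINTMENTS,
    DressingOption,
    Recommendation,
    WoundState,
    enumerate_states,
    iter_field_values,
)

__all__ = [
    "DecisionNode",
    "DecisionTree",
    "TreeError",
    "UncoveredStateError",
    "ValidationReport",
    "load_default_tree",
    "recommend",
    "safety_check",
    "validate_tree",
]


class TreeError(ValueError):
    """Structurally invalid decision tree."""


class UncoveredStateError(TreeError):
    """The tree has no leaf for a given wound state."""


@dataclass(frozen=True)
class DecisionNode:
    id: str
    question: Optional[str] = None          # attribute tested, None for leaves
    branches: dict[str, str] = field(default_factory=dict)
    payload: Optional[tuple[int, int]] = None  # (ointment code, dressing code)
    extension: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.payload is not None


@dataclass(frozen=True)
class DecisionTree:
    nodes: dict[str, DecisionNode]
    root: str
    version: str

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        doc = json.loads(text)
        nodes = {}
        for node_id, spec in doc["nodes"].items():
            payload = spec.get("payload")
            if payload is not None:
                payload = (int(payload["ointment"]), int(payload["dressing"]))
            node = DecisionNode(
                id=node_id,
                question=spec.get("question"),
                branches=dict(spec.get("branches", {})),
                payload=payload,
                extension=bool(spec.get("extension", False)),
            )
            if node.is_leaf == bool(node.branches):
                raise TreeError(
                    f"node {node_id!r} must be either a leaf with a payload "
                    "or an internal node with branches"
                )
            if node.is_leaf:
                o, d = node.payload
                if o not in OINTMENTS or d not in DRESSINGS:
                    raise TreeError(f"leaf {node_id!r} has unknown option code")
            nodes[node_id] = node
        root = doc["root"]
        if root not in nodes:
            raise TreeError(f"root node {root!r} not present")
        return cls(nodes=nodes, root=root, version=str(doc.get("version", "0")))

    def to_json(self) -> str:
        """Canonical serialization (stable key order, round-trip safe)."""
        doc: dict = {"version": self.version, "root": self.root, "nodes": {}}
        for node_id in sorted(self.nodes):
            node = self.nodes[node_id]
            spec: dict = {}
            if node.question is not None:
                spec["question"] = node.question
            if node.branches:
                spec["branches"] = dict(sorted(node.branches.items()))
            if node.payload is not None:
                spec["payload"] = {
                    "ointment": node.payload[0],
                    "dressing": node.payload[1],
                }
            if node.extension:
                spec["extension"] = True
            doc["nodes"][node_id] = spec
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def load_default_tree() -> DecisionTree:
    """The decision tree shipped with the package."""
    text = (resources.files("woundcdss") / "data" / "decision_tree.json").read_text()
    return DecisionTree.from_json(text)


def safety_check(state: WoundState, dressing: DressingOption) -> bool:
    """False iff an occlusive dressing is paired with a contraindication.

    Occlusion is contraindicated when the wound shows clear signs of
    infection or when an undermined pocket contains necrotic tissue
    (abscess risk); in every other situation any dressing passes.
    """
    if not dressing.occlusive_flag:
        return True
    return state.infection.value != "present" and state.pocket.value != "present_with_necrosis"


def recommend(state: WoundState, tree: Optional[DecisionTree] = None) -> Recommendation:
    """Walk the tree from the root to a leaf and return its payload.

    The returned trace is the ordered list of node ids visited, root to
    leaf.  Raises :class:`UncoveredStateError` if the tree is not total
    over the supplied state.
    """
    if tree is None:
        tree = load_default_tree()
    node = tree.nodes[tree.root]
    trace = [node.id]
    while not node.is_leaf:
        value = getattr(state, node.question).value
        child_id = node.branches.get(value)
        if child_id is None or child_id not in tree.nodes:
            raise UncoveredStateError(
                f"no branch for {node.question}={value!r} at node {node.id!r}; "
                f"uncovered state: {state.to_dict()}"
            )
        node = tree.nodes[child_id]
        trace.append(node.id)
    o_code, d_code = node.payload
    return Recommendation(
        ointment=OINTMENTS[o_code],
        dressing=DRESSINGS[d_code],
        trace=tuple(trace),
    )


@dataclass
class ValidationReport:
    uncovered_states: list[dict] = field(default_factory=list)
    unsafe_leaves: list[str] = field(default_factory=list)
    unreachable_nodes: list[str] = field(default_factory=list)
    non_exhaustive_nodes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.uncovered_states
            or self.unsafe_leaves
            or self.unreachable_nodes
            or self.non_exhaustive_nodes
        )

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "uncovered_states": self.uncovered_states,
            "unsafe_leaves": self.unsafe_leaves,
            "unreachable_nodes": self.unreachable_nodes,
            "non_exhaustive_nodes": self.non_exhaustive_nodes,
        }


def validate_tree(
    tree: DecisionTree, states: Optional[Iterable[WoundState]] = None
) -> ValidationReport:
    """Exhaustively audit a tree for totality, safety and dead nodes.

    Walks every enumerable wound state through the tree, recording states
    with no path to a leaf and leaves whose dressing fails
    :func:`safety_check` for any state that reaches them; nodes never
    visited by any state are reported as unreachable, and internal nodes
    whose branch map does not cover the tested attribute's full value set
    are reported as non-exhaustive.
    """
    report = ValidationReport()
    for node in tree.nodes.values():
        if node.is_leaf:
            continue
        missing = set(iter_field_values(node.question)) - set(node.branches)
        if missing:
            report.non_exhaustive_nodes.append(node.id)
    if states is None:
        states = enumerate_states()
    visited: set[str] = set()
    unsafe: set[str] = set()
    for state in states:
        try:
            rec = recommend(state, tree)
        except UncoveredStateError:
            report.uncovered_states.append(state.to_dict())
            continue
        visited.update(rec.trace)
        if not safety_check(state, rec.dressing):
            unsafe.add(rec.trace[-1])
    report.unsafe_leaves = sorted(unsafe)
    report.unreachable_nodes = sorted(set(tree.nodes) - visited)
    return report
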