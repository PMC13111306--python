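"""The symbolic corneal knowledge graph.

A layered directed acyclic graph with three node categories:

* **parameter** nodes — measured or derived biometric quantities (K1, K2,
  Kmax, CCT, axial length, ACD, astigmatism, I-S asymmetry);
* **diagnosis** nodes — ``early_keratoconus`` and ``normal_cornea``;
* **decision** nodes — ``surgery_candidate`` and ``surgery_contraindicated``.

Edges point parameter→diagnosis, diagnosis→decision or parameter→decision
and carry a weight in [0, 1] interpreted as a link probability in the
noisy-OR combiner.  Every edge leaving a parameter node carries a
:class:`ThresholdRule` stating when the parameter constitutes evidence:
direction ``above``/``below`` a threshold τ with a logistic softness s
(s = 0 is a hard step).  Evidence activation for a rule is

    a = σ((x − τ)/s)   for ``above``,  mirrored for ``below``,

which is monotone in the feature and recovers rule-book 0/1 behavior as
s → 0.  The shipped default graph lives in ``data/default_graph.json``;
every threshold, weight and prior is config-overridable because the
clinically tuned values are site-specific.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import networkx as nx

from .biometry import BiometricRecord, DerivedFeatures
from .maps import MapIndices

__all__ = [
    "NodeSpec",
    "ThresholdRule",
    "EdgeSpec",
    "KnowledgeGraph",
    "ActivationEntry",
    "EvidenceActivation",
    "GraphSchemaError",
    "build_default_graph",
    "validate_graph",
    "save_graph",
    "load_graph",
    "export_graphml",
    "activate_evidence",
    "rule_activation",
]

log = logging.getLogger(__name__)

GRAPH_SCHEMA_VERSION = "1"
CATEGORIES = ("parameter", "diagnosis", "decision")
_LAYER = {"parameter": 0, "diagnosis": 1, "decision": 2}

#: Features a rule may reference and where each resolves from.
RECORD_FEATURES = ("k1_D", "k2_D", "kmax_D", "cct_um", "axial_length_mm", "acd_mm", "astigmatism_D")
DERIVED_FEATURES = ("mean_k_D", "astig_kdiff_D", "kmax_excess_D")
MAP_FEATURES = ("is_asymmetry_D", "max_power_D")


class GraphSchemaError(ValueError):
    """Raised when a serialized graph fails schema or invariant checks."""


@dataclass(frozen=True)
class NodeSpec:
    node_id: str
    category: str
    label: str
    labels: Mapping[str, str] = field(default_factory=dict)  # language code -> label

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise GraphSchemaError(f"node {self.node_id!r}: unknown category {self.category!r}")


@dataclass(frozen=True)
class ThresholdRule:
    rule_id: str
    parameter: str
    direction: str  # "above" | "below"
    threshold: float
    softness: float  # logistic scale in feature units; 0 = hard step

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise GraphSchemaError(f"rule {self.rule_id!r}: direction must be above/below")
        if not math.isfinite(self.threshold):
            raise GraphSchemaError(f"rule {self.rule_id!r}: threshold must be finite")
        if self.softness < 0:
            raise GraphSchemaError(f"rule {self.rule_id!r}: softness must be >= 0")


@dataclass(frozen=True)
class EdgeSpec:
    source: str
    target: str
    weight: float
    rule: ThresholdRule | None = None


@dataclass(frozen=True)
class KnowledgeGraph:
    nodes: tuple[NodeSpec, ...]
    edges: tuple[EdgeSpec, ...]
    priors: Mapping[str, float]  # diagnosis node_id -> prior probability
    version: str = GRAPH_SCHEMA_VERSION

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def categories_present(self) -> set[str]:
        return {n.category for n in self.nodes}

    def rule_edges(self, target: str | None = None) -> list[EdgeSpec]:
        return [
            e
            for e in self.edges
            if e.rule is not None and (target is None or e.target == target)
        ]

    def rule(self, rule_id: str) -> ThresholdRule:
        for e in self.edges:
            if e.rule is not None and e.rule.rule_id == rule_id:
                return e.rule
        raise KeyError(rule_id)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.node_id, category=n.category, label=n.label)
        for e in self.edges:
            attrs = {"weight": e.weight}
            if e.rule is not None:
                attrs.update(
                    rule_id=e.rule.rule_id,
                    parameter=e.rule.parameter,
                    direction=e.rule.direction,
                    threshold=e.rule.threshold,
                    softness=e.rule.softness,
                )
            g.add_edge(e.source, e.target, **attrs)
        return g


# ---------------------------------------------------------------------------
# validation


def validate_graph(graph: KnowledgeGraph) -> list[str]:
    """Return every invariant violation (empty list = valid graph)."""
    violations: list[str] = []
    ids = [n.node_id for n in graph.nodes]
    if len(set(ids)) != len(ids):
        violations.append("duplicate node ids")
    by_id = {n.node_id: n for n in graph.nodes}

    for e in graph.edges:
        tag = f"edge {e.source}->{e.target}"
        src, tgt = by_id.get(e.source), by_id.get(e.target)
        if src is None or tgt is None:
            violations.append(f"{tag}: dangling node reference")
            continue
        if _LAYER[src.category] >= _LAYER[tgt.category]:
            violations.append(f"{tag}: breaks parameter->diagnosis->decision layering")
        if not 0.0 <= e.weight <= 1.0:
            violations.append(f"{tag}: weight {e.weight} outside [0, 1]")
        if src.category == "parameter" and e.rule is None:
            violations.append(f"{tag}: parameter-source edge lacks a threshold rule")

    nxg = graph.to_networkx()
    if not nx.is_directed_acyclic_graph(nxg):
        violations.append("graph contains a cycle")

    for n in graph.nodes:
        if n.category == "diagnosis":
            prior = graph.priors.get(n.node_id)
            if prior is None:
                violations.append(f"diagnosis node {n.node_id!r}: missing prior")
            elif not 0.0 < prior < 1.0:
                violations.append(f"diagnosis node {n.node_id!r}: prior {prior} outside (0, 1)")
    return violations


# ---------------------------------------------------------------------------
# serialization


def _graph_to_obj(graph: KnowledgeGraph) -> dict:
    return {
        "version": graph.version,
        "priors": dict(graph.priors),
        "nodes": [
            {"node_id": n.node_id, "category": n.category, "label": n.label, "labels": dict(n.labels)}
            for n in graph.nodes
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "weight": e.weight,
                "rule": None
                if e.rule is None
                else {
                    "rule_id": e.rule.rule_id,
                    "parameter": e.rule.parameter,
                    "direction": e.rule.direction,
                    "threshold": e.rule.threshold,
                    "softness": e.rule.softness,
                },
            }
            for e in graph.edges
        ],
    }


def _graph_from_obj(obj: dict) -> KnowledgeGraph:
    try:
        version = str(obj["version"])
        if version != GRAPH_SCHEMA_VERSION:
            raise GraphSchemaError(
                f"graph schema version {version!r} not supported (expected {GRAPH_SCHEMA_VERSION!r})"
            )
        nodes = tuple(
            NodeSpec(
                node_id=str(n["node_id"]),
                category=str(n["category"]),
                label=str(n["label"]),
                labels=dict(n.get("labels", {})),
            )
            for n in obj["nodes"]
        )
        edges = tuple(
            EdgeSpec(
                source=str(e["source"]),
                target=str(e["target"]),
                weight=float(e["weight"]),
                rule=None
                if e.get("rule") is None
                else ThresholdRule(
                    rule_id=str(e["rule"]["rule_id"]),
                    parameter=str(e["rule"]["parameter"]),
                    direction=str(e["rule"]["direction"]),
                    threshold=float(e["rule"]["threshold"]),
                    softness=float(e["rule"]["softness"]),
                ),
            )
            for e in obj["edges"]
        )
        priors = {str(k): float(v) for k, v in obj["priors"].items()}
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, GraphSchemaError):
            raise
        raise GraphSchemaError(f"malformed graph file: {exc}") from exc
    graph = KnowledgeGraph(nodes=nodes, edges=edges, priors=priors, version=version)
    violations = validate_graph(graph)
    if violations:
        raise GraphSchemaError("graph fails validation: " + "; ".join(violations))
    return graph


def save_graph(graph: KnowledgeGraph, path: str | Path) -> Path:
    """Canonical JSON serialization (sorted keys, explicit version)."""
    path = Path(path)
    path.write_text(json.dumps(_graph_to_obj(graph), indent=1, sort_keys=True), encoding="utf-8")
    return path


def load_graph(path: str | Path) -> KnowledgeGraph:
    """Load a graph; any graph this accepts passes :func:`validate_graph`."""
    with open(path, encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GraphSchemaError(f"{path}: invalid JSON: {exc}") from exc
    return _graph_from_obj(obj)


def export_graphml(graph: KnowledgeGraph, path: str | Path) -> Path:
    """GraphML export (for visualization tools); node/edge attrs flattened."""
    path = Path(path)
    nx.write_graphml(graph.to_networkx(), path)
    return path


def build_default_graph(config: Mapping | None = None) -> KnowledgeGraph:
    """Load the shipped default clinical graph, with optional overrides.

    ``config`` may carry ``priors`` (diagnosis -> prior) and ``rules``
    (rule_id -> {threshold, softness, weight}) overriding the shipped
    defaults without editing the data file.
    """
    from importlib.resources import files

    obj = json.loads(files("kerasym.data").joinpath("default_graph.json").read_text(encoding="utf-8"))
    graph = _graph_from_obj(obj)
    if not config:
        return graph
    priors = dict(graph.priors)
    priors.update(config.get("priors", {}))
    overrides = config.get("rules", {})
    edges = []
    for e in graph.edges:
        if e.rule is not None and e.rule.rule_id in overrides:
            o = overrides[e.rule.rule_id]
            rule = replace(
                e.rule,
                threshold=float(o.get("threshold", e.rule.threshold)),
                softness=float(o.get("softness", e.rule.softness)),
            )
            e = replace(e, rule=rule, weight=float(o.get("weight", e.weight)))
        edges.append(e)
    out = KnowledgeGraph(nodes=graph.nodes, edges=tuple(edges), priors=priors, version=graph.version)
    violations = validate_graph(out)
    if violations:
        raise GraphSchemaError("override produced an invalid graph: " + "; ".join(violations))
    return out


# ---------------------------------------------------------------------------
# evidence activation


@dataclass(frozen=True)
class ActivationEntry:
    """Evaluation of one rule-bearing edge against one record."""

    rule_id: str
    feature: str
    observed: float
    threshold: float
    direction: str
    activation: float  # in [0, 1]
    weight: float
    target: str  # node id the edge points into
    hard: bool  # softness == 0

    @property
    def fired(self) -> bool:
        """A rule 'fires' when its feature is strictly past the threshold."""
        return self.activation > 0.5


@dataclass(frozen=True)
class EvidenceActivation:
    """All rule evaluations for one eye, plus skipped-rule notices."""

    eye_id: str
    entries: tuple[ActivationEntry, ...]
    skipped: tuple[str, ...] = ()

    def for_target(self, target: str) -> list[ActivationEntry]:
        return [e for e in self.entries if e.target == target]


def rule_activation(rule: ThresholdRule, x: float) -> float:
    """Logistic evidence activation; s = 0 degenerates to a hard step."""
    z = x - rule.threshold if rule.direction == "above" else rule.threshold - x
    if rule.softness == 0.0:
        if z > 0:
            return 1.0
        return 0.5 if z == 0 else 0.0
    # guard overflow for extreme arguments
    t = z / rule.softness
    if t >= 0:
        return 1.0 / (1.0 + math.exp(-t))
    e = math.exp(t)
    return e / (1.0 + e)


def activate_evidence(
    record: BiometricRecord,
    features: DerivedFeatures,
    map_indices: MapIndices | None,
    graph: KnowledgeGraph,
) -> EvidenceActivation:
    """Evaluate every rule-bearing edge of the graph against one eye.

    Rules on map-derived features are skipped (with a logged notice) when no
    map indices are supplied; any other unresolvable feature is an error.
    """
    values: dict[str, float | None] = dict(record.as_dict())
    values.update(features.as_dict())
    if map_indices is not None:
        values.update(map_indices.as_dict())

    entries: list[ActivationEntry] = []
    skipped: list[str] = []
    for edge in graph.rule_edges():
        rule = edge.rule
        assert rule is not None
        if rule.parameter not in values or values[rule.parameter] is None:
            if rule.parameter in MAP_FEATURES and map_indices is None:
                log.info("eye %s: no map indices, skipping rule %s", record.eye_id, rule.rule_id)
                skipped.append(rule.rule_id)
                continue
            raise KeyError(
                f"eye {record.eye_id}: rule {rule.rule_id!r} needs feature {rule.parameter!r} "
                "which is not resolvable from the record, derived features or map indices"
            )
        x = float(values[rule.parameter])
        entries.append(
            ActivationEntry(
                rule_id=rule.rule_id,
                feature=rule.parameter,
                observed=x,
                threshold=rule.threshold,
                direction=rule.direction,
                activation=rule_activation(rule, x),
                weight=edge.weight,
                target=edge.target,
                hard=rule.softness == 0.0,
            )
        )
    return EvidenceActivation(eye_id=record.eye_id, entries=tuple(entries), skipped=tuple(skipped))
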