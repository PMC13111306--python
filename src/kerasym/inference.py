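"""Bayesian rule-based inference and reasoning-trace assembly.

The diagnosis posterior uses a **noisy-OR** combiner: each rule-bearing edge
into the early-keratoconus node is an independent risk factor that, when its
evidence activation is ``a`` and its link probability (edge weight) is
``w``, fails to trigger the disease hypothesis with probability ``1 − w·a``.
With a leak term equal to the screening prior ``p0``,

    p_kc = 1 − (1 − p0) · ∏_i (1 − w_i · a_i).

This is the standard Bayesian-network idiom for independent causes; it is
monotone in every activation and weight, bounded below by the prior, and
each rule's contribution is the interpretable product ``w_i · a_i``.  The
normal-cornea hypothesis is scored as the complement ``1 − p_kc``.

An optional neural score from the map encoder is fused with the symbolic
posterior by a logit-linear pool; with fusion weight α = 0 (the out-of-box
mode) the pipeline is purely symbolic and needs no trained encoder.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Any, Mapping

from .biometry import BiometricRecord, DerivedFeatures
from .graph import ActivationEntry, EvidenceActivation, KnowledgeGraph

__all__ = [
    "InferenceConfig",
    "DiagnosisResult",
    "DecisionResult",
    "ReasoningTrace",
    "infer_posterior",
    "fuse_scores",
    "decide_eligibility",
    "build_trace",
    "KC_NODE",
    "CONTRA_NODE",
]

KC_NODE = "early_keratoconus"
CONTRA_NODE = "surgery_contraindicated"

_CLAMP = 1e-6  # probability clamp before logit transforms


@dataclass(frozen=True)
class InferenceConfig:
    """Tunable inference parameters.

    prior
        Leak probability of the noisy-OR (screening-population prior),
        default 0.05.  ``None`` defers to the graph's stored prior.
    fusion_alpha
        Weight of the neural score in the logit-linear pool, in [0, 1];
        0 = symbolic only (default).
    decision_threshold
        Posterior at or above which surgery is contraindicated (τ_d).
    """

    prior: float | None = None
    fusion_alpha: float = 0.0
    decision_threshold: float = 0.30

    def __post_init__(self) -> None:
        if self.prior is not None and not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must be in (0, 1), got {self.prior}")
        if not 0.0 <= self.fusion_alpha <= 1.0:
            raise ValueError(f"fusion_alpha must be in [0, 1], got {self.fusion_alpha}")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError(f"decision_threshold must be in (0, 1), got {self.decision_threshold}")


@dataclass(frozen=True)
class DiagnosisResult:
    eye_id: str
    p_kc: float
    p_source: str  # "symbolic" | "fused"
    prior: float
    contributions: tuple[tuple[str, float], ...]  # (rule_id, w*a) sorted desc

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_kc <= 1.0:
            raise ValueError(f"p_kc={self.p_kc} outside [0, 1]")


@dataclass(frozen=True)
class DecisionResult:
    eye_id: str
    eligibility: str  # "candidate" | "contraindicated"
    triggered_hard_rules: tuple[str, ...]
    threshold: float
    posterior: float


@dataclass(frozen=True)
class ReasoningTrace:
    """Ordered, machine-readable chain from measurements to decision.

    Stage order is fixed: measured parameters → rule evaluations →
    posterior computation → decision rationale.  All numbers are exact
    copies of the values used in inference (no re-rounding), so report
    renderers and audits see precisely what the combiner saw.
    """

    eye_id: str
    parameters: Mapping[str, float | None]
    rules: tuple[Mapping[str, Any], ...]
    posterior: Mapping[str, Any]
    decision: Mapping[str, Any]
    skipped_rules: tuple[str, ...] = ()
    version: str = "1"

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "eye_id": self.eye_id,
                "parameters": dict(self.parameters),
                "rules": [dict(r) for r in self.rules],
                "posterior": dict(self.posterior),
                "decision": dict(self.decision),
                "skipped_rules": list(self.skipped_rules),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReasoningTrace":
        obj = json.loads(text)
        return cls(
            eye_id=obj["eye_id"],
            parameters=obj["parameters"],
            rules=tuple(obj["rules"]),
            posterior=obj["posterior"],
            decision=obj["decision"],
            skipped_rules=tuple(obj["skipped_rules"]),
            version=obj["version"],
        )

    @property
    def p_kc(self) -> float:
        return self.posterior["p_kc"]


# ---------------------------------------------------------------------------
# operations


def infer_posterior(
    evidence: EvidenceActivation,
    graph: KnowledgeGraph,
    config: InferenceConfig | None = None,
) -> DiagnosisResult:
    """Noisy-OR posterior of early keratoconus from the activated evidence."""
    config = config or InferenceConfig()
    prior = config.prior if config.prior is not None else graph.priors[KC_NODE]
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must be in (0, 1), got {prior}")

    known_rules = {e.rule.rule_id for e in graph.rule_edges()}
    survival = 1.0 - prior
    contributions: list[tuple[str, float]] = []
    for entry in evidence.for_target(KC_NODE):
        if entry.rule_id not in known_rules:
            raise KeyError(f"activation references rule {entry.rule_id!r} absent from the graph")
        term = entry.weight * entry.activation
        contributions.append((entry.rule_id, term))
        survival *= 1.0 - term
    contributions.sort(key=lambda item: (-item[1], item[0]))
    return DiagnosisResult(
        eye_id=evidence.eye_id,
        p_kc=1.0 - survival,
        p_source="symbolic",
        prior=prior,
        contributions=tuple(contributions),
    )


def _logit(p: float) -> float:
    p = min(max(p, _CLAMP), 1.0 - _CLAMP)
    return math.log(p / (1.0 - p))


def fuse_scores(p_sym: float, p_neur: float, alpha: float) -> float:
    """Logit-linear pool: logit(p) = (1−α)·logit(p_sym) + α·logit(p_neur)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    z = (1.0 - alpha) * _logit(p_sym) + alpha * _logit(p_neur)
    return 1.0 / (1.0 + math.exp(-z))


def decide_eligibility(
    diagnosis: DiagnosisResult,
    evidence: EvidenceActivation,
    graph: KnowledgeGraph,
    config: InferenceConfig | None = None,
) -> DecisionResult:
    """Surgery eligibility: contraindicated on high posterior or a hard veto.

    A hard (softness = 0) parameter→decision rule that reached activation 1
    contraindicates regardless of the posterior — e.g. a cornea thinner
    than the absolute pachymetry floor is never a candidate.
    """
    config = config or InferenceConfig()
    hard_fired = tuple(
        e.rule_id for e in evidence.for_target(CONTRA_NODE) if e.hard and e.activation == 1.0
    )
    contraindicated = diagnosis.p_kc >= config.decision_threshold or bool(hard_fired)
    return DecisionResult(
        eye_id=diagnosis.eye_id,
        eligibility="contraindicated" if contraindicated else "candidate",
        triggered_hard_rules=hard_fired,
        threshold=config.decision_threshold,
        posterior=diagnosis.p_kc,
    )


def _entry_obj(entry: ActivationEntry) -> dict[str, Any]:
    return {
        "rule_id": entry.rule_id,
        "feature": entry.feature,
        "observed": entry.observed,
        "threshold": entry.threshold,
        "direction": entry.direction,
        "activation": entry.activation,
        "weight": entry.weight,
        "target": entry.target,
        "fired": entry.fired,
    }


def build_trace(
    record: BiometricRecord,
    features: DerivedFeatures,
    evidence: EvidenceActivation,
    diagnosis: DiagnosisResult,
    decision: DecisionResult,
) -> ReasoningTrace:
    """Assemble the four-stage reasoning trace for one eye.

    All five inputs must describe the same eye; the trace stores exact
    (unrounded) copies of every number used in inference.
    """
    ids = {record.eye_id, evidence.eye_id, diagnosis.eye_id, decision.eye_id}
    if len(ids) != 1:
        raise ValueError(f"stage mismatch: trace inputs describe different eyes {sorted(ids)}")
    parameters: dict[str, float | None] = {"laterality": record.laterality}
    parameters.update(record.as_dict())
    parameters.update(features.as_dict())
    return ReasoningTrace(
        eye_id=record.eye_id,
        parameters=parameters,
        rules=tuple(_entry_obj(e) for e in evidence.entries),
        posterior={
            "prior": diagnosis.prior,
            "terms": {rule_id: term for rule_id, term in diagnosis.contributions},
            "p_kc": diagnosis.p_kc,
            "p_normal": 1.0 - diagnosis.p_kc,
            "p_source": diagnosis.p_source,
        },
        decision={
            "eligibility": decision.eligibility,
            "threshold": decision.threshold,
            "triggered_hard_rules": list(decision.triggered_hard_rules),
        },
        skipped_rules=evidence.skipped,
    )
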