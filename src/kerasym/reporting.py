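"""Deterministic structured bilingual report generation.

Reports are pure functions of a reasoning trace, a template catalog, an
audience and a language.  Two audiences are supported:

* **physician** — every fired rule with its observed value, threshold and
  direction; the posterior probability to three decimals; the eligibility
  decision; caveats.  Section order is fixed: measurements → evidence →
  probability → decision → caveats.
* **patient** — lay wording only: the probability is mapped to bands
  (low < 0.1, moderate 0.1 up to the decision threshold, elevated at or
  above it, so the elevated band starts exactly at τ_d), no rule
  identifiers, no raw probabilities, and no jargon from a maintained
  blocklist.

Template catalogs are versioned data files (English and Simplified Chinese
ship with the package); any language can be added by dropping in a catalog
with the same keys.  An adapter hook lets callers plug in an external text
generator that receives the trace and the deterministic report as grounding
context; on any generator failure the deterministic report is returned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable

from .inference import ReasoningTrace

__all__ = [
    "SHIPPED_LANGUAGES",
    "PATIENT_JARGON_BLOCKLIST",
    "ClinicalReport",
    "load_catalog",
    "generate_physician_report",
    "generate_patient_summary",
    "adapter_hook",
]

log = logging.getLogger(__name__)

SHIPPED_LANGUAGES = ("en", "zh")

#: Band edges for patient wording; the upper edge follows the decision threshold.
LOW_BAND_UPPER = 0.1

#: Tokens that must never appear in a patient summary.
PATIENT_JARGON_BLOCKLIST = (
    "noisy-OR",
    "noisy-or",
    "posterior",
    "prior",
    "logit",
    "sigmoid",
    "activation",
    "Bayesian",
    "AUC",
    "keratometry",
)


@dataclass(frozen=True)
class ClinicalReport:
    audience: str  # "physician" | "patient"
    language: str
    sections: tuple[tuple[str, str], ...]  # (section name, rendered text), ordered
    appendix_trace_json: str

    def to_markdown(self) -> str:
        return "\n\n".join(text for _, text in self.sections)

    def to_json(self) -> str:
        return json.dumps(
            {
                "audience": self.audience,
                "language": self.language,
                "sections": [{"name": n, "text": t} for n, t in self.sections],
                "trace": json.loads(self.appendix_trace_json),
            },
            ensure_ascii=False,
            sort_keys=True,
        )

    @property
    def section_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.sections)


def load_catalog(lang: str) -> dict:
    """Load a shipped template catalog; unknown codes list the available ones."""
    from importlib.resources import files

    if lang not in SHIPPED_LANGUAGES:
        raise ValueError(f"unknown language {lang!r}; available: {', '.join(SHIPPED_LANGUAGES)}")
    return json.loads(
        files("kerasym.data").joinpath(f"templates/{lang}.json").read_text(encoding="utf-8")
    )


def _fmt(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}"


def generate_physician_report(trace: ReasoningTrace, lang: str = "en") -> ClinicalReport:
    """Render the physician report (deterministic; probabilities to 3 decimals)."""
    catalog = load_catalog(lang)
    t = catalog["physician"]
    labels = catalog["param_labels"]

    rows = []
    for name, value in trace.parameters.items():
        if name == "laterality" or value is None or name not in labels:
            continue
        label, units = labels[name]
        rows.append(t["measurement_row"].format(label=label, value=_fmt(value, 2), units=units))
    measurements = f"## {t['measurements_header']}\n" + "\n".join(rows)

    fired = [r for r in trace.rules if r["fired"]]
    if fired:
        lines = []
        for r in fired:
            label, units = labels.get(r["feature"], (r["feature"], ""))
            lines.append(
                t["evidence_row"].format(
                    rule_id=r["rule_id"],
                    label=label,
                    observed=_fmt(r["observed"], 2),
                    units=units,
                    direction=r["direction"],
                    threshold=_fmt(r["threshold"], 2),
                    activation=_fmt(r["activation"], 3),
                )
            )
        evidence_body = "\n".join(lines)
    else:
        evidence_body = t["evidence_none"]
    if trace.skipped_rules:
        evidence_body += "\n" + t["skipped_note"].format(rules=", ".join(trace.skipped_rules))
    evidence = f"## {t['evidence_header']}\n{evidence_body}"

    probability = f"## {t['probability_header']}\n" + t["probability"].format(
        p_kc=_fmt(trace.posterior["p_kc"], 3), prior=_fmt(trace.posterior["prior"], 3)
    )

    decision_info = trace.decision
    key = "decision_contraindicated" if decision_info["eligibility"] == "contraindicated" else "decision_candidate"
    decision_body = t[key].format(threshold=_fmt(decision_info["threshold"], 3))
    if decision_info["triggered_hard_rules"]:
        decision_body += "\n" + t["hard_rule_note"].format(rules=", ".join(decision_info["triggered_hard_rules"]))
    decision = f"## {t['decision_header']}\n{decision_body}"

    caveats = f"## {t['caveats_header']}\n{t['caveats']}"

    title = t["title"].format(eye_id=trace.eye_id, laterality=trace.parameters.get("laterality", ""))
    return ClinicalReport(
        audience="physician",
        language=lang,
        sections=(
            ("title", f"# {title}"),
            ("measurements", measurements),
            ("evidence", evidence),
            ("probability", probability),
            ("decision", decision),
            ("caveats", caveats),
        ),
        appendix_trace_json=trace.to_json(),
    )


def probability_band(p_kc: float, threshold: float) -> str:
    """Map a posterior to a lay band; 'elevated' starts exactly at τ_d."""
    if p_kc >= threshold:
        return "elevated"
    return "moderate" if p_kc >= LOW_BAND_UPPER else "low"


def generate_patient_summary(trace: ReasoningTrace, lang: str = "en") -> ClinicalReport:
    """Render the patient summary: banded wording, no jargon, no raw numbers."""
    catalog = load_catalog(lang)
    t = catalog["patient"]
    band = probability_band(trace.posterior["p_kc"], trace.decision["threshold"])
    advice_key = (
        "advice_contraindicated"
        if trace.decision["eligibility"] == "contraindicated"
        else "advice_candidate"
    )
    sections = (
        ("title", f"# {t['title']}"),
        ("summary", t["summary"].format(laterality=trace.parameters.get("laterality", ""))),
        ("risk", t[f"risk_{band}"]),
        ("advice", t[advice_key]),
        ("caveats", t["caveats"]),
    )
    report = ClinicalReport(
        audience="patient",
        language=lang,
        sections=sections,
        appendix_trace_json=trace.to_json(),
    )
    body = report.to_markdown()
    for token in PATIENT_JARGON_BLOCKLIST:
        if token in body:
            raise ValueError(f"patient template leaked jargon token {token!r}")
    return report


def adapter_hook(
    trace: ReasoningTrace,
    generator: Callable[[dict], str] | None = None,
    lang: str = "en",
) -> str:
    """Pass the trace and deterministic report to an external text generator.

    The generator receives ``{"trace": <trace dict>, "report": <markdown>}``
    as grounding context and returns free text.  With no generator (the
    default) or on any generator failure, the deterministic physician
    report is returned unchanged (failure is logged).
    """
    deterministic = generate_physician_report(trace, lang).to_markdown()
    if generator is None:
        return deterministic
    try:
        return generator({"trace": json.loads(trace.to_json()), "report": deterministic})
    except Exception:
        log.warning("text generator failed; falling back to deterministic report", exc_info=True)
        return deterministic
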