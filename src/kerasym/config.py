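"""Run configuration: one canonical YAML/JSON file plus seed derivation.

Config-first by design: no clinical threshold or weight lives in code —
graph rules come from the graph file (or overrides here), QC windows and
inference settings from this config.  Every random operation derives its
seed deterministically from the single global seed, so any artifact can be
reproduced from the logged config snapshot alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .biometry import QCConfig
from .inference import InferenceConfig

__all__ = ["RunConfig", "load_run_config", "derive_seed"]


def derive_seed(global_seed: int, tag: str) -> int:
    """Stable sub-seed (< 2^31) for a named source of randomness."""
    digest = hashlib.sha256(f"{global_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    graph_file: str | None = None  # None = shipped default graph
    graph_overrides: Mapping[str, Any] = field(default_factory=dict)
    qc: QCConfig = field(default_factory=QCConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    evaluation_k: int = 5
    log_level: str = "INFO"

    def snapshot(self) -> dict:
        return {
            "seed": self.seed,
            "graph_file": self.graph_file,
            "graph_overrides": dict(self.graph_overrides),
            "qc": asdict(self.qc),
            "inference": asdict(self.inference),
            "evaluation_k": self.evaluation_k,
            "log_level": self.log_level,
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run config; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    obj = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    obj = obj or {}
    known = {"seed", "graph_file", "graph_overrides", "qc", "inference", "evaluation_k", "log_level"}
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {k: v for k, v in obj.items() if k not in ("qc", "inference")}
    if "qc" in obj:
        qc = obj["qc"]
        kwargs["qc"] = QCConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in qc.items()})
    if "inference" in obj:
        kwargs["inference"] = InferenceConfig(**obj["inference"])
    return RunConfig(**kwargs)
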