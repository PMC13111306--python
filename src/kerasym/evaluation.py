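"""Metrics and the cross-validated screening benchmark.

Implements the evaluation battery for a binary screening task: stratified
k-fold plans, confusion-matrix metrics (sensitivity, specificity, accuracy,
F1), ROC/AUC with the Mann-Whitney tie convention and case-resampling
bootstrap confidence intervals, Cohen's κ for rater agreement, and the
end-to-end cross-validation experiment over a synthetic cohort directory.

Degenerate denominators (no positives, no negatives, chance agreement of 1)
yield NaN sentinels with an explicit warning — never a silent zero.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .biometry import aggregate_scans, derive_features, parse_records, validate_record
from .graph import KnowledgeGraph, activate_evidence
from .inference import InferenceConfig, fuse_scores, infer_posterior
from .maps import CurvatureMap, compute_map_indices

__all__ = [
    "FoldPlan",
    "MetricSet",
    "ROCCurve",
    "make_folds",
    "compute_confusion_metrics",
    "roc_auc",
    "cohens_kappa",
    "run_cv_experiment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: Mapping[str, int]  # eye_id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [eye for eye, f in self.assignments.items() if f == fold]


@dataclass(frozen=True)
class MetricSet:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ROCCurve:
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]  # descending; aligned with the interior points


def make_folds(
    eye_ids: Sequence[str],
    k: int,
    seed: int,
    labels: Sequence[str | int] | None = None,
) -> FoldPlan:
    """Seeded shuffle + round-robin fold assignment, stratified if labeled.

    Folds are disjoint, cover all eyes, and differ in size by at most one;
    with labels, each class is distributed round-robin so per-fold class
    counts differ by at most one as well.
    """
    n = len(eye_ids)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} eyes, got {n}")
    if len(set(eye_ids)) != n:
        raise ValueError("eye_ids must be unique")
    rng = np.random.default_rng(seed)
    if labels is None:
        order = list(rng.permutation(n))
    else:
        if len(labels) != n:
            raise ValueError("labels must align with eye_ids")
        order = []
        for cls in sorted(set(map(str, labels))):
            members = [i for i in range(n) if str(labels[i]) == cls]
            order.extend(rng.permutation(members).tolist())
    assignments = {eye_ids[idx]: pos % k for pos, idx in enumerate(order)}
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def compute_confusion_metrics(labels: Sequence[int], predictions: Sequence[int]) -> MetricSet:
    """Confusion counts and the derived screening metrics (no AUC).

    Undefined ratios (e.g. sensitivity with no positives) come back as NaN
    with a warning.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if not set(np.unique(y)) <= {0, 1} or not set(np.unique(p)) <= {0, 1}:
        raise ValueError("labels and predictions must be binary (0/1)")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); returning NaN", stacklevel=3)
            return math.nan
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = (tp + tn) / y.size
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "F1")
    return MetricSet(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec, accuracy=acc, f1=f1)


def _auc_rank(y: np.ndarray, s: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties ½."""
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)  # average ranks handle ties as half-credit
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(
    labels: Sequence[int],
    scores: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[ROCCurve, float, tuple[float, float]]:
    """ROC curve, rank-statistic AUC and percentile-bootstrap CI.

    The curve sweeps the unique scores as thresholds (predict positive at
    score >= threshold) and always includes (0,0) and (1,1).  The CI is the
    2.5/97.5 percentile over ``n_boot`` seeded case resamples of
    (label, score) pairs; resamples that lose one class are skipped.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")
    if n_boot < 0:
        raise ValueError("n_boot must be >= 0")

    auc = float(_auc_rank(y, s))

    thresholds = np.unique(s)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for th in thresholds:
        predicted = s >= th
        fpr.append(float(np.sum(predicted & (y == 0)) / n_neg))
        tpr.append(float(np.sum(predicted & (y == 1)) / n_pos))
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    curve = ROCCurve(fpr=tuple(fpr), tpr=tuple(tpr), thresholds=tuple(float(t) for t in thresholds))

    if n_boot == 0:
        ci = (math.nan, math.nan)
    else:
        rng = np.random.default_rng(seed)
        estimates = []
        for _ in range(n_boot):
            idx = rng.integers(0, y.size, size=y.size)
            yb = y[idx]
            if yb.sum() in (0, yb.size):
                continue
            estimates.append(_auc_rank(yb, s[idx]))
        ci = tuple(float(v) for v in np.percentile(estimates, [2.5, 97.5]))
    return curve, auc, ci


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's κ with marginal-product expected agreement.

    Returns NaN (with a warning) when expected agreement is 1, i.e. both
    raters are constant and identical, where κ is undefined.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("ratings must be non-empty and of equal length")
    categories = np.unique(np.concatenate([a, b]))
    p_obs = float(np.mean(a == b))
    p_exp = float(sum(np.mean(a == c) * np.mean(b == c) for c in categories))
    if p_exp >= 1.0:
        warnings.warn("kappa undefined: expected agreement is 1; returning NaN", stacklevel=2)
        return math.nan
    return (p_obs - p_exp) / (1.0 - p_exp)


# ---------------------------------------------------------------------------
# end-to-end cross-validated experiment


def _symbolic_scores(
    records,
    features,
    indices_by_eye: Mapping[str, object] | None,
    graph: KnowledgeGraph,
    cfg: InferenceConfig,
) -> np.ndarray:
    scores = []
    for record, feats in zip(records, features):
        idx = indices_by_eye.get(record.eye_id) if indices_by_eye else None
        evidence = activate_evidence(record, feats, idx, graph)
        scores.append(infer_posterior(evidence, graph, cfg).p_kc)
    return np.asarray(scores)


def run_cv_experiment(
    cohort_dir: str | Path,
    graph: KnowledgeGraph,
    inference_config: InferenceConfig | None = None,
    encoder_config=None,
    k: int = 5,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_boot: int = 1000,
) -> dict:
    """Cross-validated screening benchmark over a written cohort directory.

    Reads ``records.json``, ``labels.csv`` and ``maps/*.npy`` as produced by
    :func:`kerasym.cohort.write_cohort`.  Per fold, the encoder (if an
    :class:`~kerasym.encoder.EncoderConfig` is given) is trained on the
    training folds only and the held-out fold is scored by the fused — or,
    without an encoder, purely symbolic — pipeline.  The scoring path never
    sees held-out labels; an eye appearing on both sides of a fold is a hard
    error.  Pooled held-out scores give the primary ROC/AUC; per-fold and
    pooled confusion metrics are reported at the decision threshold τ_d and
    at the pooled Youden-optimal threshold.

    Returns the summary dict; when ``out_dir`` is given, also writes
    ``metrics.json``, ``roc_points.csv``, ``folds.json`` and
    ``config_snapshot.json`` there.
    """
    cohort_dir = Path(cohort_dir)
    inference_config = inference_config or InferenceConfig()

    scan_sets = parse_records(cohort_dir / "records.json")
    import csv as _csv

    with open(cohort_dir / "labels.csv", encoding="utf-8") as fh:
        label_by_eye = {row["eye_id"]: row["label"] for row in _csv.DictReader(fh)}
    records = [aggregate_scans(ss) for ss in scan_sets]
    for record in records:
        qc = validate_record(record)
        if qc.status != "pass":
            log.warning("eye %s fails QC (%s); keeping for benchmark scoring", record.eye_id, qc.reasons)
    features = {r.eye_id: derive_features(r) for r in records}

    maps_dir = cohort_dir / "maps"
    maps_by_eye: dict[str, CurvatureMap] = {}
    if maps_dir.is_dir():
        manifest = json.loads((cohort_dir / "manifest.json").read_text())
        px = manifest.get("map_pixel_size_mm") or 9.0 / 64
        for npy in sorted(maps_dir.glob("*.npy")):
            maps_by_eye[npy.stem] = CurvatureMap(values=np.load(npy), pixel_size_mm=px)
    indices_by_eye = {eye: compute_map_indices(m) for eye, m in maps_by_eye.items()}

    eye_ids = [r.eye_id for r in records]
    labels = [label_by_eye[eye] for eye in eye_ids]
    y = np.array([1 if lab == "early_kc" else 0 for lab in labels])
    plan = make_folds(eye_ids, k=k, seed=seed, labels=labels)

    record_by_eye = {r.eye_id: r for r in records}
    pooled_scores = np.empty(len(eye_ids))
    fold_rows = []
    for fold in range(k):
        test_ids = plan.fold_ids(fold)
        train_ids = [eye for eye in eye_ids if plan.assignments[eye] != fold]
        overlap = set(test_ids) & set(train_ids)
        if overlap:
            raise RuntimeError(f"leakage: eyes {sorted(overlap)} in both train and test of fold {fold}")

        test_records = [record_by_eye[eye] for eye in test_ids]
        test_feats = [features[eye] for eye in test_ids]
        scores = _symbolic_scores(test_records, test_feats, indices_by_eye, graph, inference_config)

        if encoder_config is not None:
            from .encoder import neural_scores, train_encoder

            train_maps = [maps_by_eye[eye] for eye in train_ids]
            train_labels = [label_by_eye[eye] for eye in train_ids]
            enc = train_encoder(train_maps, train_labels, graph, encoder_config)
            p_neur = neural_scores([maps_by_eye[eye] for eye in test_ids], enc)
            alpha = inference_config.fusion_alpha
            scores = np.array([fuse_scores(ps, pn, alpha) for ps, pn in zip(scores, p_neur)])

        test_pos = [eye_ids.index(eye) for eye in test_ids]
        pooled_scores[test_pos] = scores
        fold_y = y[test_pos]
        fold_pred = (scores >= inference_config.decision_threshold).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_metrics = compute_confusion_metrics(fold_y, fold_pred)
        fold_rows.append({"fold": fold, "n_test": len(test_ids), **fold_metrics.as_dict()})

    curve, auc, ci = roc_auc(y, pooled_scores, n_boot=n_boot, seed=seed)
    pred_at_tau = (pooled_scores >= inference_config.decision_threshold).astype(int)
    pooled_at_tau = compute_confusion_metrics(y, pred_at_tau)
    interior = np.asarray(curve.tpr[1:-1]) - np.asarray(curve.fpr[1:-1])
    if interior.size:
        youden_threshold = curve.thresholds[int(np.argmax(interior))]
    else:  # all scores identical: no informative threshold exists
        youden_threshold = inference_config.decision_threshold
    pooled_at_youden = compute_confusion_metrics(y, (pooled_scores >= youden_threshold).astype(int))

    summary = {
        "n_eyes": len(eye_ids),
        "k": k,
        "seed": seed,
        "mode": "fused" if encoder_config is not None else "symbolic",
        "pooled": {
            "auc": auc,
            "auc_ci": list(ci),
            "at_decision_threshold": pooled_at_tau.as_dict(),
            "decision_threshold": inference_config.decision_threshold,
            "at_youden_threshold": pooled_at_youden.as_dict(),
            "youden_threshold": youden_threshold,
        },
        "per_fold": fold_rows,
        "mean_over_folds": {
            name: float(np.nanmean([row[name] for row in fold_rows]))
            for name in ("sensitivity", "specificity", "accuracy", "f1")
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        with open(out / "roc_points.csv", "w", newline="") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["fpr", "tpr"])
            writer.writerows(zip(curve.fpr, curve.tpr))
        (out / "folds.json").write_text(json.dumps({"k": k, "seed": seed, "assignments": dict(plan.assignments)}, indent=1, sort_keys=True))
        snapshot = {
            "inference": asdict(inference_config),
            "encoder": None if encoder_config is None else asdict(encoder_config),
            "graph_version": graph.version,
            "seed": seed,
            "k": k,
        }
        (out / "config_snapshot.json").write_text(json.dumps(snapshot, indent=1, sort_keys=True))
    return summary
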