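"""Per-eye ocular biometry: record schema, scan aggregation, quality control.

An optical biometer (IOLMaster-class device) reports, per eye, flat and steep
keratometry (K1/K2, diopters), maximum keratometry (Kmax), central corneal
thickness (CCT, micrometers), axial length and anterior chamber depth
(millimeters).  A measurement session consists of a small number of repeat
scans (three by default); the per-parameter median over the scans is the
value handed to downstream reasoning, which suppresses single-scan outliers.

Corneal astigmatism is handled as a magnitude, ``K2 - K1``, with no axis.
Missing values are explicit (``None``) and are never imputed: records with a
missing parameter are excluded by quality control rather than repaired.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PARAMETERS",
    "Scan",
    "ScanSet",
    "BiometricRecord",
    "QCConfig",
    "QCResult",
    "DerivedFeatures",
    "SchemaError",
    "parse_records",
    "aggregate_scans",
    "validate_record",
    "derive_features",
]

#: Measured parameters carried by a single scan, in schema order.
PARAMETERS = ("k1_D", "k2_D", "kmax_D", "cct_um", "axial_length_mm", "acd_mm")

#: All parameters of an aggregated record (adds the derived astigmatism).
RECORD_PARAMETERS = PARAMETERS + ("astigmatism_D",)

KMAX_TOLERANCE_D = 0.5  # Kmax is a point maximum; allow it slightly below K2

LATERALITIES = ("OD", "OS")


class SchemaError(ValueError):
    """Raised when an input file does not conform to the record schema."""


@dataclass(frozen=True)
class Scan:
    """One raw acquisition of the six measured parameters (``None`` = missing)."""

    order: int
    k1_D: float | None = None
    k2_D: float | None = None
    kmax_D: float | None = None
    cct_um: float | None = None
    axial_length_mm: float | None = None
    acd_mm: float | None = None

    def __post_init__(self) -> None:
        for name in PARAMETERS:
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"scan {self.order}: {name}={value!r} must be strictly positive")


@dataclass(frozen=True)
class ScanSet:
    """All repeat scans of one eye from one examination session."""

    eye_id: str
    laterality: str
    scans: tuple[Scan, ...]
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}, got {self.laterality!r}")
        if len(self.scans) < 1:
            raise ValueError(f"eye {self.eye_id}: at least one scan required")
        orders = [s.order for s in self.scans]
        if len(set(orders)) != len(orders):
            raise SchemaError(f"eye {self.eye_id}: duplicate acquisition order in {orders}")


@dataclass(frozen=True)
class BiometricRecord:
    """Aggregated (per-parameter median) biometry of one eye.

    Invariants such as ``k2_D >= k1_D`` are checked by :func:`validate_record`,
    not at construction time, so that inconsistent device output can be
    represented and then excluded with an explicit reason.
    """

    eye_id: str
    laterality: str
    k1_D: float | None
    k2_D: float | None
    kmax_D: float | None
    cct_um: float | None
    axial_length_mm: float | None
    acd_mm: float | None
    astigmatism_D: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in RECORD_PARAMETERS}


@dataclass(frozen=True)
class QCConfig:
    """Plausibility windows for quality control (units as the field names).

    Defaults are generous physiologic ranges; every window is overridable so
    site-specific criteria can be swapped in without code changes.
    """

    k_window_D: tuple[float, float] = (35.0, 60.0)
    cct_window_um: tuple[float, float] = (350.0, 700.0)
    al_window_mm: tuple[float, float] = (19.0, 32.0)
    acd_window_mm: tuple[float, float] = (1.5, 5.0)


@dataclass(frozen=True)
class QCResult:
    status: str  # "pass" | "excluded"
    reasons: tuple[str, ...]
    details: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.status == "excluded") != bool(self.reasons):
            raise ValueError("status must be 'excluded' iff reasons are present")


@dataclass(frozen=True)
class DerivedFeatures:
    """Features derived from an aggregated record for rule evaluation."""

    mean_k_D: float
    astig_kdiff_D: float
    kmax_excess_D: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_k_D": self.mean_k_D,
            "astig_kdiff_D": self.astig_kdiff_D,
            "kmax_excess_D": self.kmax_excess_D,
        }


# ---------------------------------------------------------------------------
# parsing


def _coerce(value: Any, eye_id: str, fieldname: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"record {eye_id!r}: field {fieldname!r} is not numeric: {value!r}") from None


def _scanset_from_obj(obj: Mapping[str, Any]) -> ScanSet:
    try:
        eye_id = str(obj["eye_id"])
        laterality = str(obj["laterality"])
        raw_scans = obj["scans"]
    except KeyError as exc:
        raise SchemaError(f"record {obj.get('eye_id', '<unknown>')!r}: missing field {exc}") from None
    if not isinstance(raw_scans, Sequence) or not raw_scans:
        raise SchemaError(f"record {eye_id!r}: 'scans' must be a non-empty list")
    scans = []
    for raw in raw_scans:
        if "order" not in raw:
            raise SchemaError(f"record {eye_id!r}: scan missing field 'order'")
        scans.append(
            Scan(
                order=int(raw["order"]),
                **{name: _coerce(raw.get(name), eye_id, name) for name in PARAMETERS},
            )
        )
    metadata = {k: v for k, v in obj.items() if k not in ("eye_id", "laterality", "scans")}
    if laterality not in LATERALITIES:
        raise SchemaError(f"record {eye_id!r}: laterality must be one of {LATERALITIES}, got {laterality!r}")
    return ScanSet(eye_id=eye_id, laterality=laterality, scans=tuple(scans), metadata=metadata)


def parse_records(path: str | Path, format: str | None = None) -> list[ScanSet]:
    """Read per-eye scan sets from a JSON or CSV file.

    JSON: top-level list of ``{eye_id, laterality, scans: [{order, k1_D, ...}]}``;
    unknown top-level fields are kept as opaque metadata.  CSV: one row per
    scan with columns ``eye_id, laterality, order`` plus the six parameters,
    UTF-8, '.' decimal separator.  Empty cells are missing values.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(data, list):
            raise SchemaError(f"{path}: top level must be a list of records")
        return [_scanset_from_obj(obj) for obj in data]
    if format == "csv":
        frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
        required = {"eye_id", "laterality", "order"}
        missing_cols = required - set(frame.columns)
        if missing_cols:
            raise SchemaError(f"{path}: missing required columns {sorted(missing_cols)}")
        out: list[ScanSet] = []
        for (eye_id, laterality), group in frame.groupby(["eye_id", "laterality"], sort=False):
            orders = group["order"].tolist()
            if len(set(orders)) != len(orders):
                raise SchemaError(f"record {eye_id!r}: duplicate acquisition order in {orders}")
            scans = tuple(
                Scan(
                    order=int(row["order"]),
                    **{
                        name: _coerce(row.get(name), str(eye_id), name)
                        for name in PARAMETERS
                        if name in frame.columns
                    },
                )
                for _, row in group.iterrows()
            )
            out.append(ScanSet(eye_id=str(eye_id), laterality=str(laterality), scans=scans))
        return out
    raise ValueError(f"unknown format {format!r} (expected 'json' or 'csv')")


# ---------------------------------------------------------------------------
# aggregation and QC


def _median_present(values: Iterable[float | None]) -> float | None:
    present = [v for v in values if v is not None]
    return statistics.median(present) if present else None


def aggregate_scans(scan_set: ScanSet) -> BiometricRecord:
    """Collapse repeat scans to one record via per-parameter medians.

    Each parameter's median is taken independently over the scans where it is
    present; a parameter missing from every scan stays missing.  Astigmatism
    is the median of the per-scan ``K2 - K1`` differences (computed before
    aggregation so K1/K2 always come from the same acquisition).
    """
    values = {name: _median_present(getattr(s, name) for s in scan_set.scans) for name in PARAMETERS}
    astig = _median_present(
        (s.k2_D - s.k1_D) if (s.k1_D is not None and s.k2_D is not None) else None
        for s in scan_set.scans
    )
    return BiometricRecord(
        eye_id=scan_set.eye_id,
        laterality=scan_set.laterality,
        astigmatism_D=astig,
        **values,
    )


def validate_record(record: BiometricRecord, qc: QCConfig | None = None) -> QCResult:
    """Quality-control a record; always returns a result, never raises.

    Exclusion reasons: ``incomplete`` (any parameter missing),
    ``implausible_range`` (outside the configured windows) and
    ``inconsistent`` (K2 < K1, Kmax more than 0.5 D below K2, or negative
    astigmatism).
    """
    qc = qc or QCConfig()
    reasons: list[str] = []
    details: list[str] = []

    missing = [name for name in RECORD_PARAMETERS if getattr(record, name) is None]
    if missing:
        reasons.append("incomplete")
        details.append(f"missing parameters: {', '.join(missing)}")

    windows = {
        "k1_D": qc.k_window_D,
        "k2_D": qc.k_window_D,
        "kmax_D": qc.k_window_D,
        "cct_um": qc.cct_window_um,
        "axial_length_mm": qc.al_window_mm,
        "acd_mm": qc.acd_window_mm,
    }
    out_of_range = []
    for name, (lo, hi) in windows.items():
        value = getattr(record, name)
        if value is not None and not (lo <= value <= hi):
            out_of_range.append(f"{name}={value:g} outside [{lo:g}, {hi:g}]")
    if out_of_range:
        reasons.append("implausible_range")
        details.extend(out_of_range)

    inconsistent = []
    if record.k1_D is not None and record.k2_D is not None and record.k2_D < record.k1_D:
        inconsistent.append(f"k2_D={record.k2_D:g} < k1_D={record.k1_D:g}")
    if record.k2_D is not None and record.kmax_D is not None and record.kmax_D < record.k2_D - KMAX_TOLERANCE_D:
        inconsistent.append(f"kmax_D={record.kmax_D:g} < k2_D - {KMAX_TOLERANCE_D}")
    if record.astigmatism_D is not None and record.astigmatism_D < 0:
        inconsistent.append(f"astigmatism_D={record.astigmatism_D:g} < 0")
    if inconsistent:
        reasons.append("inconsistent")
        details.extend(inconsistent)

    status = "excluded" if reasons else "pass"
    return QCResult(status=status, reasons=tuple(reasons), details=tuple(details))


def derive_features(record: BiometricRecord) -> DerivedFeatures:
    """Compute mean keratometry, K2−K1 astigmatism and Kmax excess.

    ``kmax_excess_D = Kmax - (K1+K2)/2`` is the focal-steepening signal the
    diagnosis rules consume.  Raises on missing inputs: callers must QC first.
    """
    needed = ("k1_D", "k2_D", "kmax_D")
    missing = [name for name in needed if getattr(record, name) is None]
    if missing:
        raise ValueError(f"eye {record.eye_id}: cannot derive features, missing {', '.join(missing)}")
    mean_k = (record.k1_D + record.k2_D) / 2.0
    return DerivedFeatures(
        mean_k_D=mean_k,
        astig_kdiff_D=record.k2_D - record.k1_D,
        kmax_excess_D=record.kmax_D - mean_k,
    )
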