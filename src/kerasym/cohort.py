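"""Synthetic ocular-biometry cohorts, repeat-scan noise and rendered maps.

Two sampling modes:

``marginal``
    Each of the seven biometric parameters is drawn independently from an
    untruncated normal distribution calibrated to the published cohort
    summary statistics (mean/SD per parameter; the printed min/max are
    treated as observed extremes, not distribution bounds).  This mode
    exists to recover the cohort's marginal statistics without bias; because
    parameters are drawn independently, individual eyes may violate the
    clinical ordering K1 ≤ K2 ≤ Kmax and are not meant to pass the
    consistency QC check.

``labeled`` (default)
    A two-class benchmark cohort (normal vs. early keratoconus) with
    class-conditional effect sizes producing the canonical early-KC
    signature: focally steep Kmax, thinner cornea, larger astigmatism, and
    an inferior paracentral cone on the rendered axial map.  Every labeled
    eye satisfies the record invariants and passes default QC.

Repeat scans add independent zero-mean Gaussian device noise per parameter;
axial maps are rendered as mean keratometry + a with-the-rule bowtie
(regular astigmatism) + a Gaussian cone bump whose amplitude is set so the
map maximum matches the eye's Kmax.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .biometry import PARAMETERS, BiometricRecord, Scan, ScanSet, derive_features
from .maps import BACKGROUND_POWER_D, CurvatureMap, map_to_rgb

__all__ = [
    "TABLE1_STATS",
    "DEFAULT_SCAN_NOISE",
    "CohortSpec",
    "ConeDescriptor",
    "SyntheticEye",
    "sample_cohort",
    "simulate_repeat_scans",
    "render_curvature_map",
    "write_cohort",
]

#: Published cohort summary statistics (mean, SD) per parameter — the
#: calibration source for marginal mode.
TABLE1_STATS: dict[str, tuple[float, float]] = {
    "k1_D": (43.21, 1.18),
    "k2_D": (44.36, 1.42),
    "kmax_D": (46.02, 2.15),
    "cct_um": (532.6, 28.4),
    "axial_length_mm": (24.18, 1.12),
    "acd_mm": (3.21, 0.38),
    "astigmatism_D": (1.15, 0.72),
}

#: Default per-parameter repeat-scan noise SDs (device repeatability scale).
DEFAULT_SCAN_NOISE: dict[str, float] = {
    "k1_D": 0.10,
    "k2_D": 0.10,
    "kmax_D": 0.10,
    "cct_um": 3.0,
    "axial_length_mm": 0.02,
    "acd_mm": 0.03,
}

#: Bowtie (regular astigmatism) steep-axis default: 90° = with-the-rule.
DEFAULT_ASTIG_AXIS_DEG = 90.0


@dataclass(frozen=True)
class ConeDescriptor:
    """Latent focal-steepening bump: amplitude (D), polar center (mm, deg), width (mm)."""

    amplitude_D: float
    center_radius_mm: float
    center_angle_deg: float
    sigma_mm: float


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of one synthetic cohort draw.

    ``seed`` is mandatory: all sampling is reproducible from (spec, seed)
    with no hidden global randomness.
    """

    n_eyes: int
    seed: int
    mode: str = "labeled"  # "labeled" | "marginal"
    kc_fraction: float = 0.5
    scan_noise: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SCAN_NOISE))
    map_grid_px: int = 64
    map_extent_mm: float = 9.0

    def __post_init__(self) -> None:
        if self.n_eyes < 0:
            raise ValueError(f"n_eyes must be >= 0, got {self.n_eyes}")
        if not 0.0 <= self.kc_fraction <= 1.0:
            raise ValueError(f"kc_fraction must be in [0, 1], got {self.kc_fraction}")
        if self.mode not in ("labeled", "marginal"):
            raise ValueError(f"mode must be 'labeled' or 'marginal', got {self.mode!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class SyntheticEye:
    """Latent ground truth for one simulated eye."""

    eye_id: str
    label: str | None  # "normal" | "early_kc" | None (marginal mode)
    true_params: BiometricRecord
    cone: ConeDescriptor

    def __post_init__(self) -> None:
        if self.label == "early_kc" and not self.cone.amplitude_D > 0:
            raise ValueError("early_kc eyes must carry a positive cone amplitude")


# ---------------------------------------------------------------------------
# sampling


def _clip(value: float, lo: float, hi: float) -> float:
    return float(min(max(value, lo), hi))


def _marginal_eye(i: int, rng: np.random.Generator) -> SyntheticEye:
    draws = {name: float(rng.normal(mu, sd)) for name, (mu, sd) in TABLE1_STATS.items()}
    record = BiometricRecord(eye_id=f"eye{i:05d}", laterality=("OD", "OS")[i % 2], **draws)
    return SyntheticEye(
        eye_id=record.eye_id,
        label=None,
        true_params=record,
        cone=ConeDescriptor(0.0, 0.0, 0.0, 1.0),
    )


def _labeled_eye(i: int, label: str, rng: np.random.Generator) -> SyntheticEye:
    # class-conditional effect sizes: benchmark choices, not published values
    k1 = _clip(rng.normal(43.0, 1.0), 35.5, 59.0)
    if label == "early_kc":
        astig = abs(rng.normal(1.8, 0.8))
        excess = max(float(rng.normal(4.5, 1.5)), 2.5)
        cct = _clip(rng.normal(495.0, 25.0), 360.0, 690.0)
    else:
        astig = abs(rng.normal(0.9, 0.5))
        excess = abs(rng.normal(0.8, 0.4))
        cct = _clip(rng.normal(545.0, 25.0), 360.0, 690.0)
    # Kmax is a point maximum over the map, hence never below the steep
    # meridian power: floor the excess at astig/2 so kmax >= k2
    excess = max(excess, astig / 2.0)
    k2 = k1 + astig
    mean_k = (k1 + k2) / 2.0
    kmax = mean_k + excess
    al = _clip(rng.normal(*TABLE1_STATS["axial_length_mm"]), 19.5, 31.5)
    acd = _clip(rng.normal(*TABLE1_STATS["acd_mm"]), 1.6, 4.9)

    if label == "early_kc":
        center_r = float(rng.uniform(1.0, 2.0))
        center_a = float(rng.normal(270.0, 20.0)) % 360.0
        sigma = float(rng.uniform(0.8, 1.4))
        # amplitude such that the map maximum (cone apex on top of the bowtie)
        # approximately equals Kmax
        bowtie_at_center = (astig / 2.0) * np.cos(2.0 * np.radians(center_a - DEFAULT_ASTIG_AXIS_DEG))
        amplitude = max(excess - float(bowtie_at_center), 0.5)
        cone = ConeDescriptor(amplitude, center_r, center_a, sigma)
    else:
        cone = ConeDescriptor(0.0, 0.0, 0.0, 1.0)

    record = BiometricRecord(
        eye_id=f"eye{i:05d}",
        laterality=("OD", "OS")[i % 2],
        k1_D=k1,
        k2_D=k2,
        kmax_D=kmax,
        cct_um=cct,
        axial_length_mm=al,
        acd_mm=acd,
        astigmatism_D=astig,
    )
    return SyntheticEye(eye_id=record.eye_id, label=label, true_params=record, cone=cone)


def sample_cohort(spec: CohortSpec) -> list[SyntheticEye]:
    """Draw a cohort of synthetic eyes, reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "marginal":
        return [_marginal_eye(i, rng) for i in range(spec.n_eyes)]
    n_kc = int(round(spec.n_eyes * spec.kc_fraction))
    labels = np.array(["early_kc"] * n_kc + ["normal"] * (spec.n_eyes - n_kc))
    rng.shuffle(labels)
    return [_labeled_eye(i, str(label), rng) for i, label in enumerate(labels)]


def simulate_repeat_scans(
    eye: SyntheticEye,
    k: int = 3,
    noise: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> ScanSet:
    """Simulate ``k`` consecutive scans: truth + independent Gaussian noise.

    Noise SDs are per parameter (same units as the parameter); astigmatism
    is not perturbed directly — it re-emerges from the noisy K1/K2 when the
    scan set is aggregated.

    Each noisy scan is then relabeled the way the device defines its
    outputs: K1/K2 are the flat/steep meridians (sorted, never K2 < K1) and
    Kmax, being a map maximum, is floored at K2.  For a consistent eye this
    is the identity unless noise crosses the labels.
    """
    if k < 1:
        raise ValueError(f"scan count must be >= 1, got {k}")
    noise = dict(DEFAULT_SCAN_NOISE) if noise is None else dict(noise)
    for name, sd in noise.items():
        if sd < 0:
            raise ValueError(f"negative noise SD for {name}: {sd}")
    rng = np.random.default_rng(seed)
    scans = []
    for order in range(1, k + 1):
        values = {}
        for name in PARAMETERS:
            truth = getattr(eye.true_params, name)
            if truth is None:
                values[name] = None
            else:
                values[name] = float(truth + rng.normal(0.0, noise.get(name, 0.0)))
        if values["k1_D"] is not None and values["k2_D"] is not None:
            values["k1_D"], values["k2_D"] = sorted((values["k1_D"], values["k2_D"]))
            if values["kmax_D"] is not None:
                values["kmax_D"] = max(values["kmax_D"], values["k2_D"])
        scans.append(Scan(order=order, **values))
    return ScanSet(eye_id=eye.eye_id, laterality=eye.true_params.laterality, scans=tuple(scans))


# ---------------------------------------------------------------------------
# map rendering


def render_curvature_map(
    eye: SyntheticEye,
    grid_px: int = 64,
    extent_mm: float = 9.0,
    astig_axis_deg: float = DEFAULT_ASTIG_AXIS_DEG,
) -> CurvatureMap:
    """Render the eye's axial power map on a square mm grid.

    Inside the corneal disc (radius = extent/2) the power is

        K(x, y) = mean_k + (astig/2)·cos(2(θ − axis)) + A·exp(−d²/(2σ²))

    where θ is the polar angle, axis the steep meridian of the bowtie, and
    d the distance to the cone center.  Outside-disc pixels carry the
    defined background value.
    """
    if grid_px <= 0 or extent_mm <= 0:
        raise ValueError("grid size and extent must be positive")
    feats = derive_features(eye.true_params)
    px = extent_mm / grid_px
    template = CurvatureMap(values=np.zeros((grid_px, grid_px)), pixel_size_mm=px)
    x, y = template.coords_mm()
    radius, angle = template.polar_mm()

    power = feats.mean_k_D + (feats.astig_kdiff_D / 2.0) * np.cos(
        2.0 * np.radians(angle - astig_axis_deg)
    )
    cone = eye.cone
    if cone.amplitude_D > 0:
        cx = cone.center_radius_mm * np.cos(np.radians(cone.center_angle_deg))
        cy = cone.center_radius_mm * np.sin(np.radians(cone.center_angle_deg))
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        power = power + cone.amplitude_D * np.exp(-d2 / (2.0 * cone.sigma_mm**2))

    disc = radius <= extent_mm / 2.0
    values = np.where(disc, power, BACKGROUND_POWER_D)
    return CurvatureMap(values=values, pixel_size_mm=px)


# ---------------------------------------------------------------------------
# cohort writer


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(
    eyes: Sequence[SyntheticEye],
    scan_sets: Sequence[ScanSet],
    maps: Sequence[CurvatureMap] | None,
    out_dir: str | Path,
    write_png: bool = False,
) -> dict:
    """Write a cohort to disk in the documented record schema.

    Produces ``records.json`` and ``records.csv`` (scan-level schema),
    ``labels.csv`` (kept separate so the inference path never sees labels),
    per-eye ``maps/*.npy`` arrays (optionally color PNGs), and a
    ``manifest.json`` listing every artifact with its SHA-256 checksum.
    Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if maps is not None and len(maps) != len(eyes):
        raise ValueError("one map per eye required when maps are given")
    if len(scan_sets) != len(eyes):
        raise ValueError("one scan set per eye required")

    records_obj = [
        {
            "eye_id": ss.eye_id,
            "laterality": ss.laterality,
            "scans": [
                {"order": s.order, **{name: getattr(s, name) for name in PARAMETERS}}
                for s in ss.scans
            ],
        }
        for ss in scan_sets
    ]
    (out / "records.json").write_text(json.dumps(records_obj, indent=1, sort_keys=True), encoding="utf-8")

    with open(out / "records.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["eye_id", "laterality", "order", *PARAMETERS])
        for ss in scan_sets:
            for s in ss.scans:
                writer.writerow([ss.eye_id, ss.laterality, s.order, *(getattr(s, name) for name in PARAMETERS)])

    with open(out / "labels.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["eye_id", "label"])
        for eye in eyes:
            writer.writerow([eye.eye_id, eye.label if eye.label is not None else ""])

    files = ["records.json", "records.csv", "labels.csv"]
    if maps is not None:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for eye, cmap in zip(eyes, maps):
            np.save(maps_dir / f"{eye.eye_id}.npy", cmap.values)
            files.append(f"maps/{eye.eye_id}.npy")
            if write_png:
                from PIL import Image

                Image.fromarray(map_to_rgb(cmap)).save(maps_dir / f"{eye.eye_id}.png")
                files.append(f"maps/{eye.eye_id}.png")

    manifest = {
        "n_eyes": len(eyes),
        "map_pixel_size_mm": maps[0].pixel_size_mm if maps else None,
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
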