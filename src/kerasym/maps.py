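"""Axial curvature maps and deterministic morphology indices.

A :class:`CurvatureMap` is a square grid of axial corneal power (diopters)
centered on the corneal apex.  Coordinate convention: pixel (0, 0) is the
top-left corner; the +x axis points right (temporal for a right eye) and the
+y axis points up (superior), i.e. increasing row index is inferior.  Angles
are measured counter-clockwise from +x, so 90° is superior and 270° inferior.

The inferior-minus-superior (I-S) asymmetry index is the classical
keratoconus screening statistic: mean power over an inferior mid-peripheral
annulus minus the superior counterpart.  Regular with-the-rule astigmatism
(a vertical bowtie) cancels out of I-S by mirror symmetry; an inferior cone
does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CurvatureMap",
    "MapIndices",
    "compute_map_indices",
    "BACKGROUND_POWER_D",
    "COLOR_SCALE_D",
    "map_to_rgb",
    "rgb_png_to_map",
]

#: Power value written outside the corneal disc.
BACKGROUND_POWER_D = 0.0

#: Fixed color scale (diopters) used for PNG export/import.
COLOR_SCALE_D = (38.0, 52.0)

#: Annulus (mm) over which the I-S asymmetry is evaluated.
IS_ANNULUS_MM = (2.0, 3.0)


@dataclass(frozen=True)
class CurvatureMap:
    """Square grid of axial power in diopters with physical pixel size."""

    values: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"map grid must be square, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("map contains non-finite values")
        if not self.pixel_size_mm > 0:
            raise ValueError(f"pixel_size_mm must be positive, got {self.pixel_size_mm}")
        object.__setattr__(self, "values", values)

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @property
    def extent_mm(self) -> float:
        """Physical edge length of the grid."""
        return self.size * self.pixel_size_mm

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center (x, y) coordinates in mm, apex at the grid midpoint."""
        n = self.size
        offsets = (np.arange(n) - (n - 1) / 2.0) * self.pixel_size_mm
        x = np.broadcast_to(offsets[None, :], (n, n))
        y = np.broadcast_to(-offsets[:, None], (n, n))  # row 0 is superior
        return x, y

    def polar_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Radius (mm) and angle (deg in [0, 360)) of every pixel center."""
        x, y = self.coords_mm()
        radius = np.hypot(x, y)
        angle = np.degrees(np.arctan2(y, x)) % 360.0
        return radius, angle

    def disc_mask(self) -> np.ndarray:
        radius, _ = self.polar_mm()
        return radius <= self.extent_mm / 2.0


@dataclass(frozen=True)
class MapIndices:
    """Morphology indices of one curvature map."""

    is_asymmetry_D: float
    max_power_D: float
    max_location: tuple[float, float]  # (radius_mm, angle_deg)

    def as_dict(self) -> dict[str, float]:
        return {
            "is_asymmetry_D": self.is_asymmetry_D,
            "max_power_D": self.max_power_D,
            "max_radius_mm": self.max_location[0],
            "max_angle_deg": self.max_location[1],
        }


def compute_map_indices(cmap: CurvatureMap) -> MapIndices:
    """I-S asymmetry over the 2–3 mm annulus and the disc power maximum.

    The inferior half-disc is angle ∈ (180°, 360°), superior ∈ (0°, 180°);
    pixels exactly on the horizontal meridian belong to neither.  Requires a
    mapped diameter of at least 6 mm so the annulus is fully covered.
    """
    if cmap.extent_mm < 2 * IS_ANNULUS_MM[1]:
        raise ValueError(
            f"map extent {cmap.extent_mm:g} mm < {2 * IS_ANNULUS_MM[1]:g} mm required for I-S annulus"
        )
    radius, angle = cmap.polar_mm()
    annulus = (radius >= IS_ANNULUS_MM[0]) & (radius <= IS_ANNULUS_MM[1])
    inferior = annulus & (angle > 180.0) & (angle < 360.0)
    superior = annulus & (angle > 0.0) & (angle < 180.0)
    if not inferior.any() or not superior.any():
        raise ValueError("annulus not resolved by the grid")
    is_asym = float(cmap.values[inferior].mean() - cmap.values[superior].mean())

    disc = cmap.disc_mask()
    disc_values = np.where(disc, cmap.values, -np.inf)
    flat_idx = int(np.argmax(disc_values))
    row, col = np.unravel_index(flat_idx, cmap.values.shape)
    return MapIndices(
        is_asymmetry_D=is_asym,
        max_power_D=float(cmap.values[row, col]),
        max_location=(float(radius[row, col]), float(angle[row, col])),
    )


# ---------------------------------------------------------------------------
# color-mapped PNG round-trip (fixed 38–52 D scale)

# compact blue->green->yellow->red clinical-style ramp; grayscale channel is
# the value channel so PNGs decode back to powers via the fixed scale.
_RAMP = np.array(
    [
        (0.10, 0.15, 0.60),
        (0.05, 0.55, 0.85),
        (0.10, 0.75, 0.35),
        (0.90, 0.85, 0.15),
        (0.85, 0.25, 0.10),
    ]
)


def map_to_rgb(cmap: CurvatureMap) -> np.ndarray:
    """Render a map as uint8 RGB using the fixed 38–52 D color scale."""
    lo, hi = COLOR_SCALE_D
    t = np.clip((cmap.values - lo) / (hi - lo), 0.0, 1.0)
    pos = t * (len(_RAMP) - 1)
    idx = np.clip(pos.astype(int), 0, len(_RAMP) - 2)
    frac = pos - idx
    rgb = _RAMP[idx] * (1 - frac[..., None]) + _RAMP[idx + 1] * frac[..., None]
    return (rgb * 255.0 + 0.5).astype(np.uint8)


def _ramp_lut(steps: int = 256) -> np.ndarray:
    t = np.linspace(0.0, 1.0, steps)
    pos = t * (len(_RAMP) - 1)
    idx = np.clip(pos.astype(int), 0, len(_RAMP) - 2)
    frac = (pos - idx)[:, None]
    return _RAMP[idx] * (1 - frac) + _RAMP[idx + 1] * frac


def rgb_png_to_map(path, pixel_size_mm: float) -> CurvatureMap:
    """Decode a color-mapped PNG back to powers on the fixed 38–52 D scale.

    Inverts the fixed color ramp by nearest-color lookup, so the import is
    quantized to the ramp resolution (and clipped to the scale); it is meant
    for feeding archived report images to the encoder, not for recovering
    exact powers.
    """
    from PIL import Image

    lo, hi = COLOR_SCALE_D
    rgb = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
    lut = _ramp_lut()
    # nearest ramp entry per pixel: (H, W, steps) distance tensor is fine at 64x64
    d2 = ((rgb[..., None, :] - lut[None, None, :, :]) ** 2).sum(-1)
    t = np.argmin(d2, axis=-1) / (lut.shape[0] - 1)
    return CurvatureMap(values=lo + t * (hi - lo), pixel_size_mm=pixel_size_mm)
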