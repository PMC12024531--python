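"""Probe-centered rotational augmentation.

EUS frames are rotationally symmetric about the ultrasound probe, so the
augmentation rotates each raw frame about the probe center in fixed angular
increments (22.5 degrees by default, giving 15 extra variants) and then trims
a square crop (360 px by default) centered on the probe — rotation happens
before trimming so crops never contain blank corners.  The identity crop is a
pure sub-array (no resampling); rotated crops are sampled directly on the
source grid, which is equivalent to rotating the full canvas and then
cropping.

Angle convention: the sampling position for an output offset (dr, dc) from
the probe center is ``center + (cos a * dr - sin a * dc, sin a * dr + cos a *
dc)``; with a pixel-aligned center, a 90-degree rotation therefore equals
``np.rot90(crop, k=-1)`` of the identity crop.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigError, MarginError

__all__ = [
    "ProbeFrame",
    "AugmentConfig",
    "NormalizationStats",
    "rotation_angles",
    "crop_centered",
    "augment_image",
    "compute_normalization",
]

RAW_MIN_SHAPE = (500, 400)  # clinical-style raw frames are at least this large


@dataclass
class ProbeFrame:
    """A grayscale frame with the probe-center coordinate and metadata."""

    pixels: np.ndarray  # 2-D float array, values in [0, 1]
    probe_center: tuple[float, float]  # (row, col)
    source_id: str = ""
    patient_id: str = ""
    label: str = ""  # "GIST" or "leiomyoma"
    lesion_size_mm: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ConfigError("ProbeFrame.pixels must be a 2-D grayscale array")
        r, c = self.probe_center
        h, w = self.pixels.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ConfigError(f"probe_center {self.probe_center} outside {h}x{w} frame")


@dataclass(frozen=True)
class AugmentConfig:
    angle_step_deg: float = 22.5
    crop_side: int = 360
    interpolation: str = "bilinear"  # or "nearest"
    margin_policy: str = "strict_error"  # or "reflect_pad_warn"

    def __post_init__(self):
        if self.crop_side <= 0:
            raise ConfigError("crop_side must be positive")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ConfigError(f"unknown interpolation {self.interpolation!r}")
        if self.margin_policy not in ("strict_error", "reflect_pad_warn"):
            raise ConfigError(f"unknown margin_policy {self.margin_policy!r}")
        rotation_angles(self.angle_step_deg)  # validates divisibility


@dataclass(frozen=True)
class NormalizationStats:
    """Population mean/std of all pixels of a set, flattened together."""

    mean: float
    std: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * self.std + self.mean


def rotation_angles(angle_step_deg: float) -> list[float]:
    """Non-identity rotation angles k*step for k = 1 .. 360/step - 1."""
    if not 0 < angle_step_deg <= 360:
        raise ConfigError(f"angle step must be in (0, 360], got {angle_step_deg}")
    n = 360.0 / angle_step_deg
    if abs(n - round(n)) > 1e-9:
        raise ConfigError(f"angle step {angle_step_deg} does not divide 360")
    return [k * angle_step_deg for k in range(1, int(round(n)))]


def _crop_box(frame: ProbeFrame, crop_side: int) -> tuple[int, int]:
    """Top-left (row, col) of the crop box anchored at the rounded center."""
    r, c = frame.probe_center
    return int(round(r)) - crop_side // 2, int(round(c)) - crop_side // 2


def crop_centered(frame: ProbeFrame, crop_side: int) -> np.ndarray:
    """Exact sub-array of side ``crop_side`` centered on the probe (no
    resampling; the box is anchored at the rounded center)."""
    h, w = frame.pixels.shape
    r0, c0 = _crop_box(frame, crop_side)
    for edge, bad in (("top", r0 < 0), ("left", c0 < 0),
                      ("bottom", r0 + crop_side > h), ("right", c0 + crop_side > w)):
        if bad:
            raise MarginError(
                f"{crop_side}-px crop centered at {frame.probe_center} exceeds the "
                f"{edge} edge of the {h}x{w} frame"
            )
    return frame.pixels[r0 : r0 + crop_side, c0 : c0 + crop_side]


def _corner_positions(frame: ProbeFrame, crop_side: int, angle_deg: float) -> np.ndarray:
    """Raw-frame positions of the four crop-box corners after rotation."""
    r0, c0 = _crop_box(frame, crop_side)
    cr, cc = frame.probe_center
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    corners = np.array(
        [
            [r0 - cr, c0 - cc],
            [r0 - cr, c0 + crop_side - 1 - cc],
            [r0 + crop_side - 1 - cr, c0 - cc],
            [r0 + crop_side - 1 - cr, c0 + crop_side - 1 - cc],
        ]
    )
    return corners @ rot.T + np.array([cr, cc])


def _check_margins(frame: ProbeFrame, crop_side: int, angle_deg: float) -> bool:
    h, w = frame.pixels.shape
    pos = _corner_positions(frame, crop_side, angle_deg)
    return bool(
        (pos[:, 0] >= 0).all()
        and (pos[:, 0] <= h - 1).all()
        and (pos[:, 1] >= 0).all()
        and (pos[:, 1] <= w - 1).all()
    )


def _rotated_crop(frame: ProbeFrame, crop_side: int, angle_deg: float,
                  order: int, mode: str) -> np.ndarray:
    """Sample the rotated crop window directly on the raw grid."""
    r0, c0 = _crop_box(frame, crop_side)
    cr, cc = frame.probe_center
    a = np.deg2rad(angle_deg)
    rows = np.arange(r0, r0 + crop_side, dtype=float) - cr
    cols = np.arange(c0, c0 + crop_side, dtype=float) - cc
    dr, dc = np.meshgrid(rows, cols, indexing="ij")
    src_r = cr + np.cos(a) * dr - np.sin(a) * dc
    src_c = cc + np.sin(a) * dr + np.cos(a) * dc
    out = ndimage.map_coordinates(
        frame.pixels.astype(np.float64), [src_r, src_c], order=order, mode=mode
    )
    return np.clip(out, 0.0, 1.0).astype(frame.pixels.dtype, copy=False)


def augment_image(frame: ProbeFrame, config: AugmentConfig) -> list[np.ndarray]:
    """The identity crop plus one rotated crop per non-identity angle
    (360/step crops in total, 16 at the default 22.5-degree step)."""
    order = 1 if config.interpolation == "bilinear" else 0
    crops = [crop_centered(frame, config.crop_side)]
    for angle in rotation_angles(config.angle_step_deg):
        if not _check_margins(frame, config.crop_side, angle):
            if config.margin_policy == "strict_error":
                raise MarginError(
                    f"rotation by {angle} deg about {frame.probe_center} swings the "
                    f"{config.crop_side}-px crop box outside the "
                    f"{frame.pixels.shape[0]}x{frame.pixels.shape[1]} frame"
                )
            warnings.warn(
                f"frame {frame.source_id or '<unnamed>'}: crop corners leave the frame "
                f"at {angle} deg; filling by reflection",
                stacklevel=2,
            )
            crops.append(_rotated_crop(frame, config.crop_side, angle, order, "reflect"))
        else:
            crops.append(_rotated_crop(frame, config.crop_side, angle, order, "constant"))
    return crops


def compute_normalization(images: Iterable[np.ndarray] | Sequence[np.ndarray]) -> NormalizationStats:
    """Population mean and standard deviation over all pixels of all images,
    treated as one flattened array (streamed, so the set can be large)."""
    n = 0
    s = 0.0
    s2 = 0.0
    for img in images:
        a = np.asarray(img, dtype=np.float64)
        n += a.size
        s += float(a.sum())
        s2 += float((a * a).sum())
    if n == 0:
        raise ConfigError("cannot compute normalization statistics of an empty set")
    mean = s / n
    var = max(s2 / n - mean * mean, 0.0)
    return NormalizationStats(mean=mean, std=float(np.sqrt(var)))
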