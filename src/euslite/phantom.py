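"""Synthetic EUS phantom generator.

The clinical image data behind this toolkit are private, so every downstream
stage (augmentation, training, evaluation, saliency) is exercised on a
synthetic phantom that reproduces the qualitative structure of an EUS frame:

* a central circular probe (dark disc with a bright rim),
* concentric echogenic wall layers around it,
* a hypoechoic elliptical lesion embedded in the wall, and
* fully developed multiplicative speckle (unit-mean gamma field).

The two classes differ the way they do on real EUS: leiomyoma-like lesions
are homogeneous with sharp, regular margins; GIST-like lesions carry internal
texture heterogeneity and irregular margins.  Mean lesion brightness is the
same for both classes, so a classifier has to pick up texture/margin
structure rather than a trivial intensity offset.  No claim of physical
ultrasound realism is made.

Cohort generation assigns each synthetic patient one class and one lesion
size drawn from a truncated normal matching the study population
(9.3 +/- 5.7 mm for the development cohort; a test preset uses
18.7 +/- 10.7 mm), with several frames per patient at varied lesion
orientation and offset.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .augment import ProbeFrame
from .errors import ConfigError, GeometryError

__all__ = [
    "PhantomSpec",
    "PhantomRecord",
    "CohortConfig",
    "PhantomDataset",
    "render_envelope",
    "render_frame",
    "apply_speckle",
    "generate_cohort",
]

GIST = "GIST"
LEIOMYOMA = "leiomyoma"

DEFAULT_WALL_LAYERS = (
    (6.0, 0.35),
    (9.0, 0.75),
    (13.0, 0.45),
    (18.0, 0.60),
    (26.0, 0.30),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom frame.

    ``class_label`` is ``"GIST_like"`` or ``"leiomyoma_like"``; the class
    defaults (set by :meth:`for_class`) encode the qualitative EUS contrast:
    leiomyoma-like lesions have ``margin_irregularity = 0`` and
    ``internal_heterogeneity = 0``, GIST-like lesions have both positive.
    """

    image_height: int = 520
    image_width: int = 440
    px_per_mm: float = 10.0
    probe_radius_mm: float = 3.0
    wall_layers: tuple[tuple[float, float], ...] = DEFAULT_WALL_LAYERS
    lesion_center_offset_mm: tuple[float, float] = (0.0, 11.0)
    lesion_diameter_mm: float = 9.3
    lesion_axis_ratio: float = 0.8
    lesion_angle_deg: float = 0.0
    class_label: str = "GIST_like"
    margin_irregularity: float = 0.35
    internal_heterogeneity: float = 1.0
    speckle_looks: float = 25.0
    psf_sigma_px: float = 1.0
    seed: int = 0

    @classmethod
    def for_class(cls, label: str, **overrides) -> "PhantomSpec":
        if label in ("GIST_like", GIST):
            base = cls(class_label="GIST_like", margin_irregularity=0.35,
                       internal_heterogeneity=1.0)
        elif label in ("leiomyoma_like", LEIOMYOMA):
            base = cls(class_label="leiomyoma_like", margin_irregularity=0.0,
                       internal_heterogeneity=0.0)
        else:
            raise ConfigError(f"unknown class label {label!r}")
        return replace(base, **overrides)

    @property
    def manifest_label(self) -> str:
        return GIST if self.class_label == "GIST_like" else LEIOMYOMA


@dataclass
class PhantomRecord:
    frame: ProbeFrame
    lesion_mask: np.ndarray
    spec: PhantomSpec


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level sampling parameters (development-cohort defaults)."""

    n_patients: int = 50
    images_per_patient: tuple[int, int] = (4, 4)  # inclusive range
    class_balance: float = 0.5  # fraction of GIST-like patients
    size_mean_mm: float = 9.3
    size_sd_mm: float = 5.7
    size_truncation_mm: tuple[float, float] = (4.0, 35.0)
    image_height: int = 128
    image_width: int = 128
    px_per_mm: float = 3.5
    probe_radius_mm: float = 3.0
    speckle_looks: float = 25.0
    gist_heterogeneity: float = 1.0
    gist_margin_irregularity: float = 0.35
    leiomyoma_heterogeneity: float = 0.0
    leiomyoma_margin_irregularity: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigError("need at least 2 patients")
        lo, hi = self.size_truncation_mm
        if not (0 < lo < hi) or not (lo < self.size_mean_mm < hi):
            raise ConfigError(f"infeasible size truncation range {self.size_truncation_mm}")
        if not 0 <= self.class_balance <= 1:
            raise ConfigError("class_balance must be in [0, 1]")

    @classmethod
    def test_cohort(cls, **overrides) -> "CohortConfig":
        """Preset mirroring the held-out cohort's larger lesions
        (18.7 +/- 10.7 mm)."""
        base = cls(size_mean_mm=18.7, size_sd_mm=10.7, size_truncation_mm=(3.0, 50.0))
        return replace(base, **overrides)


def _sample_lesion_sizes(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    """Truncated-normal lesion sizes whose *truncated* mean equals the
    configured mean (the location parameter is solved for, since truncating
    at a positive lower bound would otherwise inflate the mean)."""
    from scipy import optimize

    lo, hi = config.size_truncation_mm
    sd = config.size_sd_mm
    target = config.size_mean_mm

    def mean_at(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    loc = optimize.brentq(lambda l: mean_at(l) - target, lo - 6 * sd, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd,
                               size=config.n_patients, random_state=rng)


def _smooth_periodic_noise(rng: np.random.Generator, theta: np.ndarray,
                           n_harmonics: int = 5) -> np.ndarray:
    """Zero-mean smooth periodic profile with roughly unit amplitude."""
    out = np.zeros_like(theta)
    for h in range(2, 2 + n_harmonics):
        amp = rng.normal(0.0, 1.0 / h)
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.cos(h * theta + phase)
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def render_envelope(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free echogenicity map and lesion mask.

    Deterministic given the spec: the seed drives only the lesion texture and
    margin-perturbation fields.
    """
    h, w = spec.image_height, spec.image_width
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    r_px = np.hypot(rows - cr, cols - cc)
    r_mm = r_px / spec.px_per_mm

    img = np.full((h, w), 0.08)
    prev = spec.probe_radius_mm
    for outer, echo in spec.wall_layers:
        img[(r_mm >= prev) & (r_mm < outer)] = echo
        prev = outer
    # probe: dark transducer disc with a bright rim
    img[r_mm < spec.probe_radius_mm] = 0.06
    rim = (r_mm >= spec.probe_radius_mm) & (r_mm < spec.probe_radius_mm + 0.8)
    img[rim] = 0.95

    mask = np.zeros((h, w), dtype=bool)
    if spec.lesion_diameter_mm > 0:
        rng = np.random.default_rng(spec.seed)
        dr_mm, dc_mm = spec.lesion_center_offset_mm
        lr = cr + dr_mm * spec.px_per_mm
        lc = cc + dc_mm * spec.px_per_mm
        a_px = (spec.lesion_diameter_mm / 2.0) * spec.px_per_mm  # semi-major
        b_px = a_px * spec.lesion_axis_ratio
        if a_px < 1.0:
            raise GeometryError(
                f"lesion of {spec.lesion_diameter_mm} mm is below one pixel at "
                f"{spec.px_per_mm} px/mm"
            )
        if not (0 <= lr < h and 0 <= lc < w):
            raise GeometryError(
                f"lesion center ({lr:.1f}, {lc:.1f}) px falls outside the {h}x{w} frame"
            )
        ang = np.deg2rad(spec.lesion_angle_deg)
        u = (rows - lr) * np.cos(ang) + (cols - lc) * np.sin(ang)
        v = -(rows - lr) * np.sin(ang) + (cols - lc) * np.cos(ang)
        rho = np.hypot(u / a_px, v / b_px)  # 1.0 on the unperturbed boundary
        if spec.margin_irregularity > 0:
            theta = np.arctan2(v, u)
            boundary = 1.0 + spec.margin_irregularity * _smooth_periodic_noise(rng, theta)
        else:
            boundary = 1.0
        mask = rho <= boundary
        lesion = np.full((h, w), 0.22)
        if spec.internal_heterogeneity > 0:
            # texture correlation length scales with the lesion so small
            # lesions still contain a few texture cells
            tex_sigma = float(np.clip(a_px / 5.0, 1.2, 4.0))
            tex = rng.normal(0.0, 1.0, (h, w))
            tex = ndimage.gaussian_filter(tex, sigma=tex_sigma)
            tex /= max(tex.std(), 1e-9)
            lesion = lesion + spec.internal_heterogeneity * 0.3 * tex
        img[mask] = np.clip(lesion, 0.02, 0.98)[mask]
        # keep the probe visible even for large central lesions
        img[r_mm < spec.probe_radius_mm] = 0.06
        img[rim] = 0.95
        mask &= ~(r_mm < spec.probe_radius_mm + 0.8)

    return np.clip(img, 0.0, 1.0), mask


def apply_speckle(image: np.ndarray, looks: float, seed: int) -> np.ndarray:
    """Fully developed multiplicative speckle: pixel-wise product with a
    unit-mean gamma field (shape ``looks``, scale ``1/looks``), clipped to
    [0, 1].  Larger ``looks`` means weaker speckle (variance 1/looks)."""
    if looks <= 0:
        raise ConfigError(f"speckle looks must be positive, got {looks}")
    rng = np.random.default_rng(seed)
    fieldv = rng.gamma(shape=looks, scale=1.0 / looks, size=np.asarray(image).shape)
    return np.clip(np.asarray(image, dtype=np.float64) * fieldv, 0.0, 1.0)


def render_frame(spec: PhantomSpec) -> PhantomRecord:
    """Envelope -> point-spread blur -> multiplicative speckle."""
    env, mask = render_envelope(spec)
    if spec.psf_sigma_px > 0:
        env = ndimage.gaussian_filter(env, sigma=spec.psf_sigma_px)
    img = apply_speckle(env, spec.speckle_looks, seed=spec.seed + 1)
    h, w = img.shape
    frame = ProbeFrame(
        pixels=img.astype(np.float32),
        probe_center=((h - 1) / 2.0, (w - 1) / 2.0),
        label=spec.manifest_label,
        lesion_size_mm=spec.lesion_diameter_mm,
    )
    return PhantomRecord(frame=frame, lesion_mask=mask, spec=spec)


@dataclass
class PhantomDataset:
    records: list[PhantomRecord]
    manifest: pd.DataFrame
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.records)

    def save(self, out_dir: str | Path) -> Path:
        """Write frames and masks as 8-bit grayscale PNGs plus manifest.csv."""
        from PIL import Image

        out = Path(out_dir)
        (out / "frames").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        paths = []
        for i, rec in enumerate(self.records):
            name = f"{rec.frame.source_id or f'frame{i:04d}'}.png"
            arr = (np.clip(rec.frame.pixels, 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / "frames" / name)
            Image.fromarray((rec.lesion_mask * 255).astype(np.uint8), mode="L").save(
                out / "masks" / name
            )
            paths.append(str(Path("frames") / name))
        manifest["image_path"] = paths
        manifest.to_csv(out / "manifest.csv", index=False)
        return out / "manifest.csv"


def generate_cohort(config: CohortConfig) -> PhantomDataset:
    """Sample a cohort of synthetic patients and render their frames.

    Each patient gets one class and one lesion size (truncated normal); each
    frame varies lesion orientation, offset and eccentricity.  All randomness
    derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_gist = int(round(config.n_patients * config.class_balance))
    labels = ["GIST_like"] * n_gist + ["leiomyoma_like"] * (config.n_patients - n_gist)
    rng.shuffle(labels)

    sizes = _sample_lesion_sizes(rng, config)

    locations = ("esophagus", "cardia", "fundus", "body")
    layers = ("mucosa", "submucosa", "muscularis propria")
    records: list[PhantomRecord] = []
    rows = []
    half_extent_mm = min(config.image_height, config.image_width) / (2 * config.px_per_mm)
    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        label = labels[p]
        size = float(sizes[p])
        n_img = int(rng.integers(config.images_per_patient[0],
                                 config.images_per_patient[1] + 1))
        location = locations[rng.integers(0, len(locations))]
        layer = layers[rng.integers(0, len(layers))]
        for j in range(n_img):
            # keep the lesion inside the frame: offset + radius < half extent
            max_off = max(half_extent_mm - size / 2.0 - 2.0, 4.0)
            off_r = float(np.clip(rng.uniform(7.0, 10.5), 0, max_off))
            phi = rng.uniform(0, 2 * np.pi)
            if label == "GIST_like":
                het = config.gist_heterogeneity
                irr = config.gist_margin_irregularity
            else:
                het = config.leiomyoma_heterogeneity
                irr = config.leiomyoma_margin_irregularity
            spec = PhantomSpec(
                image_height=config.image_height,
                image_width=config.image_width,
                px_per_mm=config.px_per_mm,
                probe_radius_mm=config.probe_radius_mm,
                lesion_center_offset_mm=(off_r * np.sin(phi), off_r * np.cos(phi)),
                lesion_diameter_mm=size,
                lesion_axis_ratio=float(rng.uniform(0.6, 1.0)),
                lesion_angle_deg=float(rng.uniform(0, 180)),
                class_label=label,
                margin_irregularity=irr,
                internal_heterogeneity=het,
                speckle_looks=config.speckle_looks,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec = render_frame(spec)
            rec.frame.source_id = f"{pid}_img{j}"
            rec.frame.patient_id = pid
            records.append(rec)
            rows.append(
                dict(
                    image_path="",
                    patient_id=pid,
                    label=rec.frame.label,
                    lesion_size_mm=size,
                    location=location,
                    layer=layer,
                    probe_center_row=rec.frame.probe_center[0],
                    probe_center_col=rec.frame.probe_center[1],
                    split="unassigned",
                )
            )
    return PhantomDataset(records=records, manifest=pd.DataFrame(rows), config=config)
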