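"""Synthetic paddy-field image generator.

Emulates nadir UAV RGB imagery of a transplanted rice field: plants sit
on a near-regular row grid with Gaussian jitter, each plant is an
irregular rosette of elongated green lobes (tillering leaves) whose
intensity maximum coincides with the annotated center, and the
background is textured soil/water with darker inter-row water bands and
occasional bright specular (sun-glint) patches.  Not photorealistic —
the goal is that every downstream stage (density targets, attention,
localization, sizing) has deterministic, seed-controlled fixtures with
known plant centers.

With an identical :class:`FieldSpec` (including ``seed``) the output is
bit-identical across calls and processes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import zoom

from .io import PointSet, write_image, write_points

log = logging.getLogger(__name__)


class InvalidSpecError(ValueError):
    """A FieldSpec whose geometry cannot be rendered."""


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and appearance of one synthetic field image.

    Defaults describe the scaled-down study condition used throughout the
    test suite: a 256×256 tile with 5 rows × 5 plants at ~44 px spacing
    (≈25 plants per tile, mirroring a dense transplanted stand at reduced
    resolution).
    """

    image_height: int = 256
    image_width: int = 256
    n_rows: int = 5
    plants_per_row: int = 5
    row_spacing: float = 44.0
    within_row_spacing: float = 44.0
    jitter_sd: float = 3.0
    plant_radius_range: tuple[float, float] = (7.0, 12.0)
    background_tone_range: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (70, 110),
        (60, 95),
        (45, 80),
    )
    specular_patch_prob: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        if self.n_rows < 0 or self.plants_per_row < 0:
            raise InvalidSpecError("plant counts must be non-negative")
        if self.row_spacing <= 0 or self.within_row_spacing <= 0:
            raise InvalidSpecError("spacings must be strictly positive")
        if self.within_row_spacing < 2:
            raise InvalidSpecError("within_row_spacing < 2 px implies overlapping plants")
        if self.jitter_sd < 0:
            raise InvalidSpecError("jitter_sd must be >= 0")
        lo, hi = self.plant_radius_range
        if lo <= 0 or hi < lo:
            raise InvalidSpecError("plant_radius_range must be positive and ordered")


def _background(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Textured soil/water background with darker inter-row bands."""
    h, w = spec.image_height, spec.image_width
    img = np.empty((h, w, 3), float)
    for c, (lo, hi) in enumerate(spec.background_tone_range):
        base = rng.uniform(lo, hi)
        # low-frequency value noise: coarse grid blown up smoothly
        coarse = rng.normal(0.0, (hi - lo) * 0.18, size=(max(h // 32, 2), max(w // 32, 2)))
        lowfreq = zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)[:h, :w]
        speckle = rng.normal(0.0, 4.0, size=(h, w))
        img[..., c] = base + lowfreq + speckle
    # darker water bands between plant rows
    if spec.n_rows > 1:
        y0 = (h - (spec.n_rows - 1) * spec.row_spacing) / 2.0
        yy = np.arange(h, dtype=float)[:, None]
        phase = (yy - y0) / spec.row_spacing + 0.5
        band = 0.5 * (1 + np.cos(2 * np.pi * phase))  # peaks midway between rows
        img -= (18.0 * band)[..., None] * np.array([0.6, 0.8, 0.5])
    return img


def _render_plant(img: np.ndarray, cx: float, cy: float, radius: float,
                  rng: np.random.Generator) -> None:
    """Draw one rosette of elongated lobes; intensity maximum at (cx, cy)."""
    h, w = img.shape[:2]
    r_ext = int(np.ceil(radius * 1.6))
    x0, x1 = int(np.floor(cx)) - r_ext, int(np.floor(cx)) + r_ext + 1
    y0, y1 = int(np.floor(cy)) - r_ext, int(np.floor(cy)) + r_ext + 1
    xs0, xs1 = max(x0, 0), min(x1, w)
    ys0, ys1 = max(y0, 0), min(y1, h)
    if xs0 >= xs1 or ys0 >= ys1:
        return
    yy, xx = np.mgrid[ys0:ys1, xs0:xs1]
    u = xx - cx
    v = yy - cy
    mass = np.zeros(u.shape, float)
    n_lobes = int(rng.integers(6, 13))
    base_angle = rng.uniform(0, np.pi)
    for i in range(n_lobes):
        ang = base_angle + i * np.pi / n_lobes + rng.normal(0, 0.25)
        length = radius * rng.uniform(0.7, 1.3)
        width_ = radius * rng.uniform(0.18, 0.32)
        ca, sa = np.cos(ang), np.sin(ang)
        a = (u * ca + v * sa) / length
        b = (-u * sa + v * ca) / width_
        mass += rng.uniform(0.5, 0.9) * np.exp(-0.5 * (a * a * 4 + b * b))
    # central core dominates so the blob's maximum sits at the annotation;
    # the tone also brightens with the core, keeping the center strictly
    # brightest even where the blend saturates
    core = np.exp(-0.5 * (u * u + v * v) / (radius * 0.35) ** 2)
    mass = mass / max(mass.max(), 1e-9) * 0.7 + core
    green = np.array([rng.uniform(45, 80), rng.uniform(110, 160), rng.uniform(40, 70)])
    patch = img[ys0:ys1, xs0:xs1]
    blend = np.clip(mass, 0, 1)[..., None]
    tone = green * (0.82 + 0.35 * core)[..., None]
    patch[:] = patch * (1 - blend) + tone * blend


def _specular_patch(img: np.ndarray, rng: np.random.Generator) -> None:
    """Bright low-saturation ellipse mimicking sun glint on paddy water."""
    h, w = img.shape[:2]
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    ry, rx = rng.uniform(0.06, 0.16) * h, rng.uniform(0.08, 0.22) * w
    yy, xx = np.mgrid[0:h, 0:w]
    d = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    glint = np.exp(-0.5 * d * 3)
    tone = np.array([235.0, 238.0, 228.0])
    img[:] = img * (1 - glint[..., None] * 0.85) + tone * glint[..., None] * 0.85


def generate_field(spec: FieldSpec) -> tuple[np.ndarray, PointSet]:
    """Render one field image and its plant-center annotations.

    Returns an H×W×3 uint8 image and a :class:`PointSet` at image pixel
    scale.  Grid positions are perturbed by Gaussian jitter of sd
    ``spec.jitter_sd``; perturbed positions falling outside the image are
    rejected (logged, so count control stays auditable).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    img = _background(spec, rng)

    h, w = spec.image_height, spec.image_width
    n = spec.n_rows * spec.plants_per_row
    centers = []
    if n > 0:
        y0 = (h - (spec.n_rows - 1) * spec.row_spacing) / 2.0
        x0 = (w - (spec.plants_per_row - 1) * spec.within_row_spacing) / 2.0
        rejected = 0
        for r in range(spec.n_rows):
            for c in range(spec.plants_per_row):
                cy = y0 + r * spec.row_spacing
                cx = x0 + c * spec.within_row_spacing
                if spec.jitter_sd > 0:
                    cy += rng.normal(0, spec.jitter_sd)
                    cx += rng.normal(0, spec.jitter_sd)
                if 0 <= cx < w and 0 <= cy < h:
                    centers.append((cx, cy))
                else:
                    rejected += 1
        if rejected:
            log.warning("rejected %d/%d plant centers outside image bounds", rejected, n)
        # render order fixed by grid scan so output is reproducible
        for cx, cy in centers:
            radius = rng.uniform(*spec.plant_radius_range)
            _render_plant(img, cx, cy, radius, rng)
    if rng.uniform() < spec.specular_patch_prob:
        _specular_patch(img, rng)
    image = np.clip(img, 0, 255).astype(np.uint8)
    pts = PointSet(np.asarray(centers, float).reshape(-1, 2))
    return image, pts


def generate_dataset(out_dir, n_images: int, spec: FieldSpec) -> list[tuple[Path, Path]]:
    """Write ``n_images`` PNG images plus matching annotation files.

    Per-image seeds are spawned deterministically from ``spec.seed`` so
    the whole dataset is reproducible from the single master seed.
    Returns the manifest of (image path, annotation path) pairs.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[Path, Path]] = []
    for i in range(n_images):
        child_seed = int(np.random.SeedSequence(spec.seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        image, pts = generate_field(replace(spec, seed=child_seed))
        img_path = out_dir / f"field_{i:04d}.png"
        ann_path = out_dir / f"field_{i:04d}_points.csv"
        write_image(image, img_path)
        write_points(pts, ann_path)
        manifest.append((img_path, ann_path))
    return manifest
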