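"""Synthetic seabed-like images with known ground truth.

The generator emulates the regime that matters for reconstruction-error
novelty detection on benthic survey photos: a textured, roughly homogeneous
sediment background (base colour plus band-limited noise, optionally with a
smooth illumination gradient) in which small objects of interest are rare —
object pixels stay well below a configurable rarity bound, a few objects per
image at most.  Several sediment types with distinct base colours stand in
for the changes in seabed appearance that motivate clustering images before
training one background model per cluster.

Ground truth is recorded as enclosing circles with class labels, in the same
CSV dialect the review workflow uses, so the evaluation module consumes
generated and human annotations identically.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .image_store import ImageDataset, ImageRecord
from .review import CircleAnnotation

__all__ = ["SedimentType", "ObjectSpec", "FixtureSpec", "SEDIMENT_TYPES",
           "generate_image", "generate_dataset", "object_pixel_fraction"]


@dataclass(frozen=True)
class SedimentType:
    """Background appearance: mean RGB colour, noise amplitude and grain."""

    name: str
    base_rgb: tuple[float, float, float]
    noise_amp: float = 0.06
    noise_sigma: float = 2.0  # px; blur of the white-noise field (band limit)


# Disjoint base-colour ranges so that types are separable in feature space.
SEDIMENT_TYPES = {
    "smooth-sand": SedimentType("smooth-sand", (0.72, 0.66, 0.52), 0.05, 3.0),
    "gravel": SedimentType("gravel", (0.48, 0.46, 0.42), 0.10, 1.2),
    "dark-mud": SedimentType("dark-mud", (0.22, 0.20, 0.18), 0.04, 4.0),
}


@dataclass(frozen=True)
class ObjectSpec:
    """One plantable object: shape, size (diameter, px), contrast, class."""

    shape: str = "disk"  # disk | ellipse | blob
    size: int = 20
    contrast: float = 0.5
    label: str = "ooi"


@dataclass
class FixtureSpec:
    """Recipe for one synthetic seabed image."""

    width: int = 512
    height: int = 512
    sediment_type: str = "smooth-sand"
    illumination: float = 0.0  # peak-to-peak gradient strength, 0 disables
    objects: Sequence[ObjectSpec] = field(default_factory=lambda: (ObjectSpec(),))
    density: float = 2.0  # expected objects per image
    rarity_bound: float = 0.02  # warn if object pixels exceed this fraction
    seed: int = 0


def object_pixel_fraction(spec: FixtureSpec, n_objects: int | None = None) -> float:
    """Upper bound on the fraction of image pixels covered by objects."""
    n = spec.density if n_objects is None else n_objects
    if not spec.objects:
        return 0.0
    worst = max(math.pi * (o.size / 2.0) ** 2 for o in spec.objects)
    return n * worst / float(spec.width * spec.height)


def _background(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    sed = SEDIMENT_TYPES[spec.sediment_type]
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=np.float32)
    noise = rng.standard_normal((h, w)).astype(np.float32)
    noise = gaussian_filter(noise, sed.noise_sigma)
    peak = float(np.abs(noise).max())
    if peak > 0:
        noise = noise / peak * sed.noise_amp
    for c in range(3):
        img[:, :, c] = sed.base_rgb[c] + noise
    if spec.illumination > 0:
        # smooth diagonal vignette-like gradient (irregular lighting)
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
        g = (xx / max(w - 1, 1) + yy / max(h - 1, 1)) / 2.0
        img += (g[:, :, None] - 0.5) * spec.illumination
    return np.clip(img, 0.0, 1.0)


def _render_object(img: np.ndarray, cx: int, cy: int, obj: ObjectSpec,
                   rng: np.random.Generator) -> float:
    """Draw one object; returns its enclosing-circle radius."""
    h, w = img.shape[:2]
    r = obj.size / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    if obj.shape == "disk":
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        radius = r
    elif obj.shape == "ellipse":
        a, b = r, max(1.0, r * 0.6)
        theta = rng.uniform(0, math.pi)
        xr = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
        yr = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        radius = a
    elif obj.shape == "blob":
        # a disk with a lumpy edge: radius modulated by low-order harmonics
        ang = np.arctan2(yy - cy, xx - cx)
        k = rng.integers(3, 6)
        phase = rng.uniform(0, 2 * math.pi)
        rmod = r * (1.0 + 0.25 * np.sin(k * ang + phase))
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= rmod**2
        radius = r * 1.25
    else:
        raise ValueError(f"unknown object shape {obj.shape!r}")
    base = img[mask].mean(axis=0)
    # push towards white or black depending on background brightness
    target = 1.0 if base.mean() < 0.5 else 0.0
    color = base + (target - base) * obj.contrast
    img[mask] = np.clip(color, 0.0, 1.0)
    return radius


def generate_image(spec: FixtureSpec) -> tuple[np.ndarray, list[CircleAnnotation]]:
    """Render one image and its ground-truth circles. Deterministic per seed."""
    if spec.density < 0:
        raise ValueError("density must be >= 0")
    if spec.sediment_type not in SEDIMENT_TYPES:
        raise ValueError(f"unknown sediment type {spec.sediment_type!r}")
    rng = np.random.default_rng(spec.seed)
    img = _background(spec, rng)
    n_objects = int(rng.poisson(spec.density)) if spec.density > 0 else 0
    if n_objects and object_pixel_fraction(spec, n_objects) > spec.rarity_bound:
        import warnings

        warnings.warn(
            "object pixel fraction exceeds the rarity bound; novelty "
            "detection assumes interesting objects are rare",
            stacklevel=2,
        )
    truth: list[CircleAnnotation] = []
    placed: list[tuple[int, int, float]] = []
    for _ in range(n_objects):
        obj = spec.objects[int(rng.integers(0, len(spec.objects)))]
        r = obj.size / 2.0
        margin = int(math.ceil(r * 1.3)) + 2
        if spec.width <= 2 * margin or spec.height <= 2 * margin:
            raise ValueError("objects do not fit inside the image")
        ok = False
        for _attempt in range(50):
            cx = int(rng.integers(margin, spec.width - margin))
            cy = int(rng.integers(margin, spec.height - margin))
            if all((cx - px) ** 2 + (cy - py) ** 2 > (pr + r + 4) ** 2
                   for px, py, pr in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError("could not place object without overlap after 50 tries")
        radius = _render_object(img, cx, cy, obj, rng)
        placed.append((cx, cy, radius))
        truth.append(CircleAnnotation(image_id="", cx=float(cx), cy=float(cy),
                                      radius=float(radius), label=obj.label,
                                      provenance="groundtruth"))
    return img, truth


def generate_dataset(
    out_dir: str | os.PathLike,
    n_images: int,
    type_mix: dict[str, float],
    template: FixtureSpec | None = None,
    seed: int = 0,
) -> tuple[ImageDataset, pd.DataFrame]:
    """Write ``n_images`` PNGs plus manifest and ground-truth CSVs.

    ``type_mix`` maps sediment-type names to proportions (must sum to 1);
    counts are apportioned by largest remainder so they add up exactly.
    Returns the dataset (with the planted sediment type recorded in a
    ``sediment_type`` column of the ground-truth frame for clustering
    validation) and the ground-truth table.
    """
    template = template or FixtureSpec()
    total = sum(type_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"type_mix proportions must sum to 1, got {total}")
    for name in type_mix:
        if name not in SEDIMENT_TYPES:
            raise ValueError(f"unknown sediment type {name!r}")

    # largest-remainder apportionment
    names = sorted(type_mix)
    raw = [type_mix[n] * n_images for n in names]
    counts = [int(math.floor(x)) for x in raw]
    rem = n_images - sum(counts)
    order = sorted(range(len(names)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    records: list[ImageRecord] = []
    truth_rows = []
    type_rows = []
    idx = 0
    for name, count in zip(names, counts):
        for _ in range(count):
            image_id = f"img{idx:04d}"
            spec = replace(template, sediment_type=name, seed=seed + idx)
            img, circles = generate_image(spec)
            path = out_dir / "images" / f"{image_id}.png"
            Image.fromarray((img * 255.0 + 0.5).astype(np.uint8)).save(path)
            records.append(ImageRecord(id=image_id, path=str(path),
                                       width=spec.width, height=spec.height))
            for c in circles:
                truth_rows.append({"image_id": image_id, "cx": c.cx, "cy": c.cy,
                                   "radius": c.radius, "label": c.label,
                                   "provenance": "groundtruth"})
            type_rows.append({"image_id": image_id, "sediment_type": name})
            idx += 1

    dataset = ImageDataset(records)
    dataset.to_manifest(out_dir / "manifest.csv")
    truth = pd.DataFrame(truth_rows,
                         columns=["image_id", "cx", "cy", "radius", "label", "provenance"])
    truth.to_csv(out_dir / "groundtruth.csv", index=False)
    pd.DataFrame(type_rows).to_csv(out_dir / "sediment_types.csv", index=False)
    return dataset, truth
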