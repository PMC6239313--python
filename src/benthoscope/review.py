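"""Human-in-the-loop bookkeeping and segmentation-backend plumbing.

The pipeline's two manual steps — filtering/refining training proposals and
reviewing annotation candidates — are modelled as decision streams applied
to ranked lists; the human choices themselves are inputs.  Around them sit
the preparation of 500×500 training crops with circle masks, deterministic
augmentation ("boosting") of the small training set, inference padding to a
multiple of 64, and the conversion of segmentation masks into circle
annotation candidates.  The instance-segmentation network itself is behind
the :class:`SegmentationBackend` interface so any external model producing
per-pixel class masks can be dropped in.
"""

from __future__ import annotations

import abc
import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.transform import rescale

from .geometry import min_enclosing_circle
from .proposals import TrainingProposal

__all__ = [
    "CircleAnnotation", "TrainingSample", "SegmentationBackend",
    "ThresholdBackend", "OracleBackend", "filter_proposals",
    "refine_proposal", "inscribed_circle", "make_training_samples",
    "render_circle_mask", "boost_training_samples", "pad_to_multiple_64",
    "unpad", "masks_to_candidates", "review_candidates",
    "write_circles_csv", "read_circles_csv", "DEFAULT_PER_CLASS_LIMIT",
    "DEFAULT_CROP_SIZE",
]

DEFAULT_PER_CLASS_LIMIT = 600
DEFAULT_CROP_SIZE = 500

PROVENANCES = ("proposal", "refined", "candidate", "accepted", "groundtruth")


@dataclass
class CircleAnnotation:
    """A circular annotation: centre, radius, class label, provenance."""

    image_id: str
    cx: float
    cy: float
    radius: float
    label: str = "ooi"
    provenance: str = "proposal"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


CIRCLE_COLUMNS = ["image_id", "cx", "cy", "radius", "label", "provenance"]


def write_circles_csv(circles: Sequence[CircleAnnotation], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [{"image_id": c.image_id, "cx": c.cx, "cy": c.cy, "radius": c.radius,
          "label": c.label, "provenance": c.provenance} for c in circles],
        columns=CIRCLE_COLUMNS,
    ).to_csv(path, index=False)


def write_circles_coco(circles: Sequence[CircleAnnotation],
                       path: str | os.PathLike) -> None:
    """COCO-style JSON for circle annotations (bbox = the circle's square
    bounding box; the circle itself is kept under ``circle``)."""
    import json

    image_ids = sorted({c.image_id for c in circles})
    id_map = {img: i + 1 for i, img in enumerate(image_ids)}
    labels = sorted({c.label for c in circles})
    cat_map = {lab: i + 1 for i, lab in enumerate(labels)}
    payload = {
        "images": [{"id": i, "file_name": img} for img, i in id_map.items()],
        "annotations": [
            {"id": k + 1, "image_id": id_map[c.image_id],
             "category_id": cat_map[c.label],
             "bbox": [c.cx - c.radius, c.cy - c.radius,
                      2 * c.radius, 2 * c.radius],
             "circle": [c.cx, c.cy, c.radius],
             "area": float(np.pi * c.radius**2), "iscrowd": 0}
            for k, c in enumerate(circles)
        ],
        "categories": [{"id": i, "name": lab} for lab, i in cat_map.items()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_circles_csv(path: str | os.PathLike) -> list[CircleAnnotation]:
    df = pd.read_csv(path)
    return [CircleAnnotation(image_id=str(r.image_id), cx=float(r.cx),
                             cy=float(r.cy), radius=float(r.radius),
                             label=str(r.label), provenance=str(r.provenance))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Stage II: filtering and refinement

def filter_proposals(
    ranked: Sequence[TrainingProposal],
    decisions: Mapping[int, str | None],
    per_class_limit: int = DEFAULT_PER_CLASS_LIMIT,
) -> tuple[list[tuple[TrainingProposal, str]], dict[str, int]]:
    """Apply human filter decisions to a ranked proposal list.

    ``decisions`` maps the rank index of a proposal to a class label
    (accept) or ``None`` (reject); reviewed indices must form a prefix of
    the ranked list — the reviewer works down the ranking and may stop.
    Acceptance of a class stops counting at ``per_class_limit``; later
    accepts of a full class are dropped.  Returns the accepted
    ``(proposal, label)`` list and per-class counts.
    """
    for idx in decisions:
        if not 0 <= idx < len(ranked):
            raise ValueError(f"decision references unknown proposal index {idx}")
    if decisions:
        reviewed = sorted(decisions)
        if reviewed != list(range(len(reviewed))):
            raise ValueError("decisions must cover a prefix of the ranked list")
    accepted: list[tuple[TrainingProposal, str]] = []
    counts: dict[str, int] = {}
    for idx in sorted(decisions):
        label = decisions[idx]
        if label is None:
            continue
        if counts.get(label, 0) >= per_class_limit:
            continue
        accepted.append((ranked[idx], label))
        counts[label] = counts.get(label, 0) + 1
    return accepted, counts


def inscribed_circle(proposal: TrainingProposal, label: str = "ooi") -> CircleAnnotation:
    """Default refinement suggestion: the circle inscribed in the box."""
    cx, cy = proposal.center
    return CircleAnnotation(image_id=proposal.image_id, cx=cx, cy=cy,
                            radius=proposal.edge / 2.0, label=label,
                            provenance="refined")


def refine_proposal(
    proposal: TrainingProposal,
    label: str,
    circle: CircleAnnotation | None = None,
    image_size: tuple[int, int] | None = None,
) -> CircleAnnotation:
    """Record the human-adjusted circle for an accepted proposal.

    With no adjustment, the suggestion is the proposal box's inscribed
    circle.  ``image_size`` = (width, height) enables a bounds check of the
    adjusted centre.
    """
    if circle is None:
        return inscribed_circle(proposal, label=label)
    if circle.radius <= 0:
        raise ValueError("adjusted circle must have positive radius")
    if image_size is not None:
        w, h = image_size
        if not (0 <= circle.cx < w and 0 <= circle.cy < h):
            raise ValueError(
                f"circle centre ({circle.cx},{circle.cy}) outside image {w}x{h}")
    return replace(circle, image_id=proposal.image_id, label=label,
                   provenance="refined")


# ---------------------------------------------------------------------------
# Stage III: training-sample preparation

@dataclass
class TrainingSample:
    """A training crop plus the refined circles inside it (crop coords)."""

    crop: np.ndarray
    circles: list[CircleAnnotation]
    source_image_id: str
    origin: tuple[int, int] = (0, 0)  # (x, y) of the crop in the source image


def _crop_window(c: float, size: int, extent: int) -> int:
    """Top-left coordinate of a size-window centred at c, shifted inward."""
    start = int(round(c - size / 2.0))
    return min(max(start, 0), max(extent - size, 0))


def make_training_samples(
    refined: Sequence[CircleAnnotation],
    pixels_by_id: Mapping[str, np.ndarray],
    crop_size: int = DEFAULT_CROP_SIZE,
) -> list[TrainingSample]:
    """One crop per refined circle, centred on it and shifted inward at
    borders; every refined circle intersecting a crop is carried over.

    Crops shrink to the image extent when an image is smaller than
    ``crop_size`` in a dimension.
    """
    samples: list[TrainingSample] = []
    by_image: dict[str, list[CircleAnnotation]] = {}
    for c in refined:
        by_image.setdefault(c.image_id, []).append(c)
    for c in refined:
        img = pixels_by_id[c.image_id]
        h, w = img.shape[:2]
        cw, ch = min(crop_size, w), min(crop_size, h)
        x0 = _crop_window(c.cx, cw, w)
        y0 = _crop_window(c.cy, ch, h)
        crop = img[y0 : y0 + ch, x0 : x0 + cw]
        carried = []
        for other in by_image[c.image_id]:
            # circle intersects the crop rectangle?
            nx = min(max(other.cx, x0), x0 + cw - 1)
            ny = min(max(other.cy, y0), y0 + ch - 1)
            if (other.cx - nx) ** 2 + (other.cy - ny) ** 2 <= other.radius**2:
                carried.append(replace(other, cx=other.cx - x0, cy=other.cy - y0))
        samples.append(TrainingSample(crop=np.ascontiguousarray(crop),
                                      circles=carried,
                                      source_image_id=c.image_id,
                                      origin=(x0, y0)))
    return samples


def render_circle_mask(sample: TrainingSample,
                       class_ids: Mapping[str, int] | None = None) -> np.ndarray:
    """Per-pixel class-id mask of a sample: all pixels inside each circle
    belong to the object; background is 0."""
    h, w = sample.crop.shape[:2]
    mask = np.zeros((h, w), dtype=np.int32)
    if class_ids is None:
        labels = sorted({c.label for c in sample.circles})
        class_ids = {lab: i + 1 for i, lab in enumerate(labels)}
    yy, xx = np.mgrid[0:h, 0:w]
    for c in sample.circles:
        inside = (xx - c.cx) ** 2 + (yy - c.cy) ** 2 <= c.radius**2
        mask[inside] = class_ids[c.label]
    return mask


_DIHEDRAL = [(False, False, 0), (True, False, 0), (False, True, 0), (True, True, 0),
             (False, False, 1), (True, False, 1), (False, True, 1), (True, True, 1)]


def _transform_sample(sample: TrainingSample, flip_h: bool, flip_v: bool,
                      rot90: int, scale: float) -> TrainingSample:
    img = sample.crop
    circles = list(sample.circles)
    h, w = img.shape[:2]
    if flip_h:
        img = img[:, ::-1]
        circles = [replace(c, cx=w - 1 - c.cx) for c in circles]
    if flip_v:
        img = img[::-1, :]
        circles = [replace(c, cy=h - 1 - c.cy) for c in circles]
    if rot90 % 4:
        for _ in range(rot90 % 4):
            hh, ww = img.shape[:2]
            img = np.rot90(img)  # CCW: (x, y) -> (y, ww - 1 - x)
            circles = [replace(c, cx=c.cy, cy=ww - 1 - c.cx) for c in circles]
    if abs(scale - 1.0) > 1e-12:
        hh, ww = img.shape[:2]
        scaled = rescale(img, scale, channel_axis=2, anti_aliasing=scale < 1.0,
                         preserve_range=True).astype(img.dtype)
        sh, sw = scaled.shape[:2]
        out = np.zeros_like(img)
        # keep the original frame: centre-crop or centre-pad back to (hh, ww)
        oy, ox = (sh - hh) // 2, (sw - ww) // 2
        if scale >= 1.0:
            out = scaled[oy : oy + hh, ox : ox + ww]
            shift_x, shift_y = -ox, -oy
        else:
            py, px = (hh - sh) // 2, (ww - sw) // 2
            out[py : py + sh, px : px + sw] = scaled
            shift_x, shift_y = px, py
        circles = [replace(c, cx=c.cx * scale + shift_x,
                           cy=c.cy * scale + shift_y,
                           radius=max(c.radius * scale, 1e-6)) for c in circles]
        img = out
    return TrainingSample(crop=np.ascontiguousarray(img), circles=circles,
                          source_image_id=sample.source_image_id,
                          origin=sample.origin)


def boost_training_samples(samples: Sequence[TrainingSample],
                           factor_target: int,
                           seed: int = 0,
                           scale_jitter: float = 0.1) -> Iterator[TrainingSample]:
    """Seeded stream of augmented variants of a small training set.

    Augmentations are label-preserving: horizontal/vertical flips, 90°
    rotations (the 8 dihedral symmetries, emitted first per sample) and
    ±``scale_jitter`` scale changes about the crop centre frame.  The stream
    cycles through the samples and yields ``factor_target`` variants,
    deterministic for a fixed seed.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no training samples to boost")
    rng = np.random.default_rng(seed)
    emitted = 0
    round_idx = 0
    while emitted < factor_target:
        for sample in samples:
            if emitted >= factor_target:
                return
            if round_idx < len(_DIHEDRAL):
                fh, fv, rot = _DIHEDRAL[round_idx]
                scale = 1.0
            else:
                fh, fv, rot = _DIHEDRAL[int(rng.integers(0, 8))]
                scale = float(rng.uniform(1.0 - scale_jitter, 1.0 + scale_jitter))
            yield _transform_sample(sample, fh, fv, rot, scale)
            emitted += 1
        round_idx += 1


# ---------------------------------------------------------------------------
# Stage III/IV: inference padding, mask post-processing, candidate review

def pad_to_multiple_64(image: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad right/bottom so both spatial dimensions divide by 64.

    Returns the padded image and the original ``(height, width)`` so the
    padding can be undone; original pixel coordinates remain valid.
    """
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("cannot pad a zero-sized image")
    ph = (-h) % 64
    pw = (-w) % 64
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="constant"), (h, w)


def unpad(image: np.ndarray, original_size: tuple[int, int]) -> np.ndarray:
    h, w = original_size
    return image[:h, :w]


def masks_to_candidates(mask: np.ndarray, image_id: str = "",
                        label: str = "ooi") -> list[CircleAnnotation]:
    """Minimum enclosing circle of each 8-connected region of non-background
    pixels (class-agnostic: any nonzero pixel is "interesting")."""
    interesting = np.asarray(mask) != 0
    lab = cc_label(interesting, connectivity=2)
    out: list[CircleAnnotation] = []
    for k in range(1, lab.max() + 1):
        ys, xs = np.nonzero(lab == k)
        cx, cy, r = min_enclosing_circle(np.column_stack([xs, ys]))
        out.append(CircleAnnotation(image_id=image_id, cx=cx, cy=cy,
                                    radius=max(r, 0.5), label=label,
                                    provenance="candidate"))
    return out


def review_candidates(candidates: Sequence[CircleAnnotation],
                      accepted_indices: Sequence[int]) -> tuple[list[CircleAnnotation], dict[str, int]]:
    """Keep the human-accepted subset of annotation candidates.

    ``accepted_indices`` index into ``candidates``; the result carries
    provenance ``accepted``.  Returns the accepted list and per-class counts.
    """
    accepted: list[CircleAnnotation] = []
    counts: dict[str, int] = {}
    for idx in accepted_indices:
        if not 0 <= idx < len(candidates):
            raise ValueError(f"unknown candidate index {idx}")
        c = replace(candidates[idx], provenance="accepted")
        accepted.append(c)
        counts[c.label] = counts.get(c.label, 0) + 1
    return accepted, counts


# ---------------------------------------------------------------------------
# Segmentation backend interface

class SegmentationBackend(abc.ABC):
    """Contract: RGB image in, per-pixel integer class mask out (0 = background).

    The mask has the shape of the padded input; implementations receive the
    image already padded to a multiple of 64.  This is the drop-in point for
    an external instance-segmentation network.
    """

    @abc.abstractmethod
    def segment(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        ...

    def candidates(self, image: np.ndarray, image_id: str = "") -> list[CircleAnnotation]:
        padded, orig = pad_to_multiple_64(image)
        mask = self.segment(padded)
        if mask.shape[:2] != padded.shape[:2]:
            raise ValueError("backend mask shape does not match padded input")
        return masks_to_candidates(unpad(mask, orig), image_id=image_id)


class ThresholdBackend(SegmentationBackend):
    """Trivial test backend: thresholds one channel (or the deviation of
    the mean intensity from a reference) to produce a binary mask."""

    def __init__(self, threshold: float = 0.5, channel: int | None = None,
                 reference: float | None = None):
        self.threshold = threshold
        self.channel = channel
        self.reference = reference

    def segment(self, image: np.ndarray) -> np.ndarray:
        if self.channel is not None:
            values = image[:, :, self.channel]
        else:
            values = image.mean(axis=2)
        if self.reference is not None:
            values = np.abs(values - self.reference)
        return (values > self.threshold).astype(np.int32)


class OracleBackend(SegmentationBackend):
    """Test backend returning a pre-computed mask, keyed by nothing: the
    caller supplies the mask for the image it will segment."""

    def __init__(self, mask: np.ndarray):
        self.mask = np.asarray(mask)

    def segment(self, image: np.ndarray) -> np.ndarray:
        h, w = image.shape[:2]
        out = np.zeros((h, w), dtype=np.int32)
        mh, mw = self.mask.shape[:2]
        out[:mh, :mw] = self.mask
        return out
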