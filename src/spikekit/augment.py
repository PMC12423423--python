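"""Annotation-aware data augmentation: quarter-turn rotation, flips, brightness.

Each geometric transform is applied to the pixels and, consistently, to
every oriented box: quarter turns add 90 degrees to the long-side angle,
flips mirror it (theta -> 180 - theta), brightness leaves the annotation
untouched. Coordinates are continuous with the image spanning [0, W] x
[0, H], so a horizontal flip maps cx to W - cx.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Literal, Sequence

import numpy as np

from .containers import AnnotatedImage, ImageAnnotation
from .geometry import OrientedBox, normalize_box

__all__ = [
    "rotate90",
    "flip",
    "adjust_brightness",
    "augment_dataset",
    "split_dataset",
    "BRIGHTNESS_FACTORS",
]

# +-10% and +-20% brightness.
BRIGHTNESS_FACTORS = (0.8, 0.9, 1.1, 1.2)


def _rotate_box_quarter(box: OrientedBox, W: int, H: int) -> OrientedBox:
    # one counter-clockwise quarter turn in array terms: (x, y) -> (y, W - x)
    return normalize_box(
        replace(box, cx=box.cy, cy=W - box.cx, theta=(box.theta + 90.0) % 180.0)
    )


def rotate90(img: AnnotatedImage, k: int) -> AnnotatedImage:
    """Rotate image and annotation by k quarter turns (k in {1, 2, 3})."""
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3 quarter turns, got {k}")
    pixels = np.rot90(img.pixels, k=k, axes=(0, 1)).copy()
    boxes = list(img.annotation.boxes)
    W, H = img.size
    for _ in range(k):
        boxes = [_rotate_box_quarter(b, W, H) for b in boxes]
        W, H = H, W
    ann = ImageAnnotation(img.image_id, (W, H), boxes)
    return AnnotatedImage(pixels, ann)


def flip(img: AnnotatedImage, axis: Literal["horizontal", "vertical"]) -> AnnotatedImage:
    """Mirror image and annotation horizontally (left-right) or vertically."""
    W, H = img.size
    if axis == "horizontal":
        pixels = img.pixels[:, ::-1].copy()
        boxes = [
            normalize_box(replace(b, cx=W - b.cx, theta=(180.0 - b.theta) % 180.0))
            for b in img.annotation.boxes
        ]
    elif axis == "vertical":
        pixels = img.pixels[::-1].copy()
        boxes = [
            normalize_box(replace(b, cy=H - b.cy, theta=(180.0 - b.theta) % 180.0))
            for b in img.annotation.boxes
        ]
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return AnnotatedImage(pixels, ImageAnnotation(img.image_id, (W, H), boxes))


def adjust_brightness(img: AnnotatedImage, factor: float) -> AnnotatedImage:
    """Scale pixel values by ``factor`` (clipped to [0, 255]); boxes unchanged."""
    if factor <= 0:
        raise ValueError(f"brightness factor must be positive, got {factor}")
    pixels = np.clip(img.pixels.astype(np.float64) * factor, 0, 255).astype(np.uint8)
    ann = ImageAnnotation(img.image_id, img.annotation.image_size, list(img.annotation.boxes))
    return AnnotatedImage(pixels, ann)


def _with_id(img: AnnotatedImage, image_id: str) -> AnnotatedImage:
    ann = ImageAnnotation(image_id, img.annotation.image_size, list(img.annotation.boxes))
    return AnnotatedImage(img.pixels, ann)


def augment_dataset(
    images: Sequence[AnnotatedImage], retain_originals: bool = True
) -> list[AnnotatedImage]:
    """Apply the full augmentation suite to every image.

    Per input: three quarter-turn rotations, two flips and four brightness
    variants (0.8x, 0.9x, 1.1x, 1.2x), each applied to the *original* image
    (no stacking), plus the original itself when ``retain_originals`` — a
    tenfold expansion. Output ids are the input id with a deterministic
    suffix.
    """
    if not images:
        raise ValueError("augment_dataset needs at least one image")
    out: list[AnnotatedImage] = []
    for img in images:
        base = img.image_id
        if retain_originals:
            out.append(img)
        for k in (1, 2, 3):
            out.append(_with_id(rotate90(img, k), f"{base}_rot{90 * k}"))
        out.append(_with_id(flip(img, "horizontal"), f"{base}_fliph"))
        out.append(_with_id(flip(img, "vertical"), f"{base}_flipv"))
        for f in BRIGHTNESS_FACTORS:
            out.append(_with_id(adjust_brightness(img, f), f"{base}_b{int(round(f * 100)):03d}"))
    return out


def split_dataset(
    images: Sequence[AnnotatedImage],
    ratios: Sequence[float] = (6, 1, 3),
    seed: int = 0,
) -> tuple[list[AnnotatedImage], ...]:
    """Random disjoint partition into len(ratios) parts by the given shares.

    Part sizes are the largest-remainder rounding of ``ratios``; the same
    seed always yields the same split.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError(f"ratios must be positive, got {ratios}")
    n = len(images)
    if n < len(ratios):
        raise ValueError(f"cannot split {n} images into {len(ratios)} non-empty parts")
    total = float(sum(ratios))
    exact = [n * r / total for r in ratios]
    sizes = [int(e) for e in exact]
    remainders = sorted(range(len(ratios)), key=lambda i: exact[i] - sizes[i], reverse=True)
    for i in range(n - sum(sizes)):
        sizes[remainders[i % len(ratios)]] += 1
    order = np.random.default_rng(seed).permutation(n)
    parts: list[list[AnnotatedImage]] = []
    start = 0
    for s in sizes:
        parts.append([images[j] for j in order[start:start + s]])
        start += s
    return tuple(parts)
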