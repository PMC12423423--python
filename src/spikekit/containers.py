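"""Shared data containers: annotations, detection sets, annotated images."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import OrientedBox

__all__ = ["ImageAnnotation", "DetectionSet", "AnnotatedImage"]


@dataclass
class ImageAnnotation:
    """Ground-truth oriented boxes for one image."""

    image_id: str
    image_size: tuple[int, int]  # (W, H) in px
    boxes: list[OrientedBox] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class DetectionSet:
    """Scored oriented boxes predicted for one image."""

    image_id: str
    image_size: tuple[int, int]
    boxes: list[OrientedBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in self.boxes:
            if b.score is None or not 0.0 <= b.score <= 1.0:
                raise ValueError(f"detection boxes need a score in [0, 1], got {b.score}")

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class AnnotatedImage:
    """An 8-bit RGB image together with its oriented-box annotation."""

    pixels: np.ndarray  # H x W x 3 uint8
    annotation: ImageAnnotation

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {self.pixels.shape}")
        H, W = self.pixels.shape[:2]
        if self.annotation.image_size != (W, H):
            raise ValueError(
                f"annotation size {self.annotation.image_size} != pixel size {(W, H)}"
            )

    @property
    def image_id(self) -> str:
        return self.annotation.image_id

    @property
    def size(self) -> tuple[int, int]:
        """(W, H) in px."""
        return self.annotation.image_size
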