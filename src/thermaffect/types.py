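"""Core containers shared across the pipeline.

Conventions used everywhere in this package:

* images are 2-D ``uint8`` arrays indexed ``[row, col]``, 0-based;
* rectangles are half-open row/col intervals ``[top, bottom) x [left, right)``;
* rigid transforms rotate about an explicitly supplied centre point and are
  stored as ``(dx, dy, theta)`` with ``dx`` a column shift, ``dy`` a row
  shift and ``theta`` in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical region-of-interest names, in the fixed order used by the
#: 440-entry feature vector.
ROI_NAMES: tuple[str, ...] = (
    "forehead",
    "left_cheek",
    "right_cheek",
    "nose",
    "maxillary",
)

#: Resting condition name.
BASELINE = "baseline"

#: The four website conditions: usability (U) x aesthetics (A), high (+) or
#: low (-).  U+ conditions elicit positive valence, U- negative.
TASK_CONDITIONS: tuple[str, ...] = ("U+A+", "U+A-", "U-A+", "U-A-")

#: All session conditions.
CONDITIONS: tuple[str, ...] = (BASELINE,) + TASK_CONDITIONS

POSITIVE_CONDITIONS: tuple[str, ...] = ("U+A+", "U+A-")
NEGATIVE_CONDITIONS: tuple[str, ...] = ("U-A+", "U-A-")


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle ``[top, bottom) x [left, right)``."""

    top: int
    left: int
    bottom: int
    right: int

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def center(self) -> tuple[float, float]:
        return ((self.top + self.bottom - 1) / 2.0, (self.left + self.right - 1) / 2.0)

    def is_empty(self) -> bool:
        return self.height <= 0 or self.width <= 0

    def contains(self, other: "Rect") -> bool:
        return (
            self.top <= other.top
            and self.left <= other.left
            and self.bottom >= other.bottom
            and self.right >= other.right
        )

    def clip_to(self, other: "Rect") -> "Rect":
        return Rect(
            max(self.top, other.top),
            max(self.left, other.left),
            min(self.bottom, other.bottom),
            min(self.right, other.right),
        )

    def slice(self) -> tuple[slice, slice]:
        return slice(self.top, self.bottom), slice(self.left, self.right)


@dataclass
class ThermalFrame:
    """One grayscale facial thermogram with acquisition metadata."""

    pixels: np.ndarray
    participant: str = ""
    condition: str = BASELINE
    frame_index: int = 0

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2:
            raise ValueError("frame pixels must be a 2-D matrix")
        if pix.shape[0] < 32 or pix.shape[1] < 32:
            raise ValueError("frame must be at least 32x32 pixels")
        if pix.min() < 0 or pix.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        self.pixels = pix.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RigidTransform:
    """Rotation by ``theta`` degrees about a centre, then a translation.

    The mapping is ``p_out = R(theta) @ (p - c) + c + (dy, dx)`` with points
    ``p = (row, col)`` and a centre ``c`` supplied at application time (the
    geometric frame centre throughout this package).
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def _rot(self) -> np.ndarray:
        t = math.radians(self.theta)
        return np.array(
            [[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]]
        )

    def map_points(self, points: np.ndarray, center: tuple[float, float]) -> np.ndarray:
        """Apply the transform to an ``(n, 2)`` array of (row, col) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(center, dtype=float)
        shifted = (pts - c) @ self._rot().T
        return shifted + c + np.array([self.dy, self.dx])

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``first`` then ``self``."""
        t1 = np.array([first.dy, first.dx])
        t2 = np.array([self.dy, self.dx])
        t = self._rot() @ t1 + t2
        return RigidTransform(dx=float(t[1]), dy=float(t[0]), theta=self.theta + first.theta)

    def inverse(self) -> "RigidTransform":
        t = np.array([self.dy, self.dx])
        ti = -self._rot().T @ t
        return RigidTransform(dx=float(ti[1]), dy=float(ti[0]), theta=-self.theta)

    @property
    def translation_magnitude(self) -> float:
        return math.hypot(self.dx, self.dy)


@dataclass
class FaceGeometry:
    """Face bounding box, face width ``D``, eye centroids and ROI ratios.

    ``roi_ratio_table`` maps an ROI name to
    ``(center_row_frac, center_col_frac, height_frac, width_frac)`` where the
    centre fractions are relative to the bounding-box height/width and the
    size fractions are multiples of the face width ``D``.
    """

    bbox: Rect
    face_width: float
    eye_centroids: tuple[tuple[float, float], tuple[float, float]]
    roi_ratio_table: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)


@dataclass
class RoiPatch:
    """A named rectangular sub-matrix cut from a registered frame."""

    name: str
    rect: Rect
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValueError(f"unknown ROI name: {self.name!r}")
        m = np.asarray(self.matrix)
        if m.shape != (self.rect.height, self.rect.width):
            raise ValueError("patch matrix dimensions do not match its rectangle")
        self.matrix = m
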