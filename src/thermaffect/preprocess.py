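"""Frame registration, denoising and geometric ROI localization.

The preprocessing chain mirrors standard practice for unrestrained facial
thermography: head motion between frames is removed by a rigid (translate +
rotate) registration anchored on the centroids of the two eye regions — the
hottest, most stable landmarks in a facial thermogram — then median and
Gaussian filters suppress sensor noise, Otsu binarization frames the face,
and the five ROIs (forehead, left/right cheek, nose, maxillary) are placed
from a geometric ratio model of the face box.

Nearest-neighbour resampling is used throughout so registration only
rearranges pixel values; the gray palette itself is never altered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ._imageops import apply_rigid
from .errors import EmptyForegroundError, EyesNotFoundError, ThermaffectError
from .synth import DEFAULT_ROI_RATIOS, roi_rects_from_geometry
from .types import (
    ROI_NAMES,
    FaceGeometry,
    Rect,
    RigidTransform,
    RoiPatch,
    ThermalFrame,
)

EyePair = tuple[tuple[float, float], tuple[float, float]]


def _as_pixels(frame: ThermalFrame | np.ndarray) -> np.ndarray:
    return frame.pixels if isinstance(frame, ThermalFrame) else np.asarray(frame)


def _foreground_bbox(pixels: np.ndarray) -> Rect:
    """Otsu-binarize and return the bounding box of the largest component."""
    if pixels.min() == pixels.max():
        raise EmptyForegroundError("image is uniform; no face contour to binarize")
    mask = pixels > threshold_otsu(pixels)
    if not mask.any():
        raise EmptyForegroundError("binarization produced an empty foreground")
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    rows, cols = np.nonzero(labels == largest)
    return Rect(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)


def detect_eye_centroids(
    frame: ThermalFrame | np.ndarray, percentile: float = 95.0
) -> EyePair:
    """Locate the two eye centroids in the upper half of the face box.

    Pixels at or above the given intensity percentile (within the upper half
    of the face bounding box) are grouped into connected components; the two
    components with the hottest peaks are taken as the eyes.  Returns the
    (row, col) centroids with the left eye (smaller column) first.
    """
    pixels = _as_pixels(frame)
    try:
        bbox = _foreground_bbox(pixels)
    except EmptyForegroundError as exc:
        raise EyesNotFoundError("eyes not found: no face foreground") from exc
    upper = Rect(bbox.top, bbox.left, bbox.top + bbox.height // 2, bbox.right)
    region = pixels[upper.slice()].astype(float)
    threshold = np.percentile(region, percentile)
    mask = region >= threshold
    labels, n = ndimage.label(mask)
    if n < 2:
        raise EyesNotFoundError(f"eyes not found: {n} candidate component(s)")
    peaks = ndimage.maximum(region, labels, index=np.arange(1, n + 1))
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    # Hottest two components; peak intensity first, component size as
    # tie-break so a large warm patch never outranks a true eye.
    order = np.lexsort((sizes, peaks))[::-1][:2]
    centroids = []
    for i in order:
        label = int(i) + 1
        component = labels == label
        # Restrict to the hot core near the component peak: the percentile
        # mask bleeds into the surrounding facial gradient and would bias a
        # plain centroid, while near the peak the eye blob dominates.
        peak = peaks[int(i)]
        core_level = threshold + 0.6 * (peak - threshold)
        core = component & (region >= core_level)
        if not core.any():  # pragma: no cover - peak >= core_level always
            core = component
        weights = np.where(core, region - core_level + 1.0, 0.0)
        total = weights.sum()
        rr, cc = np.nonzero(core)
        r = float((weights[rr, cc] * rr).sum() / total)
        c = float((weights[rr, cc] * cc).sum() / total)
        centroids.append((r, c))
    absolute = sorted(
        ((r + upper.top, c + upper.left) for r, c in centroids), key=lambda p: p[1]
    )
    return (absolute[0], absolute[1])


def register_frame(
    frame: ThermalFrame | np.ndarray,
    reference: ThermalFrame | np.ndarray,
    fill_value: float = 0.0,
    frame_eyes: EyePair | None = None,
    reference_eyes: EyePair | None = None,
) -> tuple[np.ndarray, RigidTransform]:
    """Rigidly align ``frame`` so its eye centroids land on the reference's.

    The rotation comes from the inter-eye angle difference and the
    translation from the eye-midpoint difference; resampling is
    nearest-neighbour, so output pixels are a permutation-with-fill of the
    input values.  The returned transform is expressed about the geometric
    frame centre.  Detected eyes can be overridden with explicit
    coordinates (e.g. manual seeding of a first frame).
    """
    pixels = _as_pixels(frame)
    ref_pixels = _as_pixels(reference)
    eyes_f = frame_eyes if frame_eyes is not None else detect_eye_centroids(pixels)
    eyes_r = (
        reference_eyes if reference_eyes is not None else detect_eye_centroids(ref_pixels)
    )

    mid_f = np.mean(np.asarray(eyes_f, dtype=float), axis=0)
    mid_r = np.mean(np.asarray(eyes_r, dtype=float), axis=0)
    vec_f = np.asarray(eyes_f[1], dtype=float) - np.asarray(eyes_f[0], dtype=float)
    vec_r = np.asarray(eyes_r[1], dtype=float) - np.asarray(eyes_r[0], dtype=float)
    ang_f = math.atan2(vec_f[0], vec_f[1])
    ang_r = math.atan2(vec_r[0], vec_r[1])
    # R(theta) rotates a vector at atan2(dr, dc) angle a to angle a - theta,
    # so mapping the frame's inter-eye angle onto the reference's needs
    # theta = ang_f - ang_r.
    theta = math.degrees(ang_f - ang_r)

    # Map p -> R (p - mid_f) + mid_r, re-expressed about the frame centre:
    # p -> R (p - c) + c + t with t = R (c - mid_f) + mid_r - c.
    center = np.array([(pixels.shape[0] - 1) / 2.0, (pixels.shape[1] - 1) / 2.0])
    t = math.radians(theta)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    trans = rot @ (center - mid_f) + mid_r - center
    transform = RigidTransform(dx=float(trans[1]), dy=float(trans[0]), theta=theta)
    registered = apply_rigid(
        pixels, transform.dx, transform.dy, transform.theta, cval=fill_value
    )
    return registered, transform


def denoise(
    frame: ThermalFrame | np.ndarray, median_window: int = 3, gaussian_sigma: float = 1.0
) -> np.ndarray:
    """Median filter then Gaussian filter, clipped/rounded back to [0, 255]."""
    if median_window < 1 or median_window % 2 == 0:
        raise ValueError("median_window must be an odd integer >= 1")
    if gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be >= 0")
    out = _as_pixels(frame).astype(float)
    if median_window > 1:
        out = ndimage.median_filter(out, size=median_window, mode="nearest")
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=gaussian_sigma, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def face_bbox(
    frame: ThermalFrame | np.ndarray,
    roi_ratio_table: dict[str, tuple[float, float, float, float]] | None = None,
    eyes: EyePair | None = None,
) -> FaceGeometry:
    """Binarize (Otsu), box the largest foreground component, measure D.

    The face width ``D`` is the column extent of the box.  Eye centroids are
    detected unless supplied explicitly.
    """
    pixels = _as_pixels(frame)
    bbox = _foreground_bbox(pixels)
    if eyes is None:
        eyes = detect_eye_centroids(pixels)
    return FaceGeometry(
        bbox=bbox,
        face_width=float(bbox.width),
        eye_centroids=eyes,
        roi_ratio_table=dict(roi_ratio_table or DEFAULT_ROI_RATIOS),
    )


def locate_rois(
    geometry: FaceGeometry, frame: ThermalFrame | np.ndarray
) -> dict[str, RoiPatch]:
    """Cut the five ROI patches from a registered frame.

    Each rectangle is centred at its ratio-table position inside the face
    box, sized as a fraction of the face width D and clipped to the box.
    """
    missing = set(ROI_NAMES) - set(geometry.roi_ratio_table)
    if missing:
        raise ThermaffectError(f"ratio table missing ROIs: {sorted(missing)}")
    pixels = _as_pixels(frame)
    frame_rect = Rect(0, 0, pixels.shape[0], pixels.shape[1])
    if not frame_rect.contains(geometry.bbox):
        raise ThermaffectError("face box lies outside the frame")
    rects = roi_rects_from_geometry(
        geometry.bbox, geometry.face_width, geometry.roi_ratio_table
    )
    return {
        name: RoiPatch(name=name, rect=rect, matrix=pixels[rect.slice()])
        for name, rect in rects.items()
        if name in ROI_NAMES
    }


@dataclass
class PreprocessedSession:
    """Registered, denoised frames of one session plus located ROI patches."""

    participant: str
    condition: str
    geometry: FaceGeometry
    frames: list[np.ndarray]
    transforms: list[RigidTransform]
    patches: list[dict[str, RoiPatch]]


def preprocess_session(
    frames: list[ThermalFrame],
    reference: ThermalFrame | np.ndarray | None = None,
    roi_ratio_table: dict[str, tuple[float, float, float, float]] | None = None,
    median_window: int = 3,
    gaussian_sigma: float = 1.0,
    reference_eyes: EyePair | None = None,
    fill_value: float = 0.0,
) -> PreprocessedSession:
    """Run the full preprocessing chain over one session.

    Registration targets the supplied reference frame (the participant's
    first baseline frame in a full study run; defaults to the session's
    first frame).  Face geometry is measured once on the denoised reference
    and reused for every registered frame, mirroring the
    seed-once-then-track protocol.  ``reference_eyes`` optionally replaces
    automatic detection on the reference with explicit coordinates.
    """
    if not frames:
        raise ValueError("session has no frames")
    ref_pixels = _as_pixels(reference if reference is not None else frames[0])
    ref_eyes = (
        reference_eyes
        if reference_eyes is not None
        else detect_eye_centroids(ref_pixels)
    )
    geometry = face_bbox(
        denoise(ref_pixels, median_window, gaussian_sigma),
        roi_ratio_table=roi_ratio_table,
        eyes=ref_eyes,
    )

    registered: list[np.ndarray] = []
    transforms: list[RigidTransform] = []
    patches: list[dict[str, RoiPatch]] = []
    for frame in frames:
        aligned, transform = register_frame(
            frame, ref_pixels, fill_value=fill_value, reference_eyes=ref_eyes
        )
        clean = denoise(aligned, median_window, gaussian_sigma)
        registered.append(clean)
        transforms.append(transform)
        patches.append(locate_rois(geometry, clean))
    return PreprocessedSession(
        participant=frames[0].participant,
        condition=frames[0].condition,
        geometry=geometry,
        frames=registered,
        transforms=transforms,
        patches=patches,
    )
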