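"""Shared low-level image operations."""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage


def apply_rigid(
    image: np.ndarray,
    dx: float,
    dy: float,
    theta: float,
    center: tuple[float, float] | None = None,
    cval: float = 0.0,
) -> np.ndarray:
    """Rotate ``image`` by ``theta`` degrees about ``center`` then shift it.

    Nearest-neighbour resampling keeps the 0-255 integer palette intact: the
    output is a permutation-with-fill of the input values.  ``dx`` shifts
    columns, ``dy`` shifts rows; ``center`` defaults to the geometric frame
    centre.
    """
    if center is None:
        center = ((image.shape[0] - 1) / 2.0, (image.shape[1] - 1) / 2.0)
    t = math.radians(theta)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    c = np.asarray(center, dtype=float)
    shift = np.array([dy, dx], dtype=float)
    # affine_transform computes input_coord = matrix @ output_coord + offset,
    # i.e. the inverse of the forward map p -> R (p - c) + c + shift.
    matrix = rot.T
    offset = c - rot.T @ (c + shift)
    return ndimage.affine_transform(
        image, matrix, offset=offset, order=0, mode="constant", cval=cval,
        output=image.dtype,
    )
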