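"""Per-ROI grayscale statistics and GLCM texture features.

Each ROI patch yields 8 statistical features computed directly on the gray
matrix — mean, variance, mean of per-row variances, mean of per-column
variances, range (max − min), median, mean of per-row medians, mean of
per-column medians — plus 5 gray-level co-occurrence statistics (angular
second moment, contrast, correlation, homogeneity, dissimilarity), each
expanded over 4 angles (0°, 45°, 90°, 135°) and 4 distances (2, 4, 8, 16
pixels by default): 8 + 5·16 = 88 features per ROI, 440 per frame over the
five canonical ROIs.

Co-occurrence counting is symmetric (both directions of every offset are
counted), and matrices are normalized to probabilities before the texture
statistics so that ASM and homogeneity stay in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateDimensionError,
    NoPairsError,
    UndefinedCorrelationError,
)
from .types import ROI_NAMES, RoiPatch

logger = logging.getLogger(__name__)

#: Statistical feature names, in their fixed order.
STAT_NAMES: tuple[str, ...] = (
    "mean",
    "variance",
    "row_var_mean",
    "col_var_mean",
    "range",
    "median",
    "row_median_mean",
    "col_median_mean",
)

#: GLCM texture statistic names, in their fixed order.
GLCM_STAT_NAMES: tuple[str, ...] = (
    "asm",
    "contrast",
    "correlation",
    "homogeneity",
    "dissimilarity",
)

#: Offset (d_row, d_col) per angle for a unit distance; both the offset and
#: its negation are counted, so the resulting matrix is symmetric.
_ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),     # same row, columns d apart
    45: (-1, 1),   # up-right diagonal (rows decrease as columns increase)
    90: (1, 0),    # same column, rows d apart
    135: (1, 1),   # down-right diagonal
}


@dataclass(frozen=True)
class GlcmConfig:
    """Quantization and offset grid for co-occurrence matrices."""

    levels: int = 32
    distances: tuple[int, ...] = (2, 4, 8, 16)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d <= 0 for d in self.distances):
            raise ValueError("distances must be positive")
        bad = set(self.angles) - set(_ANGLE_OFFSETS)
        if bad:
            raise ValueError(f"angles must be within {sorted(_ANGLE_OFFSETS)}; got {sorted(bad)}")


@dataclass
class Glcm:
    """A co-occurrence matrix with its configuration echo."""

    P: np.ndarray
    levels: int
    angle: int
    distance: int
    normalized: bool

    def marginal_moments(self) -> tuple[float, float, float, float]:
        """(mu_x, mu_y, sigma_x, sigma_y) over 1-based level indices."""
        p = self.P if self.normalized else self.P / self.P.sum()
        idx = np.arange(1, self.levels + 1, dtype=float)
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        mu_x = float(idx @ px)
        mu_y = float(idx @ py)
        sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
        sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))
        return mu_x, mu_y, sigma_x, sigma_y


def stat_features(matrix: np.ndarray) -> dict[str, float]:
    """The 8 statistical features of a gray sub-matrix.

    Variances are sample variances: the overall variance divides by
    ``w*h - 1``, per-row variances by ``h - 1`` (columns) and per-column
    variances by ``w - 1`` (rows).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("matrix must be a nonempty 2-D array")
    w, h = m.shape  # w rows, h columns
    if h < 2:
        raise DegenerateDimensionError("row variance needs >= 2 columns")
    if w < 2:
        raise DegenerateDimensionError("column variance needs >= 2 rows")
    return {
        "mean": float(m.mean()),
        "variance": float(m.var(ddof=1)),
        "row_var_mean": float(m.var(axis=1, ddof=1).mean()),
        "col_var_mean": float(m.var(axis=0, ddof=1).mean()),
        "range": float(m.max() - m.min()),
        "median": float(np.median(m)),
        "row_median_mean": float(np.median(m, axis=1).mean()),
        "col_median_mean": float(np.median(m, axis=0).mean()),
    }


def quantize(matrix: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin 0-255 intensities into ``levels`` gray levels (0-based)."""
    m = np.asarray(matrix)
    return np.minimum((m.astype(np.int64) * levels) // 256, levels - 1)


def compute_glcm(
    matrix: np.ndarray, angle: int, distance: int, config: GlcmConfig | None = None
) -> Glcm:
    """Symmetric gray-level co-occurrence matrix for one angle/distance.

    Pixels are quantized to ``config.levels`` uniform bins over [0, 255];
    ordered pixel pairs separated by the angle's offset at the given
    distance are counted in both directions, producing a symmetric count
    matrix, normalized to probabilities when ``config.normalize``.
    """
    config = config or GlcmConfig()
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    if distance <= 0:
        raise ValueError("distance must be positive")
    q = quantize(matrix, config.levels)
    rows, cols = q.shape
    dr, dc = (o * distance for o in _ANGLE_OFFSETS[angle])
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    if r0 >= r1 or c0 >= c1:
        raise NoPairsError(
            f"no pixel pairs at angle {angle} deg, distance {distance} "
            f"in a {rows}x{cols} patch"
        )
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(
        a * config.levels + b, minlength=config.levels**2
    ).reshape(config.levels, config.levels)
    counts = counts + counts.T  # both directions of the offset
    P = counts.astype(float)
    if config.normalize:
        P = P / P.sum()
    return Glcm(
        P=P,
        levels=config.levels,
        angle=angle,
        distance=distance,
        normalized=config.normalize,
    )


def glcm_features(glcm: Glcm) -> dict[str, float]:
    """ASM, contrast, correlation, homogeneity and dissimilarity of a GLCM.

    Requires a normalized matrix.  Correlation is undefined when either
    marginal standard deviation vanishes (a constant patch); that is raised
    as :class:`UndefinedCorrelationError` rather than returning a number.
    """
    base = glcm_features_no_correlation(glcm)
    p = glcm.P
    idx = np.arange(1, glcm.levels + 1, dtype=float)
    mu_x, mu_y, sigma_x, sigma_y = glcm.marginal_moments()
    if sigma_x * sigma_y <= 0.0:
        raise UndefinedCorrelationError(
            "correlation undefined: a marginal standard deviation is zero"
        )
    correlation = float(
        ((idx[:, None] * idx[None, :] * p).sum() - mu_x * mu_y) / (sigma_x * sigma_y)
    )
    return {
        "asm": base["asm"],
        "contrast": base["contrast"],
        "correlation": correlation,
        "homogeneity": base["homogeneity"],
        "dissimilarity": base["dissimilarity"],
    }


def glcm_features_no_correlation(glcm: Glcm) -> dict[str, float]:
    """The four always-defined texture statistics (correlation omitted)."""
    if not glcm.normalized:
        raise ValueError("requires a normalized GLCM")
    p = glcm.P
    idx = np.arange(1, glcm.levels + 1, dtype=float)
    diff = idx[:, None] - idx[None, :]
    return {
        "asm": float((p**2).sum()),
        "contrast": float(((diff**2) * p).sum()),
        "homogeneity": float((p / (1.0 + diff**2)).sum()),
        "dissimilarity": float((np.abs(diff) * p).sum()),
    }


def roi_feature_names(roi: str, config: GlcmConfig | None = None) -> list[str]:
    """The 88 canonical feature names of one ROI, in order."""
    config = config or GlcmConfig()
    names = [f"{roi}.{stat}" for stat in STAT_NAMES]
    for stat in GLCM_STAT_NAMES:
        for angle in config.angles:
            for distance in config.distances:
                names.append(f"{roi}.{stat}.a{angle}.d{distance}")
    return names


def feature_schema(config: GlcmConfig | None = None) -> list[str]:
    """All 440 canonical feature names: 88 per ROI in fixed ROI order."""
    config = config or GlcmConfig()
    names: list[str] = []
    for roi in ROI_NAMES:
        names.extend(roi_feature_names(roi, config))
    return names


@dataclass
class FeatureVector:
    """The ordered, named feature set for one frame.

    ``values`` holds every canonical feature; entries that could not be
    computed (an ROI smaller than a co-occurrence distance, or a degenerate
    correlation) are NaN and listed in ``missing``.
    """

    values: dict[str, float]
    missing: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else list(self.values)
        return np.array([self.values[n] for n in names], dtype=float)


def extract_table(
    sessions,
    config: GlcmConfig | None = None,
) -> "pd.DataFrame":
    """Feature table over preprocessed sessions: one row per frame.

    ``sessions`` is an iterable of objects with ``participant``,
    ``condition``, ``patches`` (per-frame ROI dicts) and optional
    ``valence``/``arousal`` attributes (e.g. a ``PreprocessedSession``
    zipped with session metadata).  Frames with any uncomputable feature
    are dropped with a logged warning rather than silently zero-filled.
    """
    import pandas as pd

    config = config or GlcmConfig()
    names = feature_schema(config)
    rows = []
    n_dropped = 0
    for session in sessions:
        valence = getattr(session, "valence", None)
        arousal = getattr(session, "arousal", None)
        for frame_index, patches in enumerate(session.patches):
            vector = frame_features(patches, config)
            if vector.missing:
                n_dropped += 1
                logger.warning(
                    "dropping frame %s/%s #%d: %d uncomputable feature(s), e.g. %s",
                    session.participant,
                    session.condition,
                    frame_index,
                    len(vector.missing),
                    vector.missing[0],
                )
                continue
            row = {
                "participant": session.participant,
                "condition": session.condition,
                "frame_index": frame_index,
                "valence": valence,
                "arousal": arousal,
            }
            row.update(vector.values)
            rows.append(row)
    if n_dropped:
        logger.warning("dropped %d frame(s) with missing features", n_dropped)
    return pd.DataFrame(rows, columns=["participant", "condition", "frame_index", "valence", "arousal"] + names)


def frame_features(
    patches: dict[str, RoiPatch] | list[RoiPatch], config: GlcmConfig | None = None
) -> FeatureVector:
    """Assemble the 440-entry feature vector for one frame.

    Expects exactly the five canonical ROI patches.  Texture statistics are
    computed on normalized GLCMs regardless of ``config.normalize`` (counts
    are an export option, not a statistics input).
    """
    config = config or GlcmConfig()
    if isinstance(patches, list):
        patches = {p.name: p for p in patches}
    if sorted(patches) != sorted(ROI_NAMES):
        raise ValueError(
            f"expected exactly ROIs {sorted(ROI_NAMES)}, got {sorted(patches)}"
        )
    norm_config = GlcmConfig(
        levels=config.levels,
        distances=config.distances,
        angles=config.angles,
        normalize=True,
    )
    values: dict[str, float] = {}
    missing: list[str] = []
    for roi in ROI_NAMES:
        matrix = patches[roi].matrix
        for stat, value in stat_features(matrix).items():
            values[f"{roi}.{stat}"] = value
        glcm_stats: dict[tuple[int, int], dict[str, float]] = {}
        for angle in config.angles:
            for distance in config.distances:
                try:
                    glcm = compute_glcm(matrix, angle, distance, norm_config)
                except NoPairsError:
                    glcm_stats[(angle, distance)] = {}
                    continue
                try:
                    glcm_stats[(angle, distance)] = glcm_features(glcm)
                except UndefinedCorrelationError:
                    # Only the correlation entry is missing for this cell.
                    cell = glcm_features_no_correlation(glcm)
                    glcm_stats[(angle, distance)] = cell
        for stat in GLCM_STAT_NAMES:
            for angle in config.angles:
                for distance in config.distances:
                    name = f"{roi}.{stat}.a{angle}.d{distance}"
                    cell = glcm_stats[(angle, distance)]
                    if stat in cell:
                        values[name] = cell[stat]
                    else:
                        values[name] = float("nan")
                        missing.append(name)
    return FeatureVector(values=values, missing=tuple(missing))
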