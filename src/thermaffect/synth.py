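"""Synthetic facial-thermogram cohorts with planted, recoverable effects.

Real facial infrared recordings of study participants are private, so the
pipeline is exercised on synthetic cohorts that emulate the acquisition
protocol: a 2-minute resting baseline (~30 frames at one frame per 4 s) and
four 5-minute website-interaction sessions (~75 frames each) per participant,
8-bit grayscale frames, small rigid head motion, additive sensor noise, and
per-ROI mean-intensity shifts whose directions follow the reported facial
thermal trends (left cheek warms under positive and cools under negative
experiences; nose and maxillary cool under both; forehead warms under
negative experiences).

Every sampled quantity is recorded in a :class:`GroundTruth` sidecar so the
preprocessing, feature and selection stages can be tested against known
answers.  Generation is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ThermaffectError
from ._imageops import apply_rigid
from .types import (
    BASELINE,
    CONDITIONS,
    ROI_NAMES,
    TASK_CONDITIONS,
    Rect,
    RigidTransform,
    ThermalFrame,
)

#: Background (non-face) gray level of synthetic frames.
BACKGROUND_LEVEL = 30

#: Default planted per-ROI mean shifts, in gray levels.  Directions follow
#: the reported trends; the +/-10 magnitude is a documented package choice
#: sized for comfortable recovery (the source trends are directional only).
_POSITIVE_EFFECT = {
    "forehead": 0.0,
    "left_cheek": 10.0,
    "right_cheek": -8.0,
    "nose": -10.0,
    "maxillary": -10.0,
}
_NEGATIVE_EFFECT = {
    "forehead": 10.0,
    "left_cheek": -10.0,
    "right_cheek": -8.0,
    "nose": -10.0,
    "maxillary": -10.0,
}
DEFAULT_ROI_EFFECTS: dict[str, dict[str, float]] = {
    BASELINE: {name: 0.0 for name in ROI_NAMES},
    "U+A+": dict(_POSITIVE_EFFECT),
    "U+A-": dict(_POSITIVE_EFFECT),
    "U-A+": dict(_NEGATIVE_EFFECT),
    "U-A-": dict(_NEGATIVE_EFFECT),
}

#: Default SAM valence distributions per website condition.  High-usability
#: (U+) websites draw valence >= 3, low-usability (U-) websites < 3, so the
#: valence -> label rule downstream always recovers the intended polarity.
DEFAULT_VALENCE_RULE: dict[str, dict[int, float]] = {
    "U+A+": {4: 0.3, 5: 0.7},
    "U+A-": {3: 0.25, 4: 0.5, 5: 0.25},
    "U-A+": {1: 0.1, 2: 0.9},
    "U-A-": {1: 0.4, 2: 0.6},
}

#: Arousal barely differed between conditions in the emulated protocol: one
#: shared distribution centred between 3 and 4.
DEFAULT_AROUSAL_RULE: dict[str, dict[int, float]] = {
    cond: {2: 0.15, 3: 0.35, 4: 0.35, 5: 0.15} for cond in TASK_CONDITIONS
}

#: ROI placement ratios relative to the face box:
#: ``(center_row_frac, center_col_frac, height_frac_of_D, width_frac_of_D)``.
#: The centre fractions are relative to box height/width; sizes are
#: multiples of the face width D.
DEFAULT_ROI_RATIOS: dict[str, tuple[float, float, float, float]] = {
    "forehead": (0.15, 0.50, 0.15, 0.40),
    "left_cheek": (0.55, 0.25, 0.20, 0.20),
    "right_cheek": (0.55, 0.75, 0.20, 0.20),
    "nose": (0.50, 0.50, 0.20, 0.15),
    "maxillary": (0.80, 0.50, 0.15, 0.30),
}


def roi_rects_from_geometry(
    bbox: Rect,
    face_width: float,
    ratio_table: dict[str, tuple[float, float, float, float]],
) -> dict[str, Rect]:
    """Place ROI rectangles inside ``bbox`` according to a ratio table.

    Each rectangle is centred at the box-relative fractional position and
    sized as a fraction of the face width ``D``, then clipped to the box.
    """
    rects: dict[str, Rect] = {}
    for name, (rf, cf, hf, wf) in ratio_table.items():
        h = max(1, int(round(hf * face_width)))
        w = max(1, int(round(wf * face_width)))
        cr = bbox.top + rf * bbox.height
        cc = bbox.left + cf * bbox.width
        top = int(round(cr - h / 2.0))
        left = int(round(cc - w / 2.0))
        rect = Rect(top, left, top + h, left + w).clip_to(bbox)
        if rect.is_empty():
            raise ThermaffectError(f"ROI {name!r} is empty after clipping to the face box")
        rects[name] = rect
    return rects


@dataclass
class SynthConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated acquisition protocol: 24 participants, a
    2-minute baseline (30 frames) and 5-minute tasks (75 frames) at one
    frame per 4 s, modest sensor noise and small unrestrained head motion.
    """

    n_participants: int = 24
    face_size: tuple[int, int] = (160, 160)
    baseline_frames: int = 30
    task_frames: int = 75
    frame_interval: float = 4.0  # seconds; metadata only
    roi_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_ROI_EFFECTS.items()}
    )
    noise_sd: float = 2.0
    motion_max_translation: float = 3.0
    motion_max_rotation: float = 2.0
    valence_rule: dict[str, dict[int, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_VALENCE_RULE.items()}
    )
    arousal_rule: dict[str, dict[int, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_AROUSAL_RULE.items()}
    )
    roi_ratio_table: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_RATIOS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.baseline_frames < 1 or self.task_frames < 1:
            raise ValueError("frame counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.motion_max_translation < 0 or self.motion_max_rotation < 0:
            raise ValueError("motion bounds must be >= 0")
        rows, cols = self.face_size
        if rows < 64 or cols < 64:
            raise ValueError("face_size must be at least 64x64 to hold the face model")
        # Fails loudly if the configured frame cannot contain all five ROIs.
        bbox, width = _face_box(self.face_size)
        rects = roi_rects_from_geometry(bbox, width, self.roi_ratio_table)
        missing = set(ROI_NAMES) - set(rects)
        if missing:
            raise ValueError(f"roi_ratio_table missing ROIs: {sorted(missing)}")

    @property
    def participants(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_participants)]


@dataclass
class GroundTruth:
    """Everything that was sampled while generating one session."""

    condition: str
    transforms: list[RigidTransform]
    roi_rects: dict[str, Rect]
    face_bbox: Rect
    face_width: float
    eye_centers: tuple[tuple[float, float], tuple[float, float]]
    template: np.ndarray | None = None
    valence: int | None = None
    arousal: int | None = None

    def __post_init__(self) -> None:
        if set(self.roi_rects) != set(ROI_NAMES):
            raise ValueError("ground truth must record exactly the 5 canonical ROIs")


@dataclass
class Session:
    """One recording session: frames plus metadata and ground truth."""

    participant: str
    condition: str
    frames: list[ThermalFrame]
    truth: GroundTruth | None = None
    valence: int | None = None
    arousal: int | None = None


@dataclass
class Cohort:
    """All sessions of a synthetic study."""

    config: SynthConfig
    sessions: list[Session]

    def for_participant(self, participant: str) -> list[Session]:
        return [s for s in self.sessions if s.participant == participant]

    @property
    def participants(self) -> list[str]:
        seen: list[str] = []
        for s in self.sessions:
            if s.participant not in seen:
                seen.append(s.participant)
        return seen


def _face_box(face_size: tuple[int, int]) -> tuple[Rect, int]:
    """Nominal face bounding box and face width D for a frame size."""
    rows, cols = face_size
    height = int(round(0.875 * rows))
    width = int(round(0.75 * cols))
    top = (rows - height) // 2
    left = (cols - width) // 2
    return Rect(top, left, top + height, left + width), width


def face_template(
    config: SynthConfig, participant: str
) -> tuple[np.ndarray, Rect, int, tuple[tuple[float, float], tuple[float, float]], dict[str, Rect]]:
    """Build the per-participant face template.

    The template is a bright ellipse on a dark background with a smooth
    radial gradient, a faint participant-specific sinusoidal texture, and
    two hot eye blobs in the upper half — enough structure for Otsu
    binarization, eye-centroid registration and co-occurrence statistics to
    have real work to do.  Deterministic in ``(config.seed, participant)``.
    """
    rng = np.random.default_rng([config.seed, zlib.crc32(participant.encode())])
    rows, cols = config.face_size
    bbox, width = _face_box(config.face_size)
    height = bbox.height
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    a, b = height / 2.0, width / 2.0

    rr, ccol = np.mgrid[0:rows, 0:cols]
    e2 = ((rr - cr) / a) ** 2 + ((ccol - cc) / b) ** 2
    inside = e2 <= 1.0

    base_level = 150.0 + rng.uniform(-8.0, 8.0)
    phase_r, phase_c = rng.uniform(0, 2 * np.pi, size=2)
    img = np.full((rows, cols), float(BACKGROUND_LEVEL))
    texture = 4.0 * np.sin(2 * np.pi * rr / 23.0 + phase_r) + 4.0 * np.sin(
        2 * np.pi * ccol / 17.0 + phase_c
    )
    img[inside] = base_level + 25.0 * (1.0 - e2[inside]) + texture[inside]

    eye_row = bbox.top + 0.30 * height + rng.uniform(-1.0, 1.0)
    eye_cols = (
        bbox.left + 0.30 * width + rng.uniform(-2.0, 2.0),
        bbox.left + 0.70 * width + rng.uniform(-2.0, 2.0),
    )
    eyes = ((eye_row, eye_cols[0]), (eye_row, eye_cols[1]))
    for er, ec in eyes:
        img += 95.0 * np.exp(-((rr - er) ** 2 + (ccol - ec) ** 2) / (2 * 3.0**2))

    template = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    rects = roi_rects_from_geometry(bbox, width, config.roi_ratio_table)
    return template, bbox, width, eyes, rects


def generate_session(
    config: SynthConfig, participant: str, condition: str, seed: int
) -> tuple[list[ThermalFrame], GroundTruth]:
    """Generate one session: frames plus the ground truth that produced them.

    Each frame is the participant template plus the condition's planted ROI
    deltas, additive Gaussian sensor noise (rounded and clipped to [0, 255])
    and an independent rigid head motion sampled uniformly within the
    configured bounds, applied with nearest-neighbour resampling.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = np.random.default_rng(seed)
    template, bbox, width, eyes, rects = face_template(config, participant)

    effects = config.roi_effects.get(condition, {})
    unknown = set(effects) - set(ROI_NAMES)
    if unknown:
        raise ValueError(f"roi_effects for {condition!r} has unknown ROIs: {sorted(unknown)}")
    base = template.astype(float)
    for name, delta in effects.items():
        rect = rects[name]
        expected = float(template[rect.slice()].mean()) + delta
        if not 0.0 <= expected <= 255.0:
            raise ThermaffectError(
                f"planted delta {delta:+g} pushes expected {name} mean to "
                f"{expected:.1f}, outside [0, 255]"
            )
        rs, cs = rect.slice()
        base[rs, cs] += delta

    valence = arousal = None
    if condition != BASELINE:
        valence = _draw_rating(rng, config.valence_rule.get(condition))
        arousal = _draw_rating(rng, config.arousal_rule.get(condition))

    n_frames = config.baseline_frames if condition == BASELINE else config.task_frames
    frames: list[ThermalFrame] = []
    transforms: list[RigidTransform] = []
    for i in range(n_frames):
        img = base
        if config.noise_sd > 0:
            img = base + rng.normal(0.0, config.noise_sd, base.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        dx = dy = theta = 0.0
        if config.motion_max_translation > 0:
            dx, dy = rng.uniform(
                -config.motion_max_translation, config.motion_max_translation, size=2
            )
        if config.motion_max_rotation > 0:
            theta = float(
                rng.uniform(-config.motion_max_rotation, config.motion_max_rotation)
            )
        if dx or dy or theta:
            img = apply_rigid(img, dx, dy, theta, cval=BACKGROUND_LEVEL)
        frames.append(ThermalFrame(img, participant, condition, i))
        transforms.append(RigidTransform(dx=float(dx), dy=float(dy), theta=theta))

    truth = GroundTruth(
        condition=condition,
        transforms=transforms,
        roi_rects=rects,
        face_bbox=bbox,
        face_width=float(width),
        eye_centers=eyes,
        template=template,
        valence=valence,
        arousal=arousal,
    )
    return frames, truth


def _draw_rating(rng: np.random.Generator, rule: dict[int, float] | None) -> int:
    if not rule:
        raise ThermaffectError("no SAM rating distribution configured for this condition")
    values = sorted(rule)
    if any(not 1 <= v <= 5 for v in values):
        raise ValueError("SAM ratings must be integers in 1..5")
    probs = np.array([rule[v] for v in values], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(values, p=probs))


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate the full study: one baseline + four website sessions each.

    Deterministic in ``(config, config.seed)``; per-session seeds are spawned
    from the cohort seed so sessions are independent but reproducible.
    """
    sessions: list[Session] = []
    for p_idx, participant in enumerate(config.participants):
        for c_idx, condition in enumerate(CONDITIONS):
            seed = int(
                np.random.SeedSequence([config.seed, p_idx, c_idx]).generate_state(1)[0]
                % (2**31)
            )
            frames, truth = generate_session(config, participant, condition, seed)
            sessions.append(
                Session(
                    participant=participant,
                    condition=condition,
                    frames=frames,
                    truth=truth,
                    valence=truth.valence,
                    arousal=truth.arousal,
                )
            )
    return Cohort(config=config, sessions=sessions)


# ---------------------------------------------------------------------------
# Disk layout: 8-bit PNG frames + session metadata CSV + ground-truth JSON.

def _rect_json(rect: Rect) -> list[int]:
    return [rect.top, rect.left, rect.bottom, rect.right]


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write frames as PNGs plus ``sessions.csv`` and truth JSON sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for session in cohort.sessions:
        stem = f"P{session.participant}_{session.condition}"
        for frame in session.frames:
            iio.imwrite(outdir / f"{stem}_{frame.frame_index:04d}.png", frame.pixels)
        rows.append(
            {
                "participant": session.participant,
                "condition": session.condition,
                "valence": session.valence,
                "arousal": session.arousal,
                "n_frames": len(session.frames),
            }
        )
        if session.truth is not None:
            t = session.truth
            payload = {
                "condition": t.condition,
                "valence": t.valence,
                "arousal": t.arousal,
                "face_bbox": _rect_json(t.face_bbox),
                "face_width": t.face_width,
                "eye_centers": [list(e) for e in t.eye_centers],
                "roi_rects": {k: _rect_json(v) for k, v in t.roi_rects.items()},
                "transforms": [asdict(tr) for tr in t.transforms],
            }
            (outdir / f"{stem}_truth.json").write_text(json.dumps(payload))
    pd.DataFrame(rows).to_csv(outdir / "sessions.csv", index=False)
    return outdir


def load_cohort(indir: str | Path) -> list[Session]:
    """Load sessions written by :func:`write_cohort` (truth left on disk)."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "sessions.csv")
    sessions: list[Session] = []
    for row in meta.itertuples(index=False):
        participant = str(row.participant)
        stem = f"P{participant}_{row.condition}"
        frames = []
        for i in range(int(row.n_frames)):
            pixels = iio.imread(indir / f"{stem}_{i:04d}.png")
            frames.append(ThermalFrame(pixels, participant, str(row.condition), i))
        valence = None if pd.isna(row.valence) else int(row.valence)
        arousal = None if pd.isna(row.arousal) else int(row.arousal)
        sessions.append(
            Session(
                participant=participant,
                condition=str(row.condition),
                frames=frames,
                valence=valence,
                arousal=arousal,
            )
        )
    return sessions
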