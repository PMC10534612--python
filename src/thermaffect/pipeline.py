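"""End-to-end study runner: frames -> features -> selection -> evaluation.

This module wires the stage modules into the full cross-subject analysis:

1. register, denoise and ROI-locate every session (reference: the
   participant's first baseline frame);
2. extract the 440-entry feature table, one row per frame;
3. optionally exclude high-head-motion participants;
4. split participants into contiguous groups (last participant of each
   group is the test subject);
5. per task and group: z-score with training statistics, select the top-k
   features by NCA weight on the training rows, grid-search a Gaussian
   SVM, and evaluate on the held-out participant's frames;
6. run the ROI grayscale trend analysis over all kept participants.

Leakage discipline: the normalizer, the NCA weights and the SVM
hyperparameters are all fit on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, report, select
from .errors import ThermaffectError
from .features import GlcmConfig, extract_table, feature_schema
from .preprocess import PreprocessedSession, detect_eye_centroids, preprocess_session
from .synth import BACKGROUND_LEVEL, Cohort, Session
from .types import BASELINE, ROI_NAMES

logger = logging.getLogger(__name__)

#: Number of features kept per task after NCA ranking.
DEFAULT_TOP_K = 15


@dataclass
class _SessionBundle:
    """A preprocessed session with the metadata the feature table needs."""

    participant: str
    condition: str
    valence: int | None
    arousal: int | None
    patches: list
    transforms: list
    processed: PreprocessedSession


@dataclass
class StudyResult:
    """Everything a study run produces."""

    features: pd.DataFrame
    split: classify.SplitPlan
    eval_tables: dict[str, pd.DataFrame]
    reports: dict[str, list[classify.EvalReport]]
    selected: dict[str, list[list[str]]]
    trends: pd.DataFrame | None
    excluded: list[str] = field(default_factory=list)
    group_labels: list[str] = field(default_factory=list)

    def mean_metric(self, metric: str, task: str) -> float:
        return float(self.eval_tables[metric].loc["Mean", task])


def preprocess_cohort(
    sessions: list[Session],
    roi_ratio_table=None,
    median_window: int = 3,
    gaussian_sigma: float = 1.0,
) -> list[_SessionBundle]:
    """Register and ROI-locate every session of a cohort.

    The registration reference for all of a participant's sessions is the
    first frame of their baseline session; its eye centroids are detected
    once and reused.
    """
    by_participant: dict[str, list[Session]] = {}
    for session in sessions:
        by_participant.setdefault(session.participant, []).append(session)

    bundles: list[_SessionBundle] = []
    for participant, plist in by_participant.items():
        baselines = [s for s in plist if s.condition == BASELINE]
        if not baselines:
            raise ThermaffectError(f"participant {participant} has no baseline session")
        reference = baselines[0].frames[0]
        ref_eyes = detect_eye_centroids(reference)
        for session in plist:
            processed = preprocess_session(
                session.frames,
                reference=reference,
                roi_ratio_table=roi_ratio_table,
                median_window=median_window,
                gaussian_sigma=gaussian_sigma,
                reference_eyes=ref_eyes,
                fill_value=BACKGROUND_LEVEL,
            )
            bundles.append(
                _SessionBundle(
                    participant=session.participant,
                    condition=session.condition,
                    valence=session.valence,
                    arousal=session.arousal,
                    patches=processed.patches,
                    transforms=processed.transforms,
                    processed=processed,
                )
            )
    return bundles


def roi_mean_rows(bundles: list[_SessionBundle]) -> pd.DataFrame:
    """Per-frame per-ROI mean gray levels with participant/state labels."""
    rows = []
    for bundle in bundles:
        state = classify.state_of(bundle.condition, bundle.valence)
        for patches in bundle.patches:
            for roi in ROI_NAMES:
                rows.append(
                    {
                        "participant": bundle.participant,
                        "state": state,
                        "roi": roi,
                        "mean_gray": float(patches[roi].matrix.mean()),
                    }
                )
    return pd.DataFrame(rows)


def _subsample_indices(
    index: np.ndarray, strata: np.ndarray, max_samples: int
) -> np.ndarray:
    """Deterministic stratified thinning: evenly spaced frames per stratum."""
    if len(index) <= max_samples:
        return index
    keep: list[np.ndarray] = []
    unique = np.unique(strata)
    quota = max(2, max_samples // len(unique))
    for stratum in unique:
        members = index[strata == stratum]
        if len(members) <= quota:
            keep.append(members)
        else:
            pos = np.linspace(0, len(members) - 1, quota).round().astype(int)
            keep.append(members[np.unique(pos)])
    return np.concatenate(keep)


def run_task_group(
    features: pd.DataFrame,
    feature_names: list[str],
    task: str,
    train_participants: list[str],
    test_participants: list[str],
    k: int = DEFAULT_TOP_K,
    nca_max_samples: int = 150,
    nca_max_iter: int = 75,
    kernel_scale_grid=classify.DEFAULT_KERNEL_SCALE_GRID,
    cost_grid=classify.DEFAULT_COST_GRID,
    seed: int = 0,
) -> tuple[classify.EvalReport, list[str]]:
    """Train and evaluate one task on one cross-subject group.

    Returns the held-out evaluation and the selected feature names.
    """
    pos_state, neg_state = classify.TASKS[task]
    rows = features[features["state"].isin([pos_state, neg_state])]
    train = rows[rows["participant"].isin(train_participants)]
    test = rows[rows["participant"].isin(test_participants)]
    if len(train) == 0 or len(test) == 0:
        raise ThermaffectError(f"task {task}: empty train or test rows")

    X_cols = list(feature_names)
    variances = train[X_cols].var(ddof=1)
    usable = [c for c in X_cols if variances[c] > 0 and np.isfinite(variances[c])]
    dropped = sorted(set(X_cols) - set(usable))
    if dropped:
        logger.warning("task %s: dropping %d zero-variance feature(s)", task, len(dropped))

    normalizer = classify.fit_normalizer(train[usable])
    X_train = normalizer.apply(train[usable]).to_numpy()
    X_test = normalizer.apply(test[usable]).to_numpy()
    y_train = train["state"].to_numpy()
    y_test = test["state"].to_numpy()
    groups_train = train["participant"].to_numpy()

    sub = _subsample_indices(
        np.arange(len(X_train)),
        np.char.add(groups_train.astype(str), y_train.astype(str)),
        nca_max_samples,
    )
    nca = select.fit_nca(
        X_train[sub],
        y_train[sub],
        groups=groups_train[sub],
        feature_names=usable,
        max_iter=nca_max_iter,
        seed=seed,
    )
    chosen = select.top_k(nca, min(k, len(usable)))
    col_idx = [usable.index(c) for c in chosen]

    model, _ = classify.train_svm(
        X_train[:, col_idx],
        y_train,
        kernel_scale_grid=kernel_scale_grid,
        cost_grid=cost_grid,
        seed=seed,
    )
    y_pred = model.predict(X_test[:, col_idx])
    return classify.evaluate(y_test, y_pred, positive_label=pos_state), chosen


def run_study(
    cohort: Cohort | list[Session],
    tasks: tuple[str, ...] = ("P-Base", "N-Base", "P-N"),
    n_groups: int = 4,
    k: int = DEFAULT_TOP_K,
    glcm_config: GlcmConfig | None = None,
    roi_ratio_table=None,
    motion_exclusion_threshold: float | None = None,
    nca_max_samples: int = 150,
    nca_max_iter: int = 75,
    with_trends: bool = True,
    seed: int = 0,
) -> StudyResult:
    """Run the full cross-subject analysis on a cohort of sessions."""
    sessions = cohort.sessions if isinstance(cohort, Cohort) else cohort
    glcm_config = glcm_config or GlcmConfig()

    bundles = preprocess_cohort(sessions, roi_ratio_table=roi_ratio_table)

    excluded: list[str] = []
    if motion_exclusion_threshold is not None:
        transforms: dict[str, list] = {}
        for bundle in bundles:
            transforms.setdefault(bundle.participant, []).extend(bundle.transforms)
        kept, excluded = classify.exclude_high_motion(
            transforms, motion_exclusion_threshold
        )
        bundles = [b for b in bundles if b.participant in kept]

    features = extract_table(bundles, glcm_config)
    features["state"] = [
        classify.state_of(c, v if pd.notna(v) else None)
        for c, v in zip(features["condition"], features["valence"])
    ]
    names = feature_schema(glcm_config)

    participants = list(dict.fromkeys(b.participant for b in bundles))
    split = classify.make_split(participants, n_groups)

    reports: dict[str, list[classify.EvalReport]] = {t: [] for t in tasks}
    selected: dict[str, list[list[str]]] = {t: [] for t in tasks}
    group_labels = [", ".join(g["train"] + g["test"]) for g in split]
    for task in tasks:
        for group in split:
            result, chosen = run_task_group(
                features,
                names,
                task,
                group["train"],
                group["test"],
                k=k,
                nca_max_samples=nca_max_samples,
                nca_max_iter=nca_max_iter,
                seed=seed,
            )
            reports[task].append(result)
            selected[task].append(chosen)

    eval_tables: dict[str, pd.DataFrame] = {}
    for metric in ("accuracy", "precision", "recall", "f1"):
        table = pd.DataFrame(
            {
                task: [getattr(r, metric) for r in reports[task]]
                for task in tasks
            },
            index=group_labels,
        )
        table.loc["Mean"] = table.mean()
        eval_tables[metric] = table

    trends = None
    if with_trends:
        means = report.state_mean_table(roi_mean_rows(bundles))
        trends = report.roi_trends(means)

    return StudyResult(
        features=features,
        split=split,
        eval_tables=eval_tables,
        reports=reports,
        selected=selected,
        trends=trends,
        excluded=excluded,
        group_labels=group_labels,
    )
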