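"""Labels, z-scoring, cross-subject splits, SVM and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from thermaffect import (
    EvalReport,
    evaluate,
    exclude_high_motion,
    fit_normalizer,
    label_from_valence,
    make_split,
    train_svm,
)
from thermaffect.classify import state_of
from thermaffect.errors import ZeroVarianceError
from thermaffect.pipeline import run_task_group
from thermaffect.types import RigidTransform


# --- labels ---------------------------------------------------------------

@pytest.mark.parametrize(
    "valence, expected",
    [(1, "negative"), (2, "negative"), (3, "positive"), (4, "positive"), (5, "positive")],
)
def test_valence_label_rule(valence, expected):
    assert label_from_valence(valence) == expected


def test_valence_out_of_range_rejected():
    for bad in (0, 6, -1):
        with pytest.raises(ValueError):
            label_from_valence(bad)


def test_state_of_baseline_ignores_valence():
    assert state_of("baseline", None) == "baseline"
    with pytest.raises(ValueError):
        state_of("U+A+", None)


# --- normalization --------------------------------------------------------

def test_normalizer_z_scores_training_columns():
    train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 30.0, 20.0]})
    normalizer = fit_normalizer(train)
    z = normalizer.apply(train)
    np.testing.assert_allclose(z.mean(), 0.0, atol=1e-10)
    np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-10)
    np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])


def test_normalizer_uses_training_statistics_on_test_rows():
    train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    test = pd.DataFrame({"a": [4.0]})
    z = fit_normalizer(train).apply(test)
    assert z["a"].iloc[0] == pytest.approx((4.0 - 2.0) / 1.0)


def test_normalizer_rejects_constant_feature_by_name():
    train = pd.DataFrame({"ok": [1.0, 2.0], "flat": [5.0, 5.0]})
    with pytest.raises(ZeroVarianceError, match="flat"):
        fit_normalizer(train)


# --- cross-subject splitting ---------------------------------------------

def test_split_23_participants_into_4_groups():
    participants = [f"S{i}" for i in range(1, 24)]
    plan = make_split(participants, 4)
    sizes = [len(g["train"]) + len(g["test"]) for g in plan]
    assert sizes == [6, 6, 6, 5]
    tests = [g["test"][0] for g in plan]
    assert len(tests) == 4
    for group in plan:
        assert group["test"][0] == (group["train"] + group["test"])[-1]
        assert not set(group["train"]) & set(group["test"])


def test_split_single_group_is_5_to_1():
    plan = make_split([f"S{i}" for i in range(6)], 1)
    assert len(plan) == 1
    assert len(plan.groups[0]["train"]) == 5
    assert len(plan.groups[0]["test"]) == 1


def test_split_rejects_degenerate_groups():
    with pytest.raises(ValueError):
        make_split(["S1", "S2"], 0)
    with pytest.raises(ValueError):
        make_split(["S1"], 2)
    with pytest.raises(ValueError):
        make_split(["S1", "S2"], 2)  # would leave a group with no train side


def test_split_membership_independent_of_frame_order():
    """The plan is a function of participant order only, never of frames."""
    participants = [f"S{i}" for i in range(1, 13)]
    plan_a = make_split(participants, 2)
    plan_b = make_split(participants, 2)
    assert plan_a.groups == plan_b.groups


# --- motion exclusion -----------------------------------------------------

def test_high_motion_participant_excluded():
    still = [RigidTransform(0.2, 0.1, 0.0)] * 5
    mover = [RigidTransform(4.0, 3.0, 1.0)] * 5
    kept, excluded = exclude_high_motion({"S1": still, "S2": mover}, 2.0)
    assert kept == ["S1"]
    assert excluded == ["S2"]


# --- SVM ------------------------------------------------------------------

def test_svm_separable_training_accuracy_is_one(rng):
    X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
    y = np.array(["neg"] * 30 + ["pos"] * 30)
    model, best = train_svm(X, y, seed=0)
    assert (model.predict(X) == y).all()
    assert best["kernel_scale"] > 0 and best["C"] > 0


def test_svm_grid_search_is_deterministic(rng):
    X = rng.normal(size=(40, 3))
    y = np.where(X[:, 0] + 0.5 * rng.normal(size=40) > 0, "a", "b")
    _, best_a = train_svm(X, y, seed=7)
    _, best_b = train_svm(X, y, seed=7)
    assert best_a == best_b


def test_svm_rejects_single_class():
    with pytest.raises(ValueError):
        train_svm(np.zeros((5, 2)), np.array(["a"] * 5))


# --- evaluation metrics ---------------------------------------------------

def test_metrics_from_confusion_counts():
    y_true = ["p"] * 5 + ["n"] * 5
    y_pred = ["p", "p", "p", "n", "n", "p", "n", "n", "n", "n"]
    rep = evaluate(y_true, y_pred, positive_label="p")
    assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 2, 4)
    assert rep.accuracy == pytest.approx(0.7)
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.6)
    assert rep.f1 == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6))
    assert rep.f1 == pytest.approx(0.6667, abs=5e-5)


def test_metrics_perfect_and_all_wrong():
    perfect = evaluate(["p", "n"], ["p", "n"], "p")
    assert (perfect.accuracy, perfect.precision, perfect.recall, perfect.f1) == (1, 1, 1, 1)
    wrong = evaluate(["p", "n"], ["n", "p"], "p")
    assert wrong.accuracy == 0.0
    assert wrong.f1 == 0.0


def test_metrics_degenerate_denominators_report_zero():
    rep = evaluate(["n", "n"], ["n", "n"], positive_label="p")
    assert rep.precision == 0.0 and rep.recall == 0.0 and rep.f1 == 0.0
    assert rep.accuracy == 1.0
    with pytest.raises(ValueError):
        evaluate([], [], "p")


# --- leakage discipline ---------------------------------------------------

def _toy_feature_table(rng, participants, n_frames=12):
    names = [f"feat{i:02d}" for i in range(10)]
    rows = []
    for p_idx, participant in enumerate(participants):
        for state, shift in (("baseline", 0.0), ("positive", 2.5)):
            for i in range(n_frames):
                values = rng.normal(size=10)
                values[3] += shift  # informative feature
                rows.append(
                    {"participant": participant, "state": state,
                     **dict(zip(names, values))}
                )
    return pd.DataFrame(rows), names


def test_selected_features_depend_only_on_training_rows(rng):
    """Swapping the held-out participant never changes fitted parameters."""
    participants = [f"S{i}" for i in range(1, 8)]
    table, names = _toy_feature_table(rng, participants)
    train = participants[:5]
    _, chosen_a = run_task_group(
        table, names, "P-Base", train, [participants[5]], k=3,
        nca_max_samples=60, nca_max_iter=30, seed=0,
    )
    _, chosen_b = run_task_group(
        table, names, "P-Base", train, [participants[6]], k=3,
        nca_max_samples=60, nca_max_iter=30, seed=0,
    )
    assert chosen_a == chosen_b
    assert "feat03" in chosen_a
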