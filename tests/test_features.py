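"""Statistical and GLCM texture features against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from thermaffect import (
    GlcmConfig,
    compute_glcm,
    feature_schema,
    frame_features,
    glcm_features,
    stat_features,
)
from thermaffect.errors import (
    DegenerateDimensionError,
    NoPairsError,
    UndefinedCorrelationError,
)
from thermaffect.features import (
    GLCM_STAT_NAMES,
    STAT_NAMES,
    Glcm,
    roi_feature_names,
)
from thermaffect.types import ROI_NAMES, Rect, RoiPatch

from oracles import glcm_brute_force, texture_stats_brute_force


def _random_symmetric_glcm(rng, levels):
    """A random normalized symmetric GLCM with non-degenerate marginals."""
    C = rng.integers(0, 10, (levels, levels)).astype(float)
    P = C + C.T
    if P.sum() == 0:
        P[0, 1] = P[1, 0] = 1.0
    P[0, 1] += 1.0
    P[1, 0] += 1.0
    return Glcm(P=P / P.sum(), levels=levels, angle=0, distance=1, normalized=True)


# --- statistical features ------------------------------------------------

@pytest.mark.parametrize(
    "matrix, expected",
    [
        (
            np.full((4, 4), 100.0),
            {
                "mean": 100, "variance": 0, "row_var_mean": 0, "col_var_mean": 0,
                "range": 0, "median": 100, "row_median_mean": 100, "col_median_mean": 100,
            },
        ),
        (
            np.array([[0.0, 255.0], [255.0, 0.0]]),
            {"mean": 127.5, "range": 255, "median": 127.5},
        ),
        (
            np.arange(1.0, 10.0).reshape(3, 3),
            {"mean": 5.0, "variance": 7.5, "row_var_mean": 1.0, "col_var_mean": 9.0,
             "range": 8, "median": 5.0, "row_median_mean": 5.0, "col_median_mean": 5.0},
        ),
    ],
)
def test_stat_features_known_values(matrix, expected):
    result = stat_features(matrix)
    assert list(result) == list(STAT_NAMES)
    for name, value in expected.items():
        assert result[name] == pytest.approx(value)


def test_stat_features_degenerate_dimensions():
    with pytest.raises(DegenerateDimensionError):
        stat_features(np.ones((1, 5)))  # single row: column variance undefined
    with pytest.raises(DegenerateDimensionError):
        stat_features(np.ones((5, 1)))  # single column: row variance undefined
    with pytest.raises(ValueError):
        stat_features(np.empty((0, 0)))


# --- co-occurrence matrices ----------------------------------------------

@pytest.mark.parametrize("angle", [0, 45, 90, 135])
@pytest.mark.parametrize("distance", [1, 2])
def test_glcm_matches_brute_force(rng, angle, distance):
    for _ in range(10):
        shape = rng.integers(3, 9, size=2)
        matrix = rng.integers(0, 256, shape)
        config = GlcmConfig(levels=4, normalize=False)
        expected = glcm_brute_force(matrix, angle, distance, 4)
        if expected.sum() == 0:
            with pytest.raises(NoPairsError):
                compute_glcm(matrix, angle, distance, config)
        else:
            result = compute_glcm(matrix, angle, distance, config)
            np.testing.assert_array_equal(result.P, expected)


def test_glcm_constant_matrix_single_entry():
    glcm = compute_glcm(np.full((6, 6), 200), 0, 2, GlcmConfig(levels=8))
    level = (200 * 8) // 256
    assert glcm.P[level, level] == pytest.approx(1.0)
    assert glcm.P.sum() == pytest.approx(1.0)


def test_glcm_vertical_stripes_all_same_level_pairs():
    """Period-2 stripes sampled at distance 2 only pair equal levels."""
    stripes = np.tile(np.array([0, 255, 0, 255]), (4, 1))
    glcm = compute_glcm(stripes, 0, 2, GlcmConfig(levels=2))
    assert glcm.P[0, 0] + glcm.P[1, 1] == pytest.approx(1.0)
    assert glcm.P[0, 1] == 0 and glcm.P[1, 0] == 0


def test_glcm_no_pairs_raises():
    with pytest.raises(NoPairsError):
        compute_glcm(np.ones((4, 4)), 0, 10, GlcmConfig(levels=4))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    matrix=arrays(np.uint8, (6, 7), elements=st.integers(0, 255)),
    angle=st.sampled_from([0, 45, 90, 135]),
    distance=st.sampled_from([1, 2, 3]),
)
def test_glcm_symmetric_and_normalized(matrix, angle, distance):
    glcm = compute_glcm(matrix, angle, distance, GlcmConfig(levels=8))
    np.testing.assert_allclose(glcm.P, glcm.P.T, atol=0)
    assert glcm.P.sum() == pytest.approx(1.0, abs=1e-12)


# --- texture statistics ---------------------------------------------------

def test_glcm_stats_constant_image_values_and_correlation_error():
    P = np.zeros((4, 4))
    P[2, 2] = 1.0
    glcm = Glcm(P=P, levels=4, angle=0, distance=1, normalized=True)
    with pytest.raises(UndefinedCorrelationError):
        glcm_features(glcm)
    from thermaffect.features import glcm_features_no_correlation

    stats = glcm_features_no_correlation(glcm)
    assert stats["asm"] == 1.0
    assert stats["contrast"] == 0.0
    assert stats["homogeneity"] == 1.0
    assert stats["dissimilarity"] == 0.0


def test_uniform_glcm_has_zero_correlation():
    P = np.full((2, 2), 0.25)
    glcm = Glcm(P=P, levels=2, angle=0, distance=1, normalized=True)
    assert glcm_features(glcm)["correlation"] == pytest.approx(0.0, abs=1e-12)


def test_texture_stats_match_double_sum_oracle(rng):
    for levels in (2, 4, 6):
        for _ in range(5):
            glcm = _random_symmetric_glcm(rng, levels)
            expected = texture_stats_brute_force(glcm.P)
            result = glcm_features(glcm)
            for name in GLCM_STAT_NAMES:
                assert result[name] == pytest.approx(expected[name], abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(matrix=arrays(np.uint8, (8, 8), elements=st.integers(0, 255)))
def test_texture_stat_ranges(matrix):
    glcm = compute_glcm(matrix, 45, 1, GlcmConfig(levels=8))
    stats = glcm_features(glcm) if _has_correlation(glcm) else None
    from thermaffect.features import glcm_features_no_correlation

    base = glcm_features_no_correlation(glcm)
    assert 0 < base["asm"] <= 1
    assert 0 < base["homogeneity"] <= 1
    assert base["dissimilarity"] >= 0
    # zero dissimilarity iff zero contrast: both measure off-diagonal mass
    assert (base["dissimilarity"] == 0) == (base["contrast"] == 0)
    if stats is not None:
        assert -1 - 1e-9 <= stats["correlation"] <= 1 + 1e-9


def _has_correlation(glcm):
    _, _, sx, sy = glcm.marginal_moments()
    return sx * sy > 0


# --- frame assembly -------------------------------------------------------

def _patches_from_truth(truth):
    return {
        name: RoiPatch(name=name, rect=rect, matrix=truth.template[rect.slice()])
        for name, rect in truth.roi_rects.items()
    }


def test_frame_vector_schema_and_composition(baseline_session):
    _, truth = baseline_session
    patches = _patches_from_truth(truth)
    vector = frame_features(patches)
    schema = feature_schema()
    assert list(vector.values) == schema
    assert len(vector) == 440
    assert not vector.missing
    # each ROI block equals the stage functions called directly
    forehead = patches["forehead"].matrix
    stats = stat_features(forehead)
    for stat, value in stats.items():
        assert vector.values[f"forehead.{stat}"] == value
    glcm = compute_glcm(forehead, 45, 4, GlcmConfig())
    direct = glcm_features(glcm)
    for stat in GLCM_STAT_NAMES:
        assert vector.values[f"forehead.{stat}.a45.d4"] == direct[stat]


def test_identical_pixels_identical_vectors(baseline_session):
    _, truth = baseline_session
    patches = _patches_from_truth(truth)
    va = frame_features(patches)
    vb = frame_features({k: RoiPatch(k, p.rect, p.matrix.copy()) for k, p in patches.items()})
    assert va.values == vb.values


def test_missing_and_duplicate_rois_rejected(baseline_session):
    _, truth = baseline_session
    patches = _patches_from_truth(truth)
    del patches["nose"]
    with pytest.raises(ValueError, match="exactly"):
        frame_features(patches)


def test_small_patch_records_missing_not_zero(rng):
    """ROIs smaller than a distance yield NaN entries flagged as missing."""
    patches = {}
    for i, name in enumerate(ROI_NAMES):
        rect = Rect(0, 0, 6, 6)
        patches[name] = RoiPatch(name, rect, rng.integers(0, 256, (6, 6)))
    vector = frame_features(patches, GlcmConfig(distances=(2, 16)))
    assert vector.missing
    for name in vector.missing:
        assert ".d16" in name
        assert np.isnan(vector.values[name])
    d2 = [n for n in vector.values if n.endswith(".d2")]
    assert all(np.isfinite(vector.values[n]) for n in d2)


def test_schema_counts():
    config = GlcmConfig()
    assert len(feature_schema(config)) == 440
    names = roi_feature_names("nose", config)
    assert len(names) == 88
    assert sum(1 for n in names if n.count(".") == 1) == 8
    for stat in GLCM_STAT_NAMES:
        assert sum(1 for n in names if f".{stat}." in n) == 16
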