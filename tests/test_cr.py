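"""Conventional-radiomics extractors against brute-force oracles."""

import numpy as np
import pytest

from oracles import (first_order_brute, glcm_brute, glrlm_brute, glzlm_brute,
                     ngldm_brute, random_roi)
from slnrad.cr import (default_catalog, extract_cr_vector, extract_first_order,
                       extract_glcm, extract_glrlm, extract_glzlm, extract_laws,
                       extract_ngldm, extract_shape, glcm_matrix, glrlm_matrix,
                       glzlm_matrix, laws_filter_bank, ngldm_vectors)
from slnrad.features import build_feature_table
from slnrad.kinetics import compute_kinetic_maps
from slnrad.regions import build_peritumoral_ring

SEEDS = range(10)


# -- shape -------------------------------------------------------------------

def test_cube_shape_features():
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[2:6, 2:6, 2:6] = True
    vals = extract_shape(mask, (1.0, 1.0, 1.0))
    assert vals["extent"] == pytest.approx(1.0)
    assert vals["volume"] == pytest.approx(64.0)
    assert vals["compacity"] == pytest.approx(1.0 / vals["sphericity"])


def test_ball_extent_near_analytic():
    # half-integer radius so the discrete bounding box spans exactly 2r voxels
    r = 10.5
    ax = np.arange(-14, 15)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    ball = x * x + y * y + z * z <= r * r
    vals = extract_shape(ball, (1.0, 1.0, 1.0))
    assert vals["extent"] == pytest.approx(np.pi / 6, rel=0.05)
    with pytest.raises(ValueError):
        extract_shape(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


def test_shape_ignores_intensities(small_cohort):
    _, studies, _ = small_cohort
    s = studies[0]
    v1 = extract_shape(s.intratumoral_mask, s.spacing)
    v2 = extract_shape(s.intratumoral_mask.copy(), s.spacing)
    assert v1 == v2


# -- first order -------------------------------------------------------------

def test_first_order_degenerate_and_two_level():
    const = np.full((3, 3, 3), 4, dtype=np.int64)
    roi = np.ones((3, 3, 3), dtype=bool)
    vals = extract_first_order(const, roi)
    assert vals["variance"] == 0.0
    assert vals["entropy_log2"] == 0.0
    two = np.array([0, 1] * 4).reshape(2, 2, 2)
    vals2 = extract_first_order(two, np.ones((2, 2, 2), dtype=bool))
    assert vals2["entropy_log2"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        extract_first_order(np.array([[[1]]]), np.ones((1, 1, 1), dtype=bool))


@pytest.mark.parametrize("seed", SEEDS)
def test_first_order_matches_direct_summation(seed):
    rng = np.random.default_rng(seed)
    levels, roi = random_roi(rng)
    if roi.sum() < 2:
        roi[:] = True
    got = extract_first_order(levels, roi)
    expect = first_order_brute(levels, roi)
    for k, v in expect.items():
        assert got[k] == pytest.approx(v, abs=1e-12), k


# -- matrix families vs oracles ----------------------------------------------

@pytest.mark.parametrize("seed", SEEDS)
def test_glcm_matrix_equals_pair_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    levels, roi = random_roi(rng)
    got = glcm_matrix(levels, roi)
    expect = glcm_brute(levels, roi)
    assert got.shape == expect.shape
    np.testing.assert_allclose(got, expect, atol=1e-12)
    assert got.sum() == pytest.approx(1.0)


def test_glcm_degenerate_cases():
    const = np.zeros((2, 2, 2), dtype=np.int64)
    vals = extract_glcm(const, np.ones((2, 2, 2), dtype=bool))
    assert vals["entropy_log2"] == 0.0
    assert vals["energy"] == pytest.approx(1.0)
    pair = np.array([[[0], [1]]]).reshape(1, 1, 2)
    vals2 = extract_glcm(pair, np.ones((1, 1, 2), dtype=bool))
    assert vals2["entropy_log2"] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", SEEDS)
def test_ngldm_vectors_equal_neighborhood_averaging(seed):
    rng = np.random.default_rng(200 + seed)
    levels, roi = random_roi(rng)
    p, s = ngldm_vectors(levels, roi)
    pe, se = ngldm_brute(levels, roi)
    np.testing.assert_allclose(p, pe, atol=1e-12)
    np.testing.assert_allclose(s, se, atol=1e-10)


def test_ngldm_constant_region():
    const = np.ones((3, 3, 3), dtype=np.int64)
    vals = extract_ngldm(const, np.ones((3, 3, 3), dtype=bool))
    assert vals["contrast"] == 0.0
    assert vals["coarseness"] == pytest.approx(1e6)  # 1/eps guard


@pytest.mark.parametrize("seed", SEEDS)
def test_glrlm_matrix_equals_line_scanning(seed):
    rng = np.random.default_rng(300 + seed)
    levels, roi = random_roi(rng)
    got = glrlm_matrix(levels, roi)
    expect = glrlm_brute(levels, roi)
    np.testing.assert_allclose(got[:, : expect.shape[1]], expect, atol=1e-12)
    assert got[:, expect.shape[1]:].sum() == 0


def test_glrlm_single_voxel_and_line():
    one = np.zeros((1, 1, 1), dtype=np.int64)
    vals = extract_glrlm(one, np.ones((1, 1, 1), dtype=bool))
    assert vals["rp"] == pytest.approx(1.0)
    line = np.zeros((1, 1, 4), dtype=np.int64)
    mat = glrlm_matrix(line, np.ones((1, 1, 4), dtype=bool))
    assert mat[0, 3] == 1  # one run of length 4 along the line's axis


@pytest.mark.parametrize("seed", SEEDS)
def test_glzlm_matrix_equals_flood_fill(seed):
    rng = np.random.default_rng(400 + seed)
    levels, roi = random_roi(rng)
    got = glzlm_matrix(levels, roi)
    expect = glzlm_brute(levels, roi)
    np.testing.assert_allclose(got[:, : expect.shape[1]], expect, atol=1e-12)


def test_glzlm_zone_semantics():
    const = np.zeros((2, 3, 1), dtype=np.int64)
    vals = extract_glzlm(const, np.ones((2, 3, 1), dtype=bool))
    assert vals["zp"] == pytest.approx(1.0 / 6.0)
    blobs = np.zeros((7, 1, 1), dtype=np.int64)
    roi = np.ones((7, 1, 1), dtype=bool)
    blobs[3] = 1  # separates two zero-level zones
    mat = glzlm_matrix(blobs, roi)
    assert mat[0].sum() == 2


# -- Laws --------------------------------------------------------------------

def test_laws_bank_shape_and_constants():
    bank = laws_filter_bank()
    assert len(bank) == 25
    assert bank[0].sum() == pytest.approx(256.0)  # sum(L5)^2
    for k in range(1, 25):
        assert bank[k].sum() == pytest.approx(0.0)


def test_laws_on_constant_image():
    img = np.full((20, 20, 1), 3.0)
    roi = np.zeros((20, 20, 1), dtype=bool)
    roi[8:12, 8:12, 0] = True  # interior: zero padding never reaches the ROI
    vals = extract_laws(img, roi)
    assert vals["laws_energy_1"] == pytest.approx((256.0 * 3.0) ** 2)
    for k in range(2, 26):
        assert vals[f"laws_energy_{k}"] == pytest.approx(0.0, abs=1e-18)
        assert vals[f"laws_skewness_{k}"] == 0.0


def test_laws_energy_matches_direct_convolution(rng):
    img = rng.normal(size=(16, 16, 2))
    roi = np.zeros((16, 16, 2), dtype=bool)
    roi[4:12, 4:12, :] = True
    vals = extract_laws(img, roi, filters=(7,))
    from scipy.ndimage import convolve

    bank = laws_filter_bank()
    pooled = np.concatenate([
        convolve(img[:, :, z], bank[6], mode="constant")[roi[:, :, z]]
        for z in range(2)
    ])
    assert vals["laws_energy_7"] == pytest.approx(np.mean(pooled ** 2))


# -- catalog + subject-level row ---------------------------------------------

def test_default_catalog_counts_match_model_inputs():
    assert len(default_catalog("intra_only")) == 93
    assert len(default_catalog("intra_peri")) == 146


def test_catalog_json_roundtrip():
    from slnrad.cr import FeatureCatalog

    cat = default_catalog("intra_peri")
    again = FeatureCatalog.from_json(cat.to_json())
    assert again.names == cat.names


def test_peritumoral_has_no_shape_features():
    cat = default_catalog("intra_peri")
    assert not any(d.family == "shape" and d.region == "peritumoral"
                   for d in cat.definitions)
    assert all(d.name.startswith("CR:") for d in cat.definitions)


def test_cr_vector_schema_stable_and_compositional(small_cohort):
    _, studies, _ = small_cohort
    cat = default_catalog("intra_peri")
    rows = []
    for s in studies[:2]:
        maps = compute_kinetic_maps(s)
        rois = build_peritumoral_ring(s.intratumoral_mask, s.spacing)
        rows.append(extract_cr_vector(s, maps, rois, cat))
    assert set(rows[0]) == set(rows[1])
    assert len(rows[0]) == 146
    # compositional consistency: row values equal direct family calls
    s = studies[0]
    maps = compute_kinetic_maps(s)
    rois = build_peritumoral_ring(s.intratumoral_mask, s.spacing)
    shape_direct = extract_shape(s.intratumoral_mask, s.spacing)
    assert rows[0]["CR:intratumoral:shape:extent"] == shape_direct["extent"]
    from slnrad.kinetics import (DEFAULT_WINDOWS, QuantizationSpec,
                                 apply_window, quantize)
    w = DEFAULT_WINDOWS[("wash_out", "intratumoral")]
    q = quantize(apply_window(maps.wash_out, w), QuantizationSpec(w))
    glcm_direct = extract_glcm(q, rois.intratumoral)
    assert rows[0]["CR:intratumoral:wash_out:glcm_entropy_log2"] == \
        glcm_direct["entropy_log2"]


def test_rotation_invariance_of_aggregated_textures(rng):
    """90-degree in-plane rotation leaves direction-pooled GLCM/GLRLM alone."""
    levels = rng.integers(0, 5, size=(7, 7, 3)).astype(np.int64)
    roi = np.ones((7, 7, 3), dtype=bool)
    rot_levels = np.rot90(levels, axes=(0, 1)).copy()
    for fn in (extract_glcm, extract_glrlm):
        a = fn(levels, roi)
        b = fn(rot_levels, roi)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-10), (fn.__name__, k)


def test_intra_only_table_has_no_peritumoral_columns(small_cohort):
    _, studies, _ = small_cohort
    table, _ = build_feature_table(studies[:2], "CR", analysis="intra_only")
    assert not any(":peritumoral:" in c for c in table.columns)
    assert table.shape[1] == 93 + 11
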