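"""Gaussian-filterbank read/write attention: examples, crop-limit oracle,
adjointness and pose-mapping contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ocra.autodiff import Tensor
from ocra.attention import (
    AttentionPose,
    build_filters,
    pose_from_raw,
    pose_from_hidden,
    read,
    write,
    retroject_coverage,
)
from ocra.nn import Linear


def make_pose(cx, cy, stride, var):
    return AttentionPose(Tensor(float(cx)), Tensor(float(cy)),
                         Tensor(float(stride)), Tensor(float(var)))


def crop_oracle(image, N, center_y, center_x):
    """Direct N×N crop whose filter centers are mu_i = center + (i - N/2 - 0.5).

    Caller must pick centers so the mu are integers inside the image
    (half-integer centers for even N); coordinates are 1-based.
    """
    mu_y = center_y + (np.arange(1, N + 1) - N / 2 - 0.5)
    mu_x = center_x + (np.arange(1, N + 1) - N / 2 - 0.5)
    ry = np.round(mu_y).astype(int) - 1
    rx = np.round(mu_x).astype(int) - 1
    return image[np.ix_(ry, rx)]


# ------------------------------------------------------------- pose mapping
def test_zero_raw_pose_is_centered_full_span():
    pose = pose_from_raw(Tensor(np.zeros(4)), grid_size=18, image_shape=(36, 36))
    assert pose.center_x.data == pytest.approx(18.5)
    assert pose.center_y.data == pytest.approx(18.5)
    assert pose.stride.data == pytest.approx(35.0 / 17.0)
    assert pose.variance.data == pytest.approx(1.0)


def test_stride_raw_plus_one_multiplies_by_e():
    p0 = pose_from_raw(Tensor(np.zeros(4)), 18, (36, 36))
    p1 = pose_from_raw(Tensor(np.array([0.0, 0.0, 1.0, 0.0])), 18, (36, 36))
    assert p1.stride.data == pytest.approx(np.e * p0.stride.data)


@given(st.lists(st.floats(-20, 20), min_size=4, max_size=4))
@settings(max_examples=50, deadline=None)
def test_any_finite_raw_gives_valid_pose(raw):
    pose = pose_from_raw(Tensor(np.array(raw)), 18, (36, 36))
    assert pose.variance.data > 0
    assert pose.stride.data >= 0


def test_pose_rejects_nonfinite():
    with pytest.raises(ValueError):
        pose_from_raw(Tensor(np.array([np.nan, 0, 0, 0])), 18, (36, 36))
    rng = np.random.default_rng(0)
    proj = Linear(8, 4, rng)
    with pytest.raises(ValueError):
        pose_from_hidden(Tensor(np.full(8, np.inf)), proj, 18, (36, 36))


def test_pose_projection_must_output_four_values():
    rng = np.random.default_rng(0)
    proj = Linear(8, 5, rng)
    with pytest.raises(ValueError):
        pose_from_hidden(Tensor(np.zeros(8)), proj, 18, (36, 36))


# ----------------------------------------------------------------- filters
def test_rows_sum_to_one():
    # centers on-image: the eps-floored normalizer is then negligible
    pose = make_pose(17.0, 20.0, 1.7, 2.3)
    grid = build_filters(pose, 18, (36, 36))
    np.testing.assert_allclose(grid.row_filters.data.sum(-1), 1.0, atol=1e-6)
    np.testing.assert_allclose(grid.col_filters.data.sum(-1), 1.0, atol=1e-6)
    assert grid.row_filters.data.min() >= 0


def test_vanishing_variance_gives_one_hot_rows():
    pose = make_pose(18.5, 18.5, 1.0, 1e-6)  # half-integer center, even N
    grid = build_filters(pose, 18, (36, 36))
    for f in (grid.row_filters.data, grid.col_filters.data):
        assert np.allclose(f.max(axis=-1), 1.0, atol=1e-4)
        hot = np.argmax(f, axis=-1)
        onehot = np.zeros_like(f)
        onehot[np.arange(18), hot] = 1.0
        np.testing.assert_allclose(f, onehot, atol=1e-4)


def test_single_filter_grid_centered():
    pose = make_pose(7.0, 11.0, 99.0, 0.5)  # stride irrelevant at N=1
    grid = build_filters(pose, 1, (20, 20))
    assert np.argmax(grid.col_filters.data[0]) == 6   # 1-based col 7
    assert np.argmax(grid.row_filters.data[0]) == 10  # 1-based row 11


def test_build_filters_rejects_bad_dims():
    pose = make_pose(5, 5, 1, 1)
    with pytest.raises(ValueError):
        build_filters(pose, 0, (10, 10))
    with pytest.raises(ValueError):
        build_filters(pose, 4, (0, 10))


# ---------------------------------------------------------------- read/write
def test_read_constant_image_gives_constant_glimpse(rng):
    pose = make_pose(13.0, 22.0, 1.3, 4.0)
    grid = build_filters(pose, 12, (36, 36))
    g = read(np.full((36, 36), 0.7), grid)
    np.testing.assert_allclose(g.data, 0.7, atol=1e-5)


def test_read_crop_limit_matches_oracle(rng):
    img = rng.random((36, 36))
    # even N: half-integer centers put filter centers on pixels
    pose = make_pose(17.5, 20.5, 1.0, 1e-6)
    grid = build_filters(pose, 18, (36, 36))
    g = read(img, grid).data
    expected = crop_oracle(img, 18, 20.5, 17.5)
    np.testing.assert_allclose(g, expected, atol=1e-4)


def test_read_is_linear(rng):
    pose = make_pose(15.0, 15.0, 2.0, 3.0)
    grid = build_filters(pose, 10, (30, 30))
    x1, x2 = rng.random((30, 30)), rng.random((30, 30))
    lhs = read(2.0 * x1 + 3.0 * x2, grid).data
    rhs = 2.0 * read(x1, grid).data + 3.0 * read(x2, grid).data
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_read_rejects_shape_mismatch(rng):
    grid = build_filters(make_pose(5, 5, 1, 1), 6, (20, 20))
    with pytest.raises(ValueError):
        read(rng.random((21, 20)), grid)
    with pytest.raises(ValueError):
        write(rng.random((7, 7)), grid)


def test_write_zero_patch_zero_increment():
    grid = build_filters(make_pose(5, 5, 1, 1), 6, (20, 20))
    np.testing.assert_array_equal(write(np.zeros((6, 6)), grid).data, 0.0)


def test_write_one_hot_places_ones_on_crop(rng):
    pose = make_pose(10.5, 12.5, 1.0, 1e-6)
    grid = build_filters(pose, 8, (30, 30))
    inc = write(np.ones((8, 8)), grid).data
    expected = np.zeros((30, 30))
    mu_y = (12.5 + (np.arange(1, 9) - 4.5)).astype(int) - 1
    mu_x = (10.5 + (np.arange(1, 9) - 4.5)).astype(int) - 1
    expected[np.ix_(mu_y, mu_x)] = 1.0
    np.testing.assert_allclose(inc, expected, atol=1e-4)


def test_adjointness_random_poses(rng):
    for _ in range(100):
        pose = make_pose(rng.uniform(-5, 40), rng.uniform(-5, 40),
                         rng.uniform(0.1, 4.0), rng.uniform(0.1, 9.0))
        grid = build_filters(pose, 9, (27, 31))
        x = rng.random((27, 31))
        p = rng.random((9, 9))
        lhs = float((write(p, grid).data * x).sum())
        rhs = float((p * read(x, grid).data).sum())
        assert lhs == pytest.approx(rhs, abs=1e-5)


@given(cx=st.floats(8, 29), cy=st.floats(8, 29),
       stride=st.floats(0.05, 1.3), var=st.floats(0.05, 16.0))
@settings(max_examples=40, deadline=None)
def test_row_stochastic_property(cx, cy, stride, var):
    # filter centers stay on-image; sums are then 1 to well within 1e-6
    grid = build_filters(make_pose(cx, cy, stride, var), 12, (36, 36))
    np.testing.assert_allclose(grid.row_filters.data.sum(-1), 1.0, atol=1e-6)
    np.testing.assert_allclose(grid.col_filters.data.sum(-1), 1.0, atol=1e-6)


def test_offimage_rows_still_normalized_bounded():
    # far off-image pose: the eps floor keeps rows finite and sub-stochastic
    grid = build_filters(make_pose(-40.0, -40.0, 1.0, 1.0), 12, (36, 36))
    s = grid.row_filters.data.sum(-1)
    assert np.all(np.isfinite(grid.row_filters.data))
    assert np.all(s <= 1.0 + 1e-12)


# ----------------------------------------------------------------- coverage
def test_coverage_one_hot_is_crop_indicator():
    pose = make_pose(10.5, 12.5, 1.0, 1e-6)
    grid = build_filters(pose, 8, (30, 30))
    cov = retroject_coverage(grid).data
    assert set(np.round(np.unique(cov), 3)) <= {0.0, 1.0}
    assert cov.sum() == pytest.approx(64, abs=1e-2)


def test_coverage_wide_variance_positive_everywhere():
    grid = build_filters(make_pose(18, 18, 2.0, 200.0), 18, (36, 36))
    cov = retroject_coverage(grid).data
    assert cov.min() > 0
    assert cov.max() == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------- gradients
def test_pose_gradients_finite(rng):
    raw = Tensor(rng.normal(0, 1, 4), requires_grad=True)
    pose = pose_from_raw(raw, 8, (24, 24))
    grid = build_filters(pose, 8, (24, 24))
    img = rng.random((24, 24))
    loss = (read(img, grid) ** 2).sum() + (write(rng.random((8, 8)), grid) ** 2).sum()
    loss.backward()
    assert np.all(np.isfinite(raw.grad))
    assert np.abs(raw.grad).sum() > 0
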