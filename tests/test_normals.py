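"""Radial projection and per-frame aggregation: examples, oracle
equivalence against a naive double loop, and the exact invariants."""

import math

import numpy as np
import pytest

import leafflow as lf
from conftest import naive_radial_projection


def _field(u, v):
    return lf.FlowField(u=np.asarray(u, float), v=np.asarray(v, float))


def _roi(mask, center):
    mask = np.asarray(mask, bool)
    return lf.PlantROI(center=center, radius=max(mask.shape), mask=mask)


def _random_case(rng, h=8, w=8):
    u = rng.normal(size=(h, w))
    v = rng.normal(size=(h, w))
    mask = rng.random((h, w)) > 0.3
    center = (rng.uniform(0, w - 1), rng.uniform(0, h - 1))
    return _field(u, v), _roi(mask, center)


class TestRadialProjection:
    def test_tangential_flow_projects_to_zero(self):
        h = w = 9
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        dx, dy = xs - 4, ys - 4
        nf = lf.radial_projection(_field(-dy, dx), _roi(np.ones((h, w)), (4, 4)))
        assert np.allclose(nf.nx, 0) and np.allclose(nf.ny, 0)
        assert np.all(nf.sign == 0)

    def test_pixel_right_of_center(self):
        u = np.zeros((3, 3)); v = np.zeros((3, 3))
        u[1, 2], v[1, 2] = 1.0, 1.0  # p = (1, 1) at the pixel right of center
        mask = np.zeros((3, 3), bool); mask[1, 2] = True
        nf = lf.radial_projection(_field(u, v), _roi(mask, (1, 1)))
        assert nf.nx[1, 2] == pytest.approx(1.0)
        assert nf.ny[1, 2] == pytest.approx(0.0)
        assert nf.sign[1, 2] == 1

    def test_center_pixel_has_no_radial_direction(self):
        u = np.ones((3, 3)); mask = np.ones((3, 3), bool)
        nf = lf.radial_projection(_field(u, u), _roi(mask, (1, 1)))
        assert nf.nx[1, 1] == 0 and nf.ny[1, 1] == 0 and nf.sign[1, 1] == 0

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            field, roi = _random_case(rng)
            nf = lf.radial_projection(field, roi)
            agg = lf.aggregate_frame(nf)
            nx, ny, sign, total, m = naive_radial_projection(
                field.u, field.v, roi.mask, roi.center)
            np.testing.assert_allclose(nf.nx, nx, atol=1e-12)
            np.testing.assert_allclose(nf.ny, ny, atol=1e-12)
            np.testing.assert_array_equal(nf.sign, sign)
            np.testing.assert_allclose(agg.n_sum, total, atol=1e-10)
            assert agg.s == m


class TestAggregation:
    def test_single_pixel_aggregate(self):
        u = np.zeros((2, 2)); v = np.zeros((2, 2))
        u[0, 1], v[0, 1] = 3.0, 4.0
        mask = np.zeros((2, 2), bool); mask[0, 1] = True
        nf = lf.NormalField(nx=u, ny=v, sign=np.sign(u).astype(np.int8),
                            mask=mask, center=(0, 0))
        agg = lf.aggregate_frame(nf, frame_index=5)
        assert agg.n_sum == (3.0, 4.0) and agg.n_mean == (3.0, 4.0)
        assert agg.magnitude == pytest.approx(5.0)
        assert agg.theta == pytest.approx(math.atan2(4, 3))
        assert agg.s == 1 and agg.frame_index == 5

    def test_cancellation_gives_zero_magnitude_undefined_angle(self):
        nx = np.array([[1.0, -1.0]]); ny = np.zeros((1, 2))
        nf = lf.NormalField(nx=nx, ny=ny, sign=np.sign(nx).astype(np.int8),
                            mask=np.ones((1, 2), bool), center=(0.5, 0))
        agg = lf.aggregate_frame(nf)
        assert agg.magnitude == 0.0 and math.isnan(agg.theta) and agg.s == 2

    def test_empty_mask_flags(self):
        nf = lf.NormalField(nx=np.zeros((2, 2)), ny=np.zeros((2, 2)),
                            sign=np.zeros((2, 2), np.int8),
                            mask=np.zeros((2, 2), bool), center=(1, 1))
        agg = lf.aggregate_frame(nf)
        assert agg.s == 0 and agg.magnitude == 0.0 and math.isnan(agg.theta)

    def test_symmetric_outward_annulus_cancels_but_moves(self):
        h = w = 21
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        dx, dy = xs - 10, ys - 10
        dist = np.hypot(dx, dy)
        mask = (dist >= 5) & (dist <= 8)
        with np.errstate(invalid="ignore"):
            u = np.where(dist > 0, dx / dist, 0)
            v = np.where(dist > 0, dy / dist, 0)
        nf = lf.radial_projection(_field(u, v), _roi(mask, (10, 10)))
        agg = lf.aggregate_frame(nf)
        mean_norm = np.hypot(nf.nx[mask], nf.ny[mask]).mean()
        assert agg.magnitude < 1e-10 and mean_norm == pytest.approx(1.0)


class TestSignMap:
    def test_outward_tangential_and_mixed_fractions(self):
        h = w = 11
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        dx, dy = xs - 5, ys - 5
        mask = np.hypot(dx, dy) > 0
        roi = _roi(mask, (5, 5))
        _, frac_out = lf.sign_map(lf.radial_projection(_field(dx, dy), roi))
        assert frac_out == 1.0
        _, frac_tan = lf.sign_map(lf.radial_projection(_field(-dy, dx), roi))
        assert frac_tan == 0.0

    def test_half_expanding_half_contracting(self):
        h = w = 21
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        dx, dy = xs - 10, ys - 10
        mask = np.hypot(dx, dy) > 0
        sign = np.where(xs >= 10, 1.0, -1.0)  # right half outward, left inward
        _, frac = lf.sign_map(
            lf.radial_projection(_field(sign * dx, sign * dy), _roi(mask, (10, 10))))
        assert frac == pytest.approx(0.5, abs=0.1)


class TestInvariants:
    def test_idempotence(self):
        rng = np.random.default_rng(1)
        field, roi = _random_case(rng)
        nf1 = lf.radial_projection(field, roi)
        nf2 = lf.radial_projection(_field(nf1.nx, nf1.ny), roi)
        np.testing.assert_allclose(nf2.nx, nf1.nx, atol=1e-12)
        np.testing.assert_allclose(nf2.ny, nf1.ny, atol=1e-12)

    def test_contraction(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            field, roi = _random_case(rng)
            nf = lf.radial_projection(field, roi)
            assert np.all(np.hypot(nf.nx, nf.ny) <= np.hypot(field.u, field.v) + 1e-12)

    def test_rotation_equivariance_exact(self):
        rng = np.random.default_rng(3)
        field, roi = _random_case(rng, 8, 8)
        agg = lf.aggregate_frame(lf.radial_projection(field, roi))
        # np.rot90 maps (x, y) -> (y, W-1-x); vectors (u, v) -> (v, -u)
        w = field.u.shape[1]
        rfield = _field(np.rot90(field.v), -np.rot90(field.u))
        rroi = _roi(np.rot90(roi.mask), (roi.center[1], w - 1 - roi.center[0]))
        ragg = lf.aggregate_frame(lf.radial_projection(rfield, rroi))
        assert ragg.s == agg.s
        assert ragg.magnitude == pytest.approx(agg.magnitude, abs=1e-12)
        assert ragg.n_mean[0] == pytest.approx(agg.n_mean[1], abs=1e-12)
        assert ragg.n_mean[1] == pytest.approx(-agg.n_mean[0], abs=1e-12)

    def test_linearity_under_nonnegative_scaling(self):
        rng = np.random.default_rng(4)
        field, roi = _random_case(rng)
        agg = lf.aggregate_frame(lf.radial_projection(field, roi))
        for alpha in (0.0, 0.5, 3.0):
            scaled = _field(alpha * field.u, alpha * field.v)
            sagg = lf.aggregate_frame(lf.radial_projection(scaled, roi))
            assert sagg.magnitude == pytest.approx(alpha * agg.magnitude, abs=1e-10)
            assert sagg.n_sum[0] == pytest.approx(alpha * agg.n_sum[0], abs=1e-9)

    def test_tidy_table_columns(self):
        rng = np.random.default_rng(5)
        aggs = []
        for k in (37, 38, 39):
            field, roi = _random_case(rng)
            aggs.append(lf.aggregate_frame(lf.radial_projection(field, roi), k))
        df = lf.aggregates_to_frame(aggs, plant_id=2)
        assert list(df.columns) == ["plant_id", "k", "t_hours", "Nx", "Ny",
                                    "magnitude", "theta", "S"]
        assert df["t_hours"].tolist() == [0.0, pytest.approx(1 / 3), pytest.approx(2 / 3)]
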