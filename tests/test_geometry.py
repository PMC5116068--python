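"""Geometry: site placement, periodic wrapping, the hard-overlap kernel."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chainstick.geometry import (Box, Cylinder, ModelParams, cylinders_overlap,
                                 folding_angle, minimum_image, site_positions)
from chainstick.model import GappedDuplex

from conftest import (cylinder_point_cloud, make_cylinder,
                      overlap_fraction_oracle, random_unit)


class TestSitePositions:
    def test_reference_offsets(self, params):
        """A at L/2 + 0.15 D/2, B at -(L/2 + sigma/2) along the axis."""
        c = make_cylinder([0, 0, 0], [0, 0, 1], params)
        a, b = site_positions(c, params)
        np.testing.assert_allclose(a, [0, 0, 8.225], atol=1e-12)
        np.testing.assert_allclose(b, [0, 0, -11.15], atol=1e-12)

    def test_axis_flip_negates_sites(self, params):
        c = make_cylinder([0, 0, 0], [0, 0, -1], params)
        a, b = site_positions(c, params)
        np.testing.assert_allclose(a, [0, 0, -8.225], atol=1e-12)
        np.testing.assert_allclose(b, [0, 0, 11.15], atol=1e-12)

    def test_rotation_equivariance(self, params, rng):
        """Sites of a rotated cylinder equal the rotated sites."""
        base = make_cylinder([0, 0, 0], [0, 0, 1], params)
        a0, b0 = site_positions(base, params)
        for _ in range(20):
            R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            c = make_cylinder(R @ base.com, R @ base.axis, params)
            a, b = site_positions(c, params)
            np.testing.assert_allclose(a, R @ a0, atol=1e-9)
            np.testing.assert_allclose(b, R @ b0, atol=1e-9)


class TestMinimumImage:
    def test_wraps_beyond_half_box(self):
        box = Box(np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(
            minimum_image(np.array([6.0, 0, 0]), box), [-4.0, 0, 0])

    def test_primary_cell_unchanged(self):
        box = Box(np.array([10.0, 20.0, 30.0]))
        dr = np.array([3.0, -9.0, 14.0])
        np.testing.assert_allclose(minimum_image(dr, box), dr)

    def test_norm_bound_and_idempotence(self, rng):
        box = Box(np.array([7.0, 11.0, 23.0]))
        dr = rng.uniform(-100, 100, size=(1000, 3))
        w = minimum_image(dr, box)
        assert np.all(np.linalg.norm(w, axis=1)
                      <= np.linalg.norm(box.edges / 2) + 1e-12)
        np.testing.assert_allclose(minimum_image(w, box), w, atol=1e-12)


class TestOverlapKernel:
    @pytest.mark.parametrize("dr, u2, expected", [
        ((2.9, 0, 0), (0, 0, 1), True),    # side-side, lateral < D
        ((3.05, 0, 0), (0, 0, 1), False),  # side-side, lateral > D
        ((0, 0, 16.1), (0, 0, 1), False),  # collinear, 0.1 nm end gap
        ((0, 0, 15.9), (0, 0, 1), True),   # collinear, ends interpenetrate
        ((0, 3.05, 0), (1, 0, 0), False),  # crossed, common perpendicular > D
        ((0, 2.9, 0), (1, 0, 0), True),    # crossed, within D
        ((9.45, 0, 0), (1, 0, 0), True),   # end cap pokes into lateral face
        ((9.55, 0, 0), (1, 0, 0), False),  # end cap just clear
    ])
    def test_reference_configurations(self, params, dr, u2, expected):
        c1 = make_cylinder([0, 0, 0], [0, 0, 1], params)
        c2 = make_cylinder(dr, u2, params)
        assert cylinders_overlap(c1, c2) is expected

    def test_agrees_with_point_sampling_oracle(self, params, rng):
        """Random oblique pairs: every overlap of volume > 1e-3 v0 found by
        uniform point sampling must be flagged by the kernel."""
        pts = cylinder_point_cloud(params, rng, 60_000)
        rmax = np.sqrt(params.L**2 + params.D**2)
        misses = 0
        substantial = 0
        for _ in range(1500):
            u1, u2 = random_unit(rng), random_unit(rng)
            dr = rng.normal(size=3)
            dr *= rng.uniform(0, rmax) / np.linalg.norm(dr)
            got = cylinders_overlap(make_cylinder([0, 0, 0], u1, params),
                                    make_cylinder(dr, u2, params))
            frac = overlap_fraction_oracle(pts, dr, u1, u2, params)
            if frac > 1e-3:
                substantial += 1
                if not got:
                    misses += 1
        assert substantial > 300  # the draw actually exercises overlaps
        assert misses == 0

    def test_symmetry(self, params, rng):
        for _ in range(300):
            u1, u2 = random_unit(rng), random_unit(rng)
            dr = rng.uniform(-1, 1, 3) * [5, 5, 18]
            a = cylinders_overlap(make_cylinder([0, 0, 0], u1, params),
                                  make_cylinder(dr, u2, params))
            b = cylinders_overlap(make_cylinder(dr, u2, params),
                                  make_cylinder([0, 0, 0], u1, params))
            assert a == b

    def test_spherocylinder_containment(self, params, rng):
        """Axis distance >= D implies no cylinder overlap, and the
        spherocylinder model is always at least as permissive."""
        for _ in range(500):
            u1, u2 = random_unit(rng), random_unit(rng)
            dr = rng.uniform(-1, 1, 3) * [6, 6, 18]
            c1 = make_cylinder([0, 0, 0], u1, params)
            c2 = make_cylinder(dr, u2, params)
            cyl = cylinders_overlap(c1, c2, overlap_model="cylinder")
            sph = cylinders_overlap(c1, c2, overlap_model="spherocylinder")
            if not sph:
                assert not cyl

    def test_rigid_motion_invariance(self, params, rng):
        for _ in range(100):
            u1, u2 = random_unit(rng), random_unit(rng)
            dr = rng.uniform(-1, 1, 3) * [4, 4, 17]
            before = cylinders_overlap(make_cylinder([0, 0, 0], u1, params),
                                       make_cylinder(dr, u2, params))
            R = Rotation.random(
                random_state=int(rng.integers(2**31))).as_matrix()
            t = rng.uniform(-50, 50, 3)
            after = cylinders_overlap(
                make_cylinder(R @ np.zeros(3) + t, R @ u1, params),
                make_cylinder(R @ dr + t, R @ u2, params))
            assert before == after

    def test_translation_mod_box(self, params, rng):
        box = Box(np.array([40.0, 40.0, 40.0]))
        for _ in range(100):
            u1, u2 = random_unit(rng), random_unit(rng)
            r1 = rng.uniform(0, 40, 3)
            dr = rng.uniform(-1, 1, 3) * [4, 4, 17]
            shift = rng.integers(-2, 3, 3) * box.edges + rng.uniform(-5, 5, 3)
            a = cylinders_overlap(make_cylinder(r1, u1, params),
                                  make_cylinder(r1 + dr, u2, params), box)
            b = cylinders_overlap(make_cylinder(r1 + shift, u1, params),
                                  make_cylinder(r1 + shift + dr, u2, params),
                                  box)
            assert a == b


class TestFoldingAngle:
    @pytest.mark.parametrize("u1, u2, expected", [
        ((0, 0, 1), (0, 0, 1), 0.0),
        ((0, 0, 1), (0, 0, -1), 180.0),
        ((1, 0, 0), (0, 1, 0), 90.0),
    ])
    def test_reference_angles(self, params, u1, u2, expected):
        d = GappedDuplex(make_cylinder([0, 0, 0], u1, params),
                         make_cylinder([5, 0, 0], u2, params))
        assert folding_angle(d) == pytest.approx(expected, abs=1e-9)

    def test_exchange_symmetry(self, params, rng):
        for _ in range(50):
            u1, u2 = random_unit(rng), random_unit(rng)
            d = GappedDuplex(make_cylinder([0, 0, 0], u1, params),
                             make_cylinder([5, 0, 0], u2, params))
            dswap = GappedDuplex(d.cyl2, d.cyl1)
            assert folding_angle(d) == pytest.approx(folding_angle(dswap))


class TestPeriodicProperties:
    """Hypothesis-driven invariants of the periodic arithmetic."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-500, 500), min_size=3, max_size=3),
           st.lists(st.floats(5.0, 80.0), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_minimum_image_idempotent_and_bounded(self, dr, edges):
        box = Box(np.array(edges))
        w = minimum_image(np.array(dr), box)
        assert np.all(np.abs(w) <= box.edges / 2 + 1e-9)
        np.testing.assert_allclose(minimum_image(w, box), w, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_folding_angle_range_and_symmetry(self, seed):
        p = ModelParams()
        r = np.random.default_rng(seed)
        u1, u2 = random_unit(r), random_unit(r)
        d = GappedDuplex(make_cylinder([0, 0, 0], u1, p),
                         make_cylinder([5, 0, 0], u2, p))
        ang = folding_angle(d)
        assert 0.0 <= ang <= 180.0
        swapped = folding_angle(GappedDuplex(d.cyl2, d.cyl1))
        assert ang == pytest.approx(swapped, abs=1e-9)
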