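"""Zernike patches: extraction, orientation, projection, expansion."""

import numpy as np
import pytest

from cirfeat.zernike import (
    PatchError,
    build_projection,
    complementarity_distance,
    extract_patch,
    orient_patch,
    patch_descriptor,
    reconstruct,
    zernike_index_pairs,
    zernike_moments,
    zernike_moments_fn,
    zernike_radial,
    ZernikeDescriptor,
)
from conftest import make_cloud


def _gauss_bump(r, psi):
    x, y = r * np.cos(psi), r * np.sin(psi)
    return np.exp(-((x - 0.3) ** 2 + (y + 0.2) ** 2) / 0.1)


class TestExtractPatch:
    def test_radius_larger_than_cloud_returns_whole_cloud(self):
        rng = np.random.default_rng(0)
        cloud = make_cloud("A", rng.uniform(0, 4, (30, 3)))
        patch = extract_patch(cloud, 0, radius=100.0)
        assert len(patch.indices) == 30

    def test_isolated_center_too_sparse(self):
        pts = np.vstack([[0, 0, 0], np.tile([20.0, 0, 0], (15, 1)) + np.random.default_rng(1).normal(0, 1, (15, 3))])
        cloud = make_cloud("A", pts)
        with pytest.raises(PatchError, match="points"):
            extract_patch(cloud, 0, radius=9.0)

    def test_membership_matches_brute_force(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(400, 3))
        sphere = 10.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        cloud = make_cloud("A", sphere, normals=sphere / 10.0)
        patch = extract_patch(cloud, 7, radius=9.0)
        d = np.linalg.norm(sphere - sphere[7], axis=1)
        assert set(patch.indices) == set(np.nonzero(d <= 9.0)[0])


class TestOrientPatch:
    def test_planar_patch_stays_planar_at_origin(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(-3, 3, (40, 2))
        cloud = make_cloud("A", np.column_stack([xy, np.zeros(40)]))
        oriented = orient_patch(extract_patch(cloud, 0, radius=20.0))
        assert np.allclose(oriented.points[:, 2], 0.0, atol=1e-9)
        assert np.allclose(oriented.points.mean(axis=0), 0.0, atol=1e-9)

    def test_rigid_rotation_gives_same_descriptor(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(-5, 5, (200, 2))
        z = np.sin(xy[:, 0]) * 0.5 + 0.3 * xy[:, 1] ** 2 / 5
        cloud = make_cloud("A", np.column_stack([xy, z]))
        d1 = patch_descriptor(cloud, 0, radius=20.0)
        axis = np.array([1.0, 2.0, 0.5])
        axis /= np.linalg.norm(axis)
        theta = 1.1
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
        cloud2 = make_cloud("A", cloud.positions @ rot.T, normals=cloud.normals @ rot.T)
        d2 = patch_descriptor(cloud2, 0, radius=20.0)
        assert complementarity_distance(d1, d2) < 1e-6 * np.linalg.norm(d1.values)

    def test_hemisphere_normal_along_symmetry_axis(self):
        rng = np.random.default_rng(5)
        # spherical cap around +z
        phi = rng.uniform(0, 2 * np.pi, 400)
        theta = np.arccos(rng.uniform(np.cos(0.6), 1.0, 400))
        pts = 8.0 * np.column_stack([
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ])
        cloud = make_cloud("A", pts, normals=pts / 8.0)
        oriented = orient_patch(extract_patch(cloud, 0, radius=30.0))
        # the fitted plane of a symmetric cap is horizontal: mean height of the
        # oriented points depends only on radius; spread in z is small vs xy
        assert oriented.points[:, 2].std() < oriented.points[:, :2].std()

    def test_collinear_points_raise(self):
        pts = np.column_stack([np.linspace(0, 5, 20), np.zeros(20), np.zeros(20)])
        cloud = make_cloud("A", pts)
        with pytest.raises(PatchError):
            orient_patch(extract_patch(cloud, 0, radius=10.0))


class TestProjection:
    def test_degenerate_on_axis_points_rejected(self):
        from cirfeat.zernike import OrientedPatch
        pts = np.column_stack([np.zeros(12), np.zeros(12), np.linspace(0, 1, 12)])
        oriented = OrientedPatch(points=pts, potential=np.zeros(12))
        with pytest.raises(PatchError):
            build_projection(oriented)

    def test_constant_potential_gives_constant_electrostatic_grid(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(-4, 4, (300, 2))
        cloud = make_cloud("A", np.column_stack([xy, np.zeros(300)]),
                           potential=np.full(300, 2.5))
        proj = build_projection(orient_patch(extract_patch(cloud, 0, radius=20.0)),
                                kind="electrostatic")
        assert np.allclose(proj.grid[proj.mask], 2.5)

    def test_flat_disk_shape_values_match_secant_geometry(self):
        # closed form: for a flat patch at z=0 the apex is at the maximal
        # planar radius and r(p) = sqrt(rho^2 + z_C^2) per point
        rng = np.random.default_rng(8)
        t = rng.uniform(0, 2 * np.pi, 500)
        rad = 5.0 * np.sqrt(rng.uniform(0, 1, 500))
        xy = np.column_stack([rad * np.cos(t), rad * np.sin(t)])
        cloud = make_cloud("A", np.column_stack([xy, np.zeros(500)]))
        patch = extract_patch(cloud, int(np.argmin(rad)), radius=20.0)
        oriented = orient_patch(patch)
        proj = build_projection(oriented, kind="shape")
        z_c = np.hypot(oriented.points[:, 0], oriented.points[:, 1]).max()
        r_expect = np.hypot(np.hypot(oriented.points[:, 0], oriented.points[:, 1]), z_c)
        assert abs(proj.apex_height - z_c) < 1e-9
        assert proj.grid[proj.mask].min() >= r_expect.min() - 1e-9
        assert proj.grid[proj.mask].max() <= r_expect.max() + 1e-9


class TestRadialPolynomial:
    def test_constant_term(self):
        assert zernike_radial(0, 0, 0.3) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,m", [(2, 0), (4, 2), (8, 8), (20, 0), (13, 5)])
    def test_boundary_identity(self, n, m):
        assert zernike_radial(n, m, 1.0) == pytest.approx(1.0)

    def test_r20_closed_form(self):
        assert zernike_radial(2, 0, 0.5) == pytest.approx(2 * 0.25 - 1)

    def test_parity_violation_raises(self):
        with pytest.raises(ValueError):
            zernike_radial(3, 0, 0.5)


class TestMoments:
    def test_descriptor_length_121_at_order_20(self):
        assert len(zernike_index_pairs(20)) == 121

    def test_constant_function_gives_only_c00(self):
        desc, coeffs = zernike_moments_fn(lambda r, p: np.ones_like(r), order=20)
        assert coeffs[0].real == pytest.approx(1.0, abs=1e-9)
        assert np.abs(coeffs[1:]).max() < 1e-3

    def test_radial_basis_function_recovered(self):
        desc, coeffs = zernike_moments_fn(lambda r, p: zernike_radial(2, 0, r), order=20)
        pairs = zernike_index_pairs(20)
        i = pairs.index((2, 0))
        assert coeffs[i].real == pytest.approx(1.0, abs=1e-6)
        assert np.abs(np.delete(coeffs, i)).max() < 1e-3

    def test_rotational_invariance_of_norms(self):
        d1, _ = zernike_moments_fn(_gauss_bump, order=20)
        d2, _ = zernike_moments_fn(lambda r, p: _gauss_bump(r, p - 0.7123), order=20)
        rel = np.linalg.norm(d1.values - d2.values) / np.linalg.norm(d1.values)
        assert rel < 1e-3

    def test_moments_reconstruct_moments_fixed_point(self):
        # band-limited input: a low-order Zernike combination
        pairs = zernike_index_pairs(8)
        rng = np.random.default_rng(9)
        c_true = rng.normal(size=len(pairs)) * np.exp(-np.arange(len(pairs)) / 6)

        def f(r, p):
            out = np.zeros_like(r)
            for (n, m), c in zip(pairs, c_true):
                z = zernike_radial(n, m, r) * np.exp(1j * m * p)
                out = out + (c * z).real * (1 if m == 0 else 2)
            return out

        _, coeffs = zernike_moments_fn(f, order=8)
        assert np.allclose(coeffs.real, c_true, atol=1e-8)


class TestReconstruct:
    def test_zero_coefficients_give_zero_function(self):
        vals, inside = reconstruct(np.zeros(121, dtype=complex), 20, 51)
        assert np.allclose(vals, 0.0)

    def test_constant_reconstruction_error_small(self):
        _, coeffs = zernike_moments_fn(lambda r, p: np.ones_like(r), order=20)
        vals, inside = reconstruct(coeffs, 20, 101)
        assert np.max(np.abs(vals[inside] - 1.0)) < 1e-2

    def test_l2_error_non_increasing_in_order(self):
        _, coeffs = zernike_moments_fn(_gauss_bump, order=20)
        errs = []
        for order in (5, 10, 15, 20):
            k = len(zernike_index_pairs(order))
            vals, inside = reconstruct(coeffs[:k], order, 101)
            c = (np.arange(101) + 0.5) * (2 / 101) - 1
            x, y = np.meshgrid(c, c, indexing="ij")
            r, p = np.hypot(x, y), np.arctan2(y, x)
            true = _gauss_bump(np.clip(r, 0, 1), p)
            errs.append(np.sqrt(np.mean((vals[inside] - true[inside]) ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestComplementarity:
    def test_identical_descriptors_have_zero_distance(self):
        d = ZernikeDescriptor(order=20, values=np.arange(121.0))
        assert complementarity_distance(d, d) == 0.0

    def test_unit_vectors_distance_sqrt2(self):
        a = np.zeros(121); a[0] = 1.0
        b = np.zeros(121); b[1] = 1.0
        da, db = ZernikeDescriptor(20, a), ZernikeDescriptor(20, b)
        assert complementarity_distance(da, db) == pytest.approx(np.sqrt(2))

    def test_mismatched_order_raises(self):
        da = ZernikeDescriptor(20, np.zeros(121))
        db = ZernikeDescriptor(10, np.zeros(36))
        with pytest.raises(ValueError):
            complementarity_distance(da, db)

    def test_mirror_self_complementarity(self, mirror_pair):
        a, b = mirror_pair
        center = int(np.argmin(np.linalg.norm(a.positions, axis=1)))
        for kind in ("shape", "electrostatic"):
            da = patch_descriptor(a, center, kind, sign=+1)
            db = patch_descriptor(b, center, kind, sign=-1)
            assert complementarity_distance(da, db) < 1e-3


class TestSerialization:
    def test_descriptor_csv_roundtrip(self, tmp_path):
        from cirfeat.zernike import descriptor_to_csv, descriptor_from_csv
        rng = np.random.default_rng(0)
        d = ZernikeDescriptor(order=8, values=rng.random(len(zernike_index_pairs(8))))
        descriptor_to_csv(d, tmp_path / "d.csv")
        back = descriptor_from_csv(tmp_path / "d.csv")
        assert back.order == 8
        assert np.array_equal(back.values, d.values)

    def test_projection_csv_export(self, tmp_path, mirror_pair):
        from cirfeat.zernike import projection_to_csv
        a, _ = mirror_pair
        proj = build_projection(orient_patch(extract_patch(a, 900)))
        projection_to_csv(proj, tmp_path / "p.csv")
        grid = np.loadtxt(tmp_path / "p.csv", delimiter=",")
        assert grid.shape == (25, 25)
        assert np.isnan(grid[~proj.mask]).all()
        assert np.allclose(grid[proj.mask], proj.grid[proj.mask])
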