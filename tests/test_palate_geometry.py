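"""Reference planes, landmark completion and the seven palatal measurements.

Oracles: analytic shapes (half-cylinder, hemisphere, half-ellipsoid, clipped
cubes), a grid-search total-least-squares oracle for the SVD plane, an
independent scipy Procrustes oracle for completion, and the synthetic-cast
generator's ground truth.  Invariants: rigid-motion invariance and scaling
laws of every measurement, plane orthogonality, half-space containment of
clipped meshes.
"""

import numpy as np
import pytest
import trimesh
from scipy.linalg import orthogonal_procrustes

from palatwin.io_formats import LandmarkSet, required_landmarks
from palatwin.palate_geometry import (
    GeometryError,
    Plane,
    clip_palate,
    complete_landmarks,
    fit_plane_svd,
    gingival_plane,
    measure_ap_length,
    measure_cast,
    measure_depths,
    measure_widths,
    midpalatal_plane,
    palatal_area,
    palatal_volume,
    posterior_plane,
)
from palatwin.synthetic_data import PalateShapeParams, generate_palate_mesh

from conftest import random_rotation


class TestFitPlaneSvd:
    def test_exact_coplanar_z0(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        plane = fit_plane_svd(pts)
        assert np.allclose(plane.normal, [0, 0, 1])
        assert plane.offset == pytest.approx(0.0, abs=1e-12)

    def test_coplanar_diagonal_plane(self):
        # points on x + y + z = 3
        pts = np.array([[3, 0, 0], [0, 3, 0], [0, 0, 3], [1, 1, 1.0]])
        plane = fit_plane_svd(pts)
        assert np.allclose(plane.normal, np.ones(3) / np.sqrt(3))
        assert plane.offset == pytest.approx(np.sqrt(3))

    def test_noisy_points_match_grid_search_oracle(self, rng):
        pts = np.column_stack([
            rng.uniform(-5, 5, 20), rng.uniform(-5, 5, 20),
            rng.normal(0, 0.2, 20),
        ])
        plane = fit_plane_svd(pts)

        def sum_sq(n):
            n = n / np.linalg.norm(n)
            d = pts @ n - (pts @ n).mean()
            return (d**2).sum()

        # brute-force minimisation over gridded unit normals
        best = (np.inf, None)
        for theta in np.linspace(0, np.pi, 181):
            for phi in np.linspace(0, np.pi, 181):
                n = np.array([
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(theta),
                ])
                v = sum_sq(n)
                if v < best[0]:
                    best = (v, n)
        assert sum_sq(plane.normal) <= best[0] + 1e-9
        assert abs(np.dot(plane.normal, best[1])) > np.cos(np.radians(1.0))

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5), [1.0, 2.0, 3.0])
        with pytest.raises(GeometryError, match="collinear"):
            fit_plane_svd(pts)


def _symmetric_landmarks(stage="primary"):
    """Hand-built bilaterally symmetric primary-dentition landmark set."""
    rng = np.random.default_rng(3)
    pts = {}
    for i, code in enumerate(["51", "52", "53", "54", "55"]):
        x = 4.0 + 2.0 * i
        y = 20.0 - 4.0 * i
        pts[f"dg_{code}"] = np.array([x, y, 0.0])
        pts[f"dg_6{code[1]}"] = np.array([-x, y, 0.0])
    pts["raphe_anterior"] = np.array([0.0, 22.0, 0.0])
    pts["raphe_middle"] = np.array([0.0, 12.0, -5.0])
    pts["raphe_posterior"] = np.array([0.0, 4.0, -9.0])
    pts["distal_55"] = np.array([13.0, 2.0, 0.0])
    pts["distal_65"] = np.array([-13.0, 2.0, 0.0])
    return LandmarkSet(cast_id="sym", stage=stage, points=pts)


class TestCompleteLandmarks:
    def test_symmetric_restores_exact_mirror(self):
        lm = _symmetric_landmarks()
        target = lm["dg_53"].copy()
        partial = LandmarkSet(
            lm.cast_id, lm.stage,
            {k: v for k, v in lm.points.items() if k != "dg_53"},
        )
        out = complete_landmarks(partial)
        assert out.imputed == {"dg_53"}
        assert np.allclose(out["dg_53"], target, atol=1e-9)
        mirror = lm["dg_63"] * [-1, 1, 1]
        assert np.allclose(out["dg_53"], mirror, atol=1e-9)

    def test_complete_input_is_identity(self):
        lm = _symmetric_landmarks()
        out = complete_landmarks(lm)
        assert out is lm
        assert not out.imputed

    def test_asymmetric_matches_independent_procrustes_oracle(self):
        # rotate the right side 2 degrees about the raphe (y) axis
        lm = _symmetric_landmarks()
        th = np.radians(2.0)
        R = np.array([
            [np.cos(th), 0, np.sin(th)], [0, 1, 0],
            [-np.sin(th), 0, np.cos(th)],
        ])
        pts = {
            k: (R @ v if v[0] > 0 else v.copy()) for k, v in lm.points.items()
        }
        asym = LandmarkSet("asym", "primary", pts)
        dropped = "dg_54"
        partial = LandmarkSet(
            "asym", "primary", {k: v for k, v in pts.items() if k != dropped}
        )
        out = complete_landmarks(partial)

        # independent oracle: reflect across the fitted mid-sagittal plane,
        # relabel antimeres, superimpose with scipy orthogonal_procrustes
        from palatwin.io_formats import antimere_map
        from palatwin.palate_geometry import _midsagittal_estimate

        amap = antimere_map("primary")
        mid = _midsagittal_estimate(partial)
        names = sorted(partial.points)
        X = partial.coords(names)
        refl = X - 2 * np.outer(mid.signed_distance(X), mid.normal)
        relabel = {amap[n]: p for n, p in zip(names, refl)}
        shared = sorted(set(relabel) & set(partial.points))
        A = np.array([relabel[n] for n in shared])
        B = partial.coords(shared)
        Ac, Bc = A - A.mean(axis=0), B - B.mean(axis=0)
        Rot, _ = orthogonal_procrustes(Ac, Bc)
        pred = (relabel[dropped] - A.mean(axis=0)) @ Rot + B.mean(axis=0)
        assert np.allclose(out[dropped], pred, atol=1e-8)

    def test_both_antimeres_missing_rejected(self):
        lm = _symmetric_landmarks()
        partial = LandmarkSet(
            lm.cast_id, lm.stage,
            {k: v for k, v in lm.points.items() if k not in ("dg_53", "dg_63")},
        )
        with pytest.raises(GeometryError, match="dg_53"):
            complete_landmarks(partial)


class TestReferencePlanes:
    def test_gingival_plane_flat_case(self):
        lm = _symmetric_landmarks()
        plane = gingival_plane(lm)
        assert np.allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert plane.offset == pytest.approx(0.0, abs=1e-12)
        # vault (raphe_middle at z=-5) must be interior (negative side)
        assert plane.signed_distance(lm["raphe_middle"]) < 0

    def test_midpalatal_is_sagittal_and_orthogonal(self):
        lm = _symmetric_landmarks()
        ging = gingival_plane(lm)
        mid = midpalatal_plane(lm, ging)
        assert np.allclose(np.abs(mid.normal), [1, 0, 0], atol=1e-12)
        assert abs(mid.normal @ ging.normal) < 1e-9
        assert mid.offset == pytest.approx(0.0, abs=1e-12)

    def test_posterior_plane_through_distal_midpoint(self):
        pts = _symmetric_landmarks().points.copy()
        pts["distal_55"] = np.array([14.0, -25.0, -2.0])
        pts["distal_65"] = np.array([-14.0, -25.0, -2.0])
        lm = LandmarkSet("t", "primary", pts)
        ging = gingival_plane(lm)
        mid = midpalatal_plane(lm, ging)
        post = posterior_plane(lm, ging, mid)
        assert abs(post.normal @ ging.normal) < 1e-9
        assert abs(post.normal @ mid.normal) < 1e-9
        # plane y = -25: distal midpoint on it, papilla interior
        assert post.signed_distance(np.array([0, -25.0, 0]))== pytest.approx(0, abs=1e-9)
        assert post.signed_distance(lm["raphe_anterior"]) < 0

    def test_gingival_plane_equivariant_under_rotation(self, rng):
        lm = _symmetric_landmarks()
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        rot = lm.transformed(R, t)
        p0 = gingival_plane(lm)
        p1 = gingival_plane(rot)
        assert np.allclose(np.abs(p1.normal @ (R @ p0.normal)), 1.0, atol=1e-9)
        # a point on the original plane maps onto the rotated plane
        pt = p0.project(lm["dg_53"])
        assert abs(p1.signed_distance(R @ pt + t)) < 1e-9


class TestLinearMeasurements:
    def test_anterior_width_from_placed_canines(self):
        pts = _symmetric_landmarks().points.copy()
        pts["dg_53"] = np.array([11.05, 12.0, 0.0])
        pts["dg_63"] = np.array([-11.05, 12.0, 0.0])
        lm = LandmarkSet("t", "primary", pts)
        aw, _ = measure_widths(lm)
        assert aw == pytest.approx(22.1)

    def test_coincident_antimeres_zero_width(self):
        pts = _symmetric_landmarks().points.copy()
        pts["dg_55"] = pts["dg_65"] = np.array([0.0, 4.0, 0.0])
        lm = LandmarkSet("t", "primary", pts)
        _, pw = measure_widths(lm)
        assert pw == 0.0

    def test_widths_rigid_invariant(self, rng):
        lm = _symmetric_landmarks()
        R = random_rotation(rng)
        rot = lm.transformed(R, rng.normal(size=3))
        assert np.allclose(measure_widths(lm), measure_widths(rot), atol=1e-9)

    def test_ap_length_papilla_to_plane(self):
        pts = _symmetric_landmarks().points.copy()
        pts["raphe_anterior"] = np.array([0.0, 0.3, 0.0])
        lm = LandmarkSet("t", "primary", pts)
        post = Plane(np.array([0, 1.0, 0]), -25.0).oriented_toward([0, 0.3, 0])
        assert measure_ap_length(lm, post) == pytest.approx(25.3)
        on_plane = LandmarkSet(
            "t", "primary",
            {**pts, "raphe_anterior": np.array([0.0, -25.0, 0.0])},
        )
        assert measure_ap_length(on_plane, post) == pytest.approx(0.0, abs=1e-12)


class TestDepths:
    def test_half_cylinder_depth_equals_radius(self):
        """Vault shaped as a half-cylinder of radius 10 under the canine line."""
        lm = _symmetric_landmarks()
        y_line = lm["dg_53"][1]
        theta = np.linspace(np.pi, 2 * np.pi, 721)
        ys = np.linspace(y_line - 0.4, y_line + 0.4, 9)
        pts = []
        for y in ys:
            for th in theta:
                pts.append([10 * np.cos(th) * 0.02, y, 10 * np.sin(th)])
        # thin strip near the mid-palatal plane (x scaled to ~0)
        vault = np.array(pts)
        ad, _ = measure_depths(
            lm, np.vstack([vault, lm["raphe_posterior"] + [0, 0, -1]]),
        )
        assert ad == pytest.approx(10.0, abs=1e-6)

    def test_flat_palate_zero_depth(self):
        lm = _symmetric_landmarks()
        y_line = lm["dg_53"][1]
        vault = np.column_stack([
            np.zeros(21), np.linspace(y_line - 0.5, y_line + 0.5, 21), np.zeros(21)
        ])
        ad, _ = measure_depths(lm, np.vstack([vault, [[0, 4.0, 0]]]))
        assert ad == pytest.approx(0.0, abs=1e-12)

    def test_empty_band_raises(self):
        lm = _symmetric_landmarks()
        vault = np.array([[50.0, 50.0, 50.0]])
        with pytest.raises(GeometryError, match="band"):
            measure_depths(lm, vault)

    def test_generator_depth_recovered(self, default_cast):
        mesh, lm, truth = default_cast
        ad, pd_ = measure_depths(lm, mesh.vertices)
        assert ad == pytest.approx(truth.anterior_depth, abs=0.1)
        assert pd_ == pytest.approx(truth.posterior_depth, abs=0.1)


class TestClipping:
    def test_sphere_clipped_to_hemisphere(self):
        sph = trimesh.creation.icosphere(subdivisions=3)
        g = Plane(np.array([0, 0, 1.0]), 0.0).oriented_toward([0, 0, -1])
        p = Plane(np.array([0, 1.0, 0]), 5.0).oriented_toward([0, 0, 0])
        hemi = clip_palate(sph, g, p)
        assert hemi.vertices[:, 2].max() <= 1e-9

    def test_fully_interior_mesh_unchanged(self):
        box = trimesh.creation.box(extents=[1, 1, 1])
        g = Plane(np.array([0, 0, 1.0]), 5.0).oriented_toward([0, 0, 0])
        p = Plane(np.array([0, 1.0, 0]), 5.0).oriented_toward([0, 0, 0])
        out = clip_palate(box, g, p)
        assert len(out.faces) == len(box.faces)
        assert out.area == pytest.approx(box.area)

    def test_empty_clip_raises(self):
        box = trimesh.creation.box(extents=[1, 1, 1])
        g = Plane(np.array([0, 0, 1.0]), -5.0).oriented_toward([0, 0, -10])
        p = Plane(np.array([0, 1.0, 0]), 5.0).oriented_toward([0, 0, 0])
        with pytest.raises(GeometryError, match="outside"):
            clip_palate(box, g, p)

    def test_cube_diagonal_clip_matches_polyhedral_oracle(self):
        """Unit cube clipped by x+y+z <= 1.5: volume 1 - corner tetra complement."""
        box = trimesh.creation.box(extents=[1, 1, 1])
        box.apply_translation([0.5, 0.5, 0.5])
        n = np.ones(3) / np.sqrt(3)
        g = Plane(n, 1.5 / np.sqrt(3)).oriented_toward([0, 0, 0])
        p = Plane(np.array([0, 1.0, 0]), 5.0).oriented_toward([0, 0, 0])
        out = clip_palate(box, g, p)
        # exact polyhedral computation: cut corner is a tetrahedron of leg 1.5
        # minus three overhanging tetra of leg 0.5
        removed = (1.5**3 - 3 * 0.5**3) / 6.0
        assert palatal_volume(out, g, p) == pytest.approx(1.0 - removed, abs=1e-9)


class TestAreaVolume:
    def test_unit_square_area(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
            faces=[[0, 1, 2], [0, 2, 3]], process=False,
        )
        assert palatal_area(mesh) == pytest.approx(1.0)

    def test_hemisphere_area_converges(self):
        r = 10.0
        sph = trimesh.creation.icosphere(subdivisions=5, radius=r)
        g = Plane(np.array([0, 0, 1.0]), 0.0).oriented_toward([0, 0, -1])
        p = Plane(np.array([0, 1.0, 0]), 2 * r).oriented_toward([0, 0, 0])
        hemi = clip_palate(sph, g, p)
        assert palatal_area(hemi) == pytest.approx(2 * np.pi * r**2, rel=0.01)

    def test_half_ellipsoid_volume_analytic(self):
        a, b, c = 13.7, 12.65, 10.6
        ell = trimesh.creation.icosphere(subdivisions=5)
        ell.apply_scale([a, b, c])
        g = Plane(np.array([0, 0, 1.0]), 0.0).oriented_toward([0, 0, -1])
        p = Plane(np.array([0, 1.0, 0]), 100.0).oriented_toward([0, 0, 0])
        half = clip_palate(ell, g, p)
        assert palatal_volume(half, g, p) == pytest.approx(
            2 / 3 * np.pi * a * b * c, rel=0.01
        )

    def test_unit_cube_volume(self):
        box = trimesh.creation.box(extents=[1, 1, 1])
        box.apply_translation([0.5, 0.5, 0.5])
        g = Plane(np.array([0, 0, 1.0]), 2.0).oriented_toward([0, 0, 0])
        p = Plane(np.array([0, 1.0, 0]), 2.0).oriented_toward([0, 0, 0])
        out = clip_palate(box, g, p)
        assert palatal_volume(out, g, p) == pytest.approx(1.0, abs=1e-12)

    def test_non_closable_boundary_rejected(self):
        # open square not lying on either clipping plane
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 3], [1, 0, 3], [1, 1, 3], [0, 1, 3.0]],
            faces=[[0, 1, 2], [0, 2, 3]], process=False,
        )
        g = Plane(np.array([0, 0, 1.0]), 5.0).oriented_toward([0, 0, 0])
        p = Plane(np.array([0, 1.0, 0]), 5.0).oriented_toward([0, 0, 0])
        with pytest.raises(GeometryError, match="boundary"):
            palatal_volume(mesh, g, p)


class TestMeasurementInvariants:
    def test_rigid_motion_invariance_all_traits(self, default_cast, rng):
        mesh, lm, _ = default_cast
        base = measure_cast(mesh, lm)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 30
        mesh2 = mesh.copy()
        mesh2.apply_transform(
            np.vstack([np.column_stack([R, t]), [0, 0, 0, 1]])
        )
        moved = measure_cast(mesh2, lm.transformed(R, t))
        for trait in ("anterior_width", "posterior_width", "anterior_depth",
                      "posterior_depth", "ap_length"):
            assert getattr(moved, trait) == pytest.approx(
                getattr(base, trait), abs=1e-6
            )
        assert moved.area == pytest.approx(base.area, abs=1e-4)
        assert moved.volume == pytest.approx(base.volume, abs=1e-3)

    def test_scaling_laws(self, default_cast):
        mesh, lm, _ = default_cast
        base = measure_cast(mesh, lm)
        s = 1.7
        mesh2 = mesh.copy()
        mesh2.apply_scale(s)
        scaled_lm = lm.transformed(np.eye(3) * s, np.zeros(3))
        # the vault-candidate band is an absolute length, so it scales too
        from palatwin.palate_geometry import DEPTH_BAND
        scaled = measure_cast(mesh2, scaled_lm, band=s * DEPTH_BAND)
        for trait in ("anterior_width", "posterior_width", "anterior_depth",
                      "posterior_depth", "ap_length"):
            assert getattr(scaled, trait) == pytest.approx(
                s * getattr(base, trait), rel=1e-9
            )
        assert scaled.area == pytest.approx(s**2 * base.area, rel=1e-9)
        assert scaled.volume == pytest.approx(s**3 * base.volume, rel=1e-9)

    def test_clipped_mesh_satisfies_half_spaces(self, default_cast):
        mesh, lm, _ = default_cast
        lm2 = complete_landmarks(lm)
        ging = gingival_plane(lm2)
        mid = midpalatal_plane(lm2, ging)
        post = posterior_plane(lm2, ging, mid)
        clipped = clip_palate(mesh, ging, post)
        assert np.all(ging.signed_distance(clipped.vertices) <= 1e-9)
        assert np.all(post.signed_distance(clipped.vertices) <= 1e-9)

    def test_area_volume_refinement_convergence(self, default_cast, fine_cast):
        _, _, truth = default_cast
        coarse_m, _, _ = default_cast
        fine_m, fine_lm, fine_truth = fine_cast
        # reference values identical regardless of tessellation
        assert truth.area == pytest.approx(fine_truth.area)
        m_coarse = measure_cast(*default_cast[:2])
        m_fine = measure_cast(fine_m, fine_lm)
        assert abs(m_fine.area - truth.area) < abs(m_coarse.area - truth.area)
        assert m_fine.area == pytest.approx(truth.area, rel=0.005)
        assert m_fine.volume == pytest.approx(truth.volume, rel=0.005)
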