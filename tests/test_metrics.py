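"""Morphometrics and quality metrics: analytic cases, oracles, invariances."""

import math

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from corsurf.io_formats import LabelMap, SurfaceMesh
from corsurf.metrics import (
    cortical_thickness,
    dice_coefficient,
    dice_per_region,
    instability,
    map_to_common_space,
    parcellation_instability,
    sulcal_depth,
    surface_displacement,
    symmetric_mean_displacement,
    triangle_quality,
)


def sphere(subdivisions=4, radius=10.0, center=(0.0, 0.0, 0.0)):
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(
        vertices=np.asarray(s.vertices) + np.asarray(center), faces=np.asarray(s.faces)
    )


def single_triangle(a, b, c):
    return SurfaceMesh(vertices=np.array([a, b, c], dtype=float), faces=np.array([[0, 1, 2]]))


class TestTriangleQuality:
    def test_equilateral_is_one(self):
        q, qm = triangle_quality(
            single_triangle([0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0])
        )
        assert q[0] == pytest.approx(1.0, abs=1e-12)
        assert qm == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_is_zero(self):
        q, _ = triangle_quality(single_triangle([0, 0, 0], [1, 0, 0], [2, 0, 0]))
        assert q[0] == 0.0

    def test_right_triangle_formula(self):
        # legs 1,1: edges 1,1,sqrt(2); A=1/2 -> Q = 4*sqrt(3)*(1/2)/4 = sqrt(3)/2
        q, _ = triangle_quality(single_triangle([0, 0, 0], [1, 0, 0], [0, 1, 0]))
        assert q[0] == pytest.approx(math.sqrt(3) / 2, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        scale=st.floats(0.01, 100.0),
        angles=st.tuples(
            st.floats(0, 2 * math.pi), st.floats(0, math.pi), st.floats(0, 2 * math.pi)
        ),
        shift=st.tuples(*[st.floats(-50, 50)] * 3),
    )
    def test_invariant_under_similarity_transforms(self, scale, angles, shift):
        from scipy.spatial.transform import Rotation

        mesh = sphere(subdivisions=1)
        q0, _ = triangle_quality(mesh)
        R = Rotation.from_euler("zyz", angles).as_matrix()
        moved = SurfaceMesh(
            vertices=scale * mesh.vertices @ R.T + np.asarray(shift), faces=mesh.faces
        )
        q1, _ = triangle_quality(moved)
        assert np.allclose(q0, q1, atol=1e-9)

    def test_bounds_on_random_meshes(self, one_phantom):
        q, qm = triangle_quality(one_phantom.white_mesh)
        assert np.all(q >= 0) and np.all(q <= 1.0 + 1e-12)
        assert 0 < qm <= 1


class TestDisplacement:
    def test_identical_meshes_zero(self, one_phantom):
        d = surface_displacement(one_phantom.white_mesh, one_phantom.white_mesh)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_concentric_spheres(self):
        d = surface_displacement(sphere(4, 10.0), sphere(4, 12.0))
        assert np.all(np.abs(d - 2.0) <= 0.1)

    def test_brute_force_oracle_small_meshes(self):
        """Exhaustive point-to-triangle minimum matches to 1e-9."""
        a = sphere(1, 5.0)  # 80 faces
        b = sphere(1, 6.0, center=(0.5, 0.3, -0.2))
        d = surface_displacement(a, b)
        tri = b.vertices[b.faces]
        for i in np.random.default_rng(0).choice(len(a.vertices), 30, replace=False):
            p = a.vertices[i]
            best = np.inf
            for t in tri:
                best = min(best, _brute_point_tri(p, *t))
            assert abs(d[i] - math.sqrt(best)) < 1e-9

    def test_triangle_type_inequality(self, phantom_bank):
        a = phantom_bank[0].white_mesh
        b = phantom_bank[1].white_mesh
        c = phantom_bank[2].white_mesh
        d_ac = surface_displacement(a, c).mean()
        d_ab = surface_displacement(a, b).mean()
        d_bc_max = surface_displacement(b, c).max()
        assert d_ac <= d_ab + d_bc_max + 1e-9


def _brute_point_tri(p, a, b, c):
    ab, ac = b - a, c - a
    cands = [a, b, c]
    g = np.array([[ab @ ab, ab @ ac], [ab @ ac, ac @ ac]])
    if np.linalg.det(g) > 1e-14:
        s, t = np.linalg.solve(g, np.array([ab @ (p - a), ac @ (p - a)]))
        if s >= 0 and t >= 0 and s + t <= 1:
            cands.append(a + s * ab + t * ac)
    for u, v in ((a, b), (a, c), (b, c)):
        d = v - u
        tt = np.clip((p - u) @ d / (d @ d), 0, 1)
        cands.append(u + tt * d)
    return min(float(np.sum((q - p) ** 2)) for q in cands)


class TestThickness:
    def test_phantom_thickness_recovered(self, one_phantom):
        th = cortical_thickness(one_phantom.white_mesh, one_phantom.pial_mesh)
        true = one_phantom.params.cortical_thickness_true
        assert th.mean() == pytest.approx(true, abs=0.2)

    def test_white_equals_pial_gives_zero(self, one_phantom):
        th = cortical_thickness(one_phantom.white_mesh, one_phantom.white_mesh)
        assert np.allclose(th, 0.0, atol=1e-12)

    def test_scale_equivariance(self, one_phantom):
        w, p = one_phantom.white_mesh, one_phantom.pial_mesh
        th1 = cortical_thickness(w, p)
        th2 = cortical_thickness(
            SurfaceMesh(2 * w.vertices, w.faces), SurfaceMesh(2 * p.vertices, p.faces)
        )
        assert np.allclose(th2, 2 * th1, atol=1e-9)

    def test_nonnegative(self, one_phantom):
        assert np.all(cortical_thickness(one_phantom.white_mesh, one_phantom.pial_mesh) >= 0)


class TestSulcalDepth:
    def test_sphere_is_flat(self):
        d = sulcal_depth(sphere(4, 10.0), smoothing_iters=50)
        assert np.abs(d).max() < 1e-3 * 10.0

    def test_zero_iterations_zero_depth(self, one_phantom):
        assert np.all(sulcal_depth(one_phantom.white_mesh, 0) == 0)

    def test_depth_scales_with_fold_amplitude(self, phantom_bank):
        """Across 5 seeds, max |depth| lies within [0.5, 1.5] x amplitude."""
        for ph in phantom_bank[:5]:
            d = sulcal_depth(ph.white_mesh, smoothing_iters=50)
            a = ph.params.fold_amplitude
            assert 0.5 * a <= np.abs(d).max() <= 1.5 * a
            # mean ~ 0 within 5% of the RMS radius
            r = np.linalg.norm(
                ph.white_mesh.vertices - ph.white_mesh.vertices.mean(0), axis=1
            )
            assert abs(d.mean()) <= 0.05 * np.sqrt((r**2).mean())

    def test_sign_convention_valleys_positive(self, one_phantom):
        """Vertices below the local midsurface radius are sulcal (positive)."""
        mesh = one_phantom.white_mesh
        d = sulcal_depth(mesh, smoothing_iters=50)
        r = np.linalg.norm(mesh.vertices - mesh.vertices.mean(0), axis=1)
        deep = r < np.quantile(r, 0.05)
        high = r > np.quantile(r, 0.95)
        assert d[deep].mean() > 0 > d[high].mean()


class TestDice:
    def test_identical_maps_all_one(self):
        lm = LabelMap(np.array([0, 1, 1, 2]), {0: "a", 1: "b", 2: "c"})
        assert all(v == 1.0 for v in dice_per_region(lm, lm).values())

    def test_disjoint_zero(self):
        a = LabelMap(np.array([1, 1, 0, 0]), {0: "x", 1: "y"})
        b = LabelMap(np.array([0, 0, 1, 1]), {0: "x", 1: "y"})
        assert dice_coefficient(a, b, 1) == 0.0

    def test_formula_60_40_30(self):
        a = LabelMap(np.r_[np.zeros(60, int), np.ones(40, int)], {0: "r", 1: "s"})
        b_labels = np.ones(100, int)
        b_labels[30:70] = 0  # 40 zeros, overlapping 30 of a's zeros
        b = LabelMap(b_labels, {0: "r", 1: "s"})
        assert dice_coefficient(a, b, 0) == pytest.approx(2 * 30 / (60 + 40))

    def test_absent_region_reported_missing(self):
        a = LabelMap(np.zeros(4, int), {0: "bg"})
        b = LabelMap(np.zeros(4, int), {0: "bg"})
        assert dice_coefficient(a, b, 7) is None

    def test_vertex_count_mismatch_rejected(self):
        a = LabelMap(np.zeros(4, int), {0: "bg"})
        b = LabelMap(np.zeros(5, int), {0: "bg"})
        with pytest.raises(ValueError, match="mismatch"):
            dice_coefficient(a, b, 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_dice_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        names = {i: f"r{i}" for i in range(4)}
        a = LabelMap(rng.integers(0, 4, 50), names)
        b = LabelMap(rng.integers(0, 4, 50), names)
        for r in range(4):
            dab = dice_coefficient(a, b, r)
            dba = dice_coefficient(b, a, r)
            assert dab == dba
            if dab is not None:
                assert 0.0 <= dab <= 1.0


class TestInstability:
    def test_identical_maps_zero(self):
        maps = [np.arange(10.0)] * 4
        assert np.allclose(instability(maps), 0.0)

    def test_two_sample_sd(self):
        m1 = np.zeros(5)
        m2 = np.zeros(5)
        m2[3] = 1.5
        sd = instability([m1, m2])
        assert sd[3] == pytest.approx(1.5 / math.sqrt(2))
        assert np.all(sd[:3] == 0)

    def test_single_map_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            instability([np.zeros(5)])

    def test_parcellation_instability_identical_sessions(self):
        lm = LabelMap(np.array([0, 0, 1, 1, 2]), {0: "a", 1: "b", 2: "c"})
        out = parcellation_instability([lm, lm, lm])
        assert all(v == 0.0 for v in out.values())


class TestCommonSpace:
    def test_identity(self, one_phantom):
        mesh = one_phantom.white_mesh
        vals = np.arange(mesh.n_vertices, dtype=float)
        assert np.array_equal(map_to_common_space(vals, mesh, mesh), vals)

    def test_constant_preserved(self):
        a, b = sphere(3, 10.0), sphere(4, 10.0)
        out = map_to_common_space(np.full(a.n_vertices, 7.5), a, b)
        assert np.allclose(out, 7.5)

    def test_linear_field_error_bound(self):
        a, b = sphere(4, 10.0), sphere(3, 10.0)
        f = a.vertices[:, 0]
        out = map_to_common_space(f, a, b)
        edge = np.linalg.norm(
            a.vertices[a.faces[:, 0]] - a.vertices[a.faces[:, 1]], axis=1
        ).mean()
        assert np.abs(out - b.vertices[:, 0]).max() < edge


def test_full_suite_conservation(one_phantom):
    """Truth against itself: Q in (0,1], zero displacement, Dice 1, zero sd."""
    from corsurf.phantom import phantom_parcellation

    mesh = one_phantom.white_mesh
    _, qm = triangle_quality(mesh)
    assert 0 < qm <= 1
    assert np.allclose(surface_displacement(mesh, mesh), 0)
    assert symmetric_mean_displacement(mesh, mesh) == 0
    lm = phantom_parcellation(mesh, 6, seed=0)
    assert all(v == 1.0 for v in dice_per_region(lm, lm).values())
    th = cortical_thickness(mesh, one_phantom.pial_mesh)
    assert np.allclose(instability([th, th]), 0)
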