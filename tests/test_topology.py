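"""Topology correction and connectivity-consistent extraction."""

import math

import numpy as np
import pytest
from scipy import ndimage

from corsurf._kernels import is_simple_point
from corsurf.io_formats import SurfaceMesh, Volume
from corsurf.levelset import LevelSet
from corsurf.topology import (
    DigitalTopologyConfig,
    correct_topology,
    extract_surface,
    smooth_surface,
)

CFG6 = DigitalTopologyConfig(6, 26)
CFG26 = DigitalTopologyConfig(26, 6)


def levelset_of(phi, voxel=1.0, truncation=8.0):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return LevelSet(
        volume=Volume(data=np.asarray(phi, float), affine=affine), truncation=truncation
    )


def torus_levelset(n=32, ring=8.0, tube=3.0):
    idx = np.indices((n, n, n)).astype(float)
    c = (n - 1) / 2
    x, y, z = idx[0] - c, idx[1] - c, idx[2] - c
    phi = np.sqrt((np.sqrt(x**2 + y**2) - ring) ** 2 + z**2) - tube
    return levelset_of(np.clip(phi, -8, 8))


def sphere_levelset(n=32, radius=10.0):
    idx = np.indices((n, n, n)).astype(float)
    c = (n - 1) / 2
    phi = np.sqrt(((idx - c) ** 2).sum(axis=0)) - radius
    return levelset_of(np.clip(phi, -8, 8))


# --- voxel-complex oracle (independent of the package) ----------------------


def complex_euler_characteristic(mask):
    """Euler characteristic of the cubical complex of a voxel set.

    The cubical complex (union of closed unit cubes) is the continuous
    analog of *26-connectivity*: voxels touching only along an edge or
    corner are joined.
    """
    mask = np.asarray(mask, bool)
    p = np.pad(mask, 1)
    n_cells = int(mask.sum())
    n_faces = n_edges = 0
    for axis in range(3):
        n_faces += int((p | np.roll(p, 1, axis)).sum())
    for axis in range(3):
        a, b = [ax for ax in range(3) if ax != axis]
        u = p | np.roll(p, 1, a) | np.roll(p, 1, b) | np.roll(np.roll(p, 1, a), 1, b)
        n_edges += int(u.sum())
    u = p.copy()
    for da in (0, 1):
        for db in (0, 1):
            for dc in (0, 1):
                u = u | np.roll(np.roll(np.roll(p, da, 0), db, 1), dc, 2)
    n_verts = int(u.sum())
    return n_verts - n_edges + n_faces - n_cells


def digital_invariants(mask):
    """(#fg 6-components, #bg 26-components, chi of the background complex).

    For the (6, 26) pair the background's cubical complex is the faithful
    continuous analog, so its Euler characteristic captures the foreground's
    handles by Alexander duality: a connected, cavity-free, genus-g 6-object
    inside a solid box leaves a background of chi = 2 - 2g.
    """
    s6 = ndimage.generate_binary_structure(3, 1)
    s26 = ndimage.generate_binary_structure(3, 3)
    _, n_fg = ndimage.label(mask, structure=s6)
    bg = np.pad(~np.asarray(mask, bool), 1, constant_values=True)
    _, n_bg = ndimage.label(bg, structure=s26)
    return n_fg, n_bg, complex_euler_characteristic(bg)


class TestSimplePoints:
    @staticmethod
    def _t_numbers_reference(nb):
        """Independent topological numbers from first principles (union-find)."""
        from itertools import product

        def components(pts, adjacent):
            parent = {p: p for p in pts}

            def find(p):
                while parent[p] != p:
                    p = parent[p]
                return p

            for a in pts:
                for b in pts:
                    if a < b and adjacent(a, b):
                        ra, rb = find(a), find(b)
                        if ra != rb:
                            parent[ra] = rb
            comps = {}
            for p in pts:
                comps.setdefault(find(p), []).append(p)
            return list(comps.values())

        fg18 = [
            p for p in product(range(3), repeat=3)
            if p != (1, 1, 1) and nb[p] and sum(abs(c - 1) for c in p) <= 2
        ]
        six = lambda a, b: sum(abs(x - y) for x, y in zip(a, b)) == 1
        t6 = sum(
            any(sum(abs(c - 1) for c in p) == 1 for p in comp)
            for comp in components(fg18, six)
        )
        bg26 = [p for p in product(range(3), repeat=3) if p != (1, 1, 1) and not nb[p]]
        cheb = lambda a, b: max(abs(x - y) for x, y in zip(a, b)) == 1
        t26_bg = len(components(bg26, cheb))
        return t6, t26_bg

    def test_kernel_matches_independent_t_numbers(self):
        """Simple iff T6(fg) == 1 and T26(bg) == 1, recomputed independently."""
        rng = np.random.default_rng(11)
        n_simple = n_not = 0
        for _ in range(400):
            nb = rng.random((3, 3, 3)) < rng.uniform(0.2, 0.8)
            nb[1, 1, 1] = False
            t6, t26_bg = self._t_numbers_reference(nb)
            expected = t6 == 1 and t26_bg == 1
            got = bool(is_simple_point(np.ascontiguousarray(nb).reshape(27), 6))
            assert got == expected, f"config:\n{nb.astype(int)}"
            n_simple += got
            n_not += not got
        assert n_simple > 20 and n_not > 20

    def test_simple_flips_preserve_digital_invariants(self):
        """Adding a simple point never changes component counts or chi."""
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(300):
            nb = rng.random((3, 3, 3)) < rng.uniform(0.2, 0.8)
            nb[1, 1, 1] = False
            if not is_simple_point(np.ascontiguousarray(nb).reshape(27), 6):
                continue
            grid = np.zeros((5, 5, 5), dtype=bool)
            grid[1:4, 1:4, 1:4] = nb
            before = digital_invariants(grid)
            grid[2, 2, 2] = True
            assert digital_invariants(grid) == before
            checked += 1
        assert checked > 20

    def test_isolated_addition_not_simple(self):
        nb = np.zeros(27, dtype=bool)
        assert not is_simple_point(nb, 6)

    def test_face_neighbor_simple(self):
        nb = np.zeros((3, 3, 3), dtype=bool)
        nb[0, 1, 1] = True
        assert is_simple_point(np.ascontiguousarray(nb).reshape(27), 6)


class TestCorrectTopology:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="incompatible"):
            DigitalTopologyConfig(6, 6)

    def test_clean_sphere_unchanged(self):
        ls = sphere_levelset()
        out = correct_topology(ls, CFG6)
        assert np.array_equal(out.data, ls.data)

    def test_torus_becomes_genus_zero(self):
        lsc = correct_topology(torus_levelset(), CFG6)
        n_fg, n_bg, chi = digital_invariants(lsc.data < 0)
        assert (n_fg, n_bg, chi) == (1, 1, 2)  # a digital ball
        mesh = extract_surface(lsc, CFG6, correct=False)
        assert mesh.euler_characteristic() == 2
        assert mesh.is_edge_manifold() and mesh.is_oriented()

    def test_cavity_filled(self):
        n = 24
        idx = np.indices((n, n, n)).astype(float)
        c = (n - 1) / 2
        r = np.sqrt(((idx - c) ** 2).sum(axis=0))
        shell = np.maximum(r - 9.0, 5.0 - r)  # hollow sphere
        lsc = correct_topology(levelset_of(np.clip(shell, -8, 8)), CFG6)
        assert lsc.data[int(c), int(c), int(c)] < 0  # interior now inside
        assert digital_invariants(lsc.data < 0)[1] == 1  # no enclosed background

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        f = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 1.5)
        ls = levelset_of(-(f - np.quantile(f, 0.7)))
        once = correct_topology(ls, CFG6)
        twice = correct_topology(once, CFG6)
        assert np.array_equal(once.data < 0, twice.data < 0)
        assert np.allclose(once.data, twice.data)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            correct_topology(levelset_of(np.ones((8, 8, 8))), CFG6)

    @pytest.mark.parametrize("cfg", [CFG6, CFG26], ids=["fg6", "fg26"])
    def test_random_fields_corrected_to_ball(self, cfg):
        """Exhaustive oracle on <= 16^3 grids: corrected region is a ball."""
        rng = np.random.default_rng(21)
        for _ in range(8):
            f = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 1.5)
            phi = -(f - np.quantile(f, 0.7))
            lsc = correct_topology(levelset_of(phi), cfg)
            region = lsc.data < 0
            s = ndimage.generate_binary_structure(
                3, 1 if cfg.foreground_connectivity == 6 else 3
            )
            _, n_fg = ndimage.label(region, structure=s)
            sb = ndimage.generate_binary_structure(
                3, 3 if cfg.background_connectivity == 26 else 1
            )
            _, n_bg = ndimage.label(
                np.pad(~region, 1, constant_values=True), structure=sb
            )
            assert n_fg == 1 and n_bg == 1
            if cfg is CFG6:
                assert digital_invariants(region) == (1, 1, 2)


class TestExtractSurface:
    def test_planar_levelset_exact(self):
        idx = np.indices((10, 10, 10)).astype(float)
        mesh = extract_surface(levelset_of(idx[2] - 5.5), CFG6, correct=False)
        assert np.all(mesh.vertices[:, 2] == 5.5)

    def test_sphere_area_and_volume(self):
        mesh = extract_surface(sphere_levelset(n=32, radius=8.0), CFG6, correct=False)
        assert mesh.area() == pytest.approx(4 * math.pi * 64, rel=0.02)
        assert mesh.enclosed_volume() == pytest.approx(4 / 3 * math.pi * 512, rel=0.02)

    def test_agrees_with_classic_marching_cubes_on_smooth_field(self):
        """Independent cross-check against scikit-image on unambiguous data."""
        from skimage import measure

        ls = sphere_levelset(n=32, radius=8.0)
        mine = extract_surface(ls, CFG6, correct=False)
        verts, faces, _, _ = measure.marching_cubes(ls.data, level=0.0)
        ref = SurfaceMesh(vertices=verts, faces=faces.astype(np.int64))
        assert mine.area() == pytest.approx(ref.area(), rel=0.01)
        assert abs(mine.enclosed_volume()) == pytest.approx(
            abs(ref.enclosed_volume()), rel=0.01
        )

    def test_no_zero_crossing_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            extract_surface(levelset_of(np.full((8, 8, 8), 3.0)), CFG6, correct=False)

    def test_sign_flip_inverts_orientation(self):
        ls = sphere_levelset(n=32, radius=8.0)
        pos = extract_surface(ls, CFG6, correct=False)
        neg = extract_surface(
            levelset_of(-np.asarray(ls.data)), CFG6, correct=False
        )
        assert pos.enclosed_volume() == pytest.approx(-neg.enclosed_volume(), rel=1e-9)
        assert np.allclose(
            np.sort(pos.vertices.ravel()), np.sort(neg.vertices.ravel())
        )

    def test_translation_equivariance(self):
        ls = sphere_levelset(n=32, radius=8.0)
        t = np.array([2.5, -1.0, 4.0])
        shifted_affine = ls.affine.copy()
        shifted_affine[:3, 3] += t
        shifted = LevelSet(
            volume=Volume(data=ls.data.copy(), affine=shifted_affine),
            truncation=ls.truncation,
        )
        a = extract_surface(ls, CFG6, correct=False)
        b = extract_surface(shifted, CFG6, correct=False)
        assert np.allclose(a.vertices + t, b.vertices)

    def test_connectivity_rule_on_diagonal_pair(self):
        data = np.ones((6, 6, 6))
        data[2, 2, 2] = -1.0
        data[3, 3, 3] = -1.0
        ls = levelset_of(data)
        two = extract_surface(ls, CFG6, correct=False)
        one = extract_surface(ls, CFG26, correct=False)
        assert two.euler_characteristic() == 4  # two separate components
        assert one.euler_characteristic() == 2  # 26-connected single object

    def test_random_binary_fields_always_watertight(self):
        rng = np.random.default_rng(9)
        for cfg in (CFG6, CFG26):
            for _ in range(15):
                data = np.where(rng.random((8, 8, 8)) < 0.4, -1.0, 1.0)
                mesh = extract_surface(
                    levelset_of(data), cfg, correct=False, pad_boundary=True
                )
                assert mesh.is_edge_manifold()
                assert mesh.is_oriented()


class TestSmoothSurface:
    def test_zero_iterations_identity(self, one_phantom):
        mesh = one_phantom.white_mesh
        out = smooth_surface(mesh, 0)
        assert np.array_equal(out.vertices, mesh.vertices)
        assert np.array_equal(out.faces, mesh.faces)

    def test_sphere_volume_nearly_preserved(self):
        mesh = extract_surface(sphere_levelset(n=32, radius=8.0), CFG6, correct=False)
        out = smooth_surface(mesh, 10)
        assert abs(out.enclosed_volume() - mesh.enclosed_volume()) < 0.01 * abs(
            mesh.enclosed_volume()
        )

    def test_topology_unchanged(self, one_phantom):
        mesh = one_phantom.white_mesh
        out = smooth_surface(mesh, 25)
        assert out.euler_characteristic() == mesh.euler_characteristic()
        assert out.n_faces == mesh.n_faces

    def test_invalid_lambda_rejected(self, one_phantom):
        with pytest.raises(ValueError, match="lambda"):
            smooth_surface(one_phantom.white_mesh, 5, lam=1.5)
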