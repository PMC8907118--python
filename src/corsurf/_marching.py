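"""Connectivity-consistent marching cubes.

Standard marching cubes resolves ambiguous cell faces with per-cell
floating-point tests (asymptotic decider / trilinear topology), which can
contradict the digital topology a correction step just enforced.  Here the
256-case triangle tables are *generated* from the chosen digital connectivity
pair: on a checkerboard face the inside corners are separated when the
foreground connectivity is 6 and connected when it is 26, always.  Cell-face
segment patterns therefore depend only on corner signs, adjacent cells agree
by construction, and the output is watertight and orientation-consistent with
no per-cell disambiguation.

Within one cell, face segments are linked into closed cycles and grouped by
the inside-corner component they bound.  A component bounded by one cycle is
triangulated as a fan.  A component bounded by two cycles (a corner loop
threading the cell) is a tunnel and is triangulated as a tube routed through
two interior Steiner vertices; this preserves the digital genus and — unlike
a direct strip between the cycles — never creates a triangle edge lying
inside a cell face, which a neighboring cell could duplicate.

The 26-connected foreground case is handled by duality: the (26, 6) surface
of ``phi`` is the (6, 26) surface of ``-phi`` with reversed orientation.

Corner c has coordinates ``(c & 1, c >> 1 & 1, c >> 2 & 1)``; "inside" means
a negative level-set value.  Triangles are wound so normals point outward.
"""

from __future__ import annotations

from collections import Counter
from functools import lru_cache

import numpy as np

__all__ = ["marching_tables", "extract_mesh"]

_CORNER_XYZ = np.array([(c & 1, (c >> 1) & 1, (c >> 2) & 1) for c in range(8)])

# 12 cube edges as (corner_a, corner_b), grouped by axis (x: 0-3, y: 4-7, z: 8-11)
_EDGES = [
    (0, 1), (2, 3), (4, 5), (6, 7),
    (0, 2), (1, 3), (4, 6), (5, 7),
    (0, 4), (1, 5), (2, 6), (3, 7),
]
_EDGE_INDEX = {e: i for i, e in enumerate(_EDGES)}
# local edge id -> (axis, base-corner offset)
_EDGE_AXIS_OFFSET = [
    (0 if i < 4 else (1 if i < 8 else 2), tuple(_CORNER_XYZ[a]))
    for i, (a, b) in enumerate(_EDGES)
]
_INTERIOR_BASE = 12  # local ids >= 12 denote per-cell interior Steiner points
_MAX_INTERIOR = 4


def _faces():
    """Six faces: cyclic corner order CCW as seen from outside the cube."""
    out = []
    for axis in range(3):
        u, v = (axis + 1) % 3, (axis + 2) % 3  # u x v = +axis
        for side in (0, 1):
            corners = []
            for qu, qv in [(0, 0), (1, 0), (1, 1), (0, 1)]:
                xyz = [0, 0, 0]
                xyz[axis] = side
                xyz[u], xyz[v] = qu, qv
                corners.append(int(np.dot(xyz, [1, 2, 4])))
            if side == 0:  # outside is the -axis direction: reverse to keep CCW
                corners = corners[::-1]
            out.append(corners)
    return out

_FACES = _faces()

_FACE_QUAD2D = np.array([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])


def _face_segments(flags, separate_inside):
    """Directed cut-edge segments for one face.

    ``flags``: inside flags of the 4 cyclic corners.  Segments are directed so
    that the inside region lies on the LEFT when the face is viewed from
    outside the cube.  ``separate_inside`` fixes the checkerboard case.
    """
    cut = [i for i in range(4) if flags[i] != flags[(i + 1) % 4]]
    if not cut:
        return []
    inside = [i for i in range(4) if flags[i]]
    if len(inside) == 2 and inside[1] - inside[0] == 2:  # checkerboard
        isolate = inside if separate_inside else [i for i in range(4) if not flags[i]]
        pairs = [((i - 1) % 4, i) for i in isolate]  # edges flanking each corner
    else:
        pairs = [(cut[0], cut[1])]

    segs = []
    for e1, e2 in pairs:
        p1 = 0.5 * (_FACE_QUAD2D[e1] + _FACE_QUAD2D[(e1 + 1) % 4])
        p2 = 0.5 * (_FACE_QUAD2D[e2] + _FACE_QUAD2D[(e2 + 1) % 4])
        # orient: the inside endpoint of cut edge e1 must lie left of the
        # directed segment (unique — each cut edge has one inside endpoint)
        ins = e1 if flags[e1] else (e1 + 1) % 4
        d = p2 - p1
        w = _FACE_QUAD2D[ins] - p1
        if d[0] * w[1] - d[1] * w[0] >= 0:
            segs.append((e1, e2))
        else:
            segs.append((e2, e1))
    return segs


def _corner_components(config, fg_connectivity):
    """Union inside corners by digital adjacency within the cube."""
    inside = [c for c in range(8) if config >> c & 1]
    parent = {c: c for c in inside}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a in inside:
        for b in inside:
            if a >= b:
                continue
            diff = bin(a ^ b).count("1")
            if fg_connectivity == 6 and diff != 1:
                continue
            parent[find(a)] = find(b)
    return {c: find(c) for c in inside}


def _cycles_for_config(config, fg_connectivity):
    """Closed cut-edge cycles (lists of local edge ids), per face rules."""
    flags8 = [bool(config >> c & 1) for c in range(8)]
    separate_inside = fg_connectivity == 6
    succ = {}
    for face in _FACES:
        fflags = [flags8[c] for c in face]
        for s1, s2 in _face_segments(fflags, separate_inside):
            def edge_id(slot):
                a, b = face[slot], face[(slot + 1) % 4]
                return _EDGE_INDEX[(min(a, b), max(a, b))]
            succ[edge_id(s1)] = edge_id(s2)
    cycles = []
    remaining = dict(succ)
    while remaining:
        start = min(remaining)
        cyc = [start]
        nxt = remaining.pop(start)
        while nxt != start:
            cyc.append(nxt)
            nxt = remaining.pop(nxt)
        cycles.append(cyc[::-1])  # outward winding (normals away from inside)
    return cycles


def _fan(cycle):
    return [(cycle[0], cycle[i], cycle[i + 1]) for i in range(1, len(cycle) - 1)]


def _strip(ca, cb):
    """Zip two cycles into a triangle strip (annulus); cb traversed reversed."""
    cb = cb[::-1]
    n, m = len(ca), len(cb)
    tris = []
    i = j = 0
    while i < n or j < m:
        if j == m or (i < n and i * m <= j * n):
            tris.append((ca[i % n], ca[(i + 1) % n], cb[j % m]))
            i += 1
        else:
            tris.append((cb[j % m], ca[i % n], cb[(j + 1) % m]))
            j += 1
    return tris


def _patch_is_consistent(tris, cycles):
    """Each cycle's directed boundary edge once; all other edges balanced."""
    count = Counter()
    for a, b, c in tris:
        for e in ((a, b), (b, c), (c, a)):
            count[e] += 1
    if any(v != 1 for v in count.values()):
        return False
    boundary = {
        (cyc[i], cyc[(i + 1) % len(cyc)]) for cyc in cycles for i in range(len(cyc))
    }
    for e in count:
        rev = (e[1], e[0])
        if e in boundary:
            if rev in count:
                return False
        elif rev not in count:
            return False
    return True


def _tube_via_interior(ca, cb, ring):
    """Annulus between two cycles glued along an interior 3-vertex ring."""
    for r1 in (list(ring), list(ring)[::-1]):
        for r2 in (list(ring), list(ring)[::-1]):
            cand = _strip(ca, r1) + _strip(r2, cb)
            if _patch_is_consistent(cand, [ca, cb]):
                return cand
    raise AssertionError("no consistent tube triangulation found")  # pragma: no cover


def _config_triangles(config, fg_connectivity):
    """Triangles (local ids) and interior-vertex definitions for one config."""
    cycles = _cycles_for_config(config, fg_connectivity)
    if not cycles:
        return [], []
    comp_of_corner = _corner_components(config, fg_connectivity)

    def cycle_component(cyc):
        comps = set()
        for e in cyc:
            a, b = _EDGES[e]
            fg_corner = a if (config >> a & 1) else b
            comps.add(comp_of_corner[fg_corner])
        if len(comps) != 1:  # pragma: no cover - cannot happen for cut edges
            raise AssertionError(f"cycle spans components in config {config}")
        return comps.pop()

    groups: dict[int, list] = {}
    for cyc in cycles:
        groups.setdefault(cycle_component(cyc), []).append(cyc)

    tris = []
    interiors: list[tuple] = []
    for comp_cycles in groups.values():
        if len(comp_cycles) == 1:
            cyc = comp_cycles[0]
            if len(cyc) == 3:
                tris += _fan(cyc)
            else:
                # centroid fan: a direct fan can put a chord inside a cell
                # face, which the neighboring cell may duplicate (non-manifold
                # edge); a per-cell Steiner vertex at the cycle centroid never
                # collides and keeps planar level sets exactly planar
                apex = _INTERIOR_BASE + len(interiors)
                interiors.append((tuple(cyc), tuple(cyc), 0.5, False))
                tris += [
                    (apex, cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))
                ]
        elif len(comp_cycles) == 2:
            ca, cb = comp_cycles
            ring = []
            for w in (0.0, 0.5, 1.0):
                ring.append(_INTERIOR_BASE + len(interiors))
                interiors.append((tuple(ca), tuple(cb), w, True))
            tris += _tube_via_interior(ca, cb, ring)
        else:  # pragma: no cover - not reachable for cube corner subsets
            for cyc in comp_cycles:
                tris += _fan(cyc)
    if len(interiors) > _MAX_INTERIOR:  # pragma: no cover
        raise AssertionError("interior vertex budget exceeded")
    return tris, interiors


@lru_cache(maxsize=4)
def marching_tables(fg_connectivity: int):
    """Triangle tables for all 256 corner-sign configurations.

    Returns ``{config: (triangles, interiors)}`` where triangles is an
    ``(t, 3)`` array of local ids (0-11 cube edges, >= 12 interior Steiner
    vertices) and ``interiors[k] = (cycle_a, cycle_b, w)`` parametrizes
    Steiner vertex ``12 + k`` between the two tube cycles' centroids.
    """
    if fg_connectivity not in (6, 26):
        raise ValueError("fg_connectivity must be 6 or 26")
    tables = {}
    for config in range(1, 255):
        tris, interiors = _config_triangles(config, fg_connectivity)
        if tris:
            tables[config] = (np.array(tris, dtype=np.int64), interiors)
    return tables


def extract_mesh(
    data: np.ndarray,
    affine: np.ndarray,
    fg_connectivity: int = 6,
    pad_boundary: bool = False,
):
    """Extract the zero isosurface of ``data`` (inside < 0) in world mm.

    Returns ``(vertices, faces)``; vertices lie on grid edges at the
    linear-interpolation zero crossing (except tunnel-cell Steiner points).
    Grid values exactly zero are treated as infinitesimally outside.  With
    ``pad_boundary`` the level set is treated as positive beyond its domain,
    so a region touching the grid border still yields a closed surface;
    without it such a surface is left open.
    """
    data = np.asarray(data, dtype=np.float64)
    scale = np.abs(data).max()
    if scale == 0:
        raise ValueError("level set is identically zero")
    data = np.where(data == 0, 1e-9 * scale, data)
    pad = 0
    if pad_boundary:
        data = np.pad(data, 1, mode="constant", constant_values=scale)
        pad = 1
    # duality: the 26-connected foreground surface of phi is the 6-connected
    # foreground surface of -phi with reversed orientation
    flip = fg_connectivity == 26
    if flip:
        data = -data
        fg_connectivity = 6
    inside = data < 0

    n0, n1, n2 = data.shape
    conf = np.zeros((n0 - 1, n1 - 1, n2 - 1), dtype=np.uint8)
    for c in range(8):
        ox, oy, oz = _CORNER_XYZ[c]
        conf |= (
            inside[ox : ox + n0 - 1, oy : oy + n1 - 1, oz : oz + n2 - 1].astype(np.uint8)
            << c
        )

    tables = marching_tables(fg_connectivity)
    nvox = n0 * n1 * n2
    interior_offset = 3 * nvox

    def edge_vertex_pos(edge_local, ii, jj, kk):
        """Interpolated crossing position (index coords) for one local edge."""
        axis, (ox, oy, oz) = _EDGE_AXIS_OFFSET[edge_local]
        ai, aj, ak = ii + ox, jj + oy, kk + oz
        bi, bj, bk = ai.copy(), aj.copy(), ak.copy()
        (bi, bj, bk)[axis][:] += 1
        pa = data[ai, aj, ak]
        pb = data[bi, bj, bk]
        t = pa / (pa - pb)
        pos = np.stack([ai, aj, ak], axis=1).astype(np.float64)
        pos[:, axis] += t
        return pos

    tri_chunks = []
    interior_gids = []
    interior_pos = []
    for config in np.unique(conf):
        config = int(config)
        if config in (0, 255) or config not in tables:
            continue
        ii, jj, kk = np.nonzero(conf == config)
        cell_lin = (ii * n1 + jj) * n2 + kk
        tris, interiors = tables[config]
        gid = np.empty((len(tris), 3, len(ii)), dtype=np.int64)
        for r in range(len(tris)):
            for col in range(3):
                le = int(tris[r, col])
                if le < _INTERIOR_BASE:
                    axis, (ox, oy, oz) = _EDGE_AXIS_OFFSET[le]
                    lin = ((ii + ox) * n1 + (jj + oy)) * n2 + (kk + oz)
                    gid[r, col] = axis * nvox + lin
                else:
                    gid[r, col] = (
                        interior_offset + cell_lin * _MAX_INTERIOR + (le - _INTERIOR_BASE)
                    )
        tri_chunks.append(gid.transpose(2, 0, 1).reshape(-1, 3))
        for k_int, (cyc_a, cyc_b, w, pull) in enumerate(interiors):
            cen_a = np.mean([edge_vertex_pos(e, ii, jj, kk) for e in cyc_a], axis=0)
            cen_b = np.mean([edge_vertex_pos(e, ii, jj, kk) for e in cyc_b], axis=0)
            centroid = (1.0 - w) * cen_a + w * cen_b
            if pull:  # tube ring vertices must sit strictly inside the cell
                center = np.stack([ii + 0.5, jj + 0.5, kk + 0.5], axis=1)
                centroid = 0.5 * (centroid + center)
            interior_gids.append(
                interior_offset + cell_lin * _MAX_INTERIOR + k_int
            )
            interior_pos.append(centroid)
    if not tri_chunks:
        raise ValueError("no zero crossing in level set")
    tri_ids = np.concatenate(tri_chunks, axis=0)

    uniq, faces = np.unique(tri_ids, return_inverse=True)
    faces = faces.reshape(tri_ids.shape)

    pos_idx = np.empty((len(uniq), 3), dtype=np.float64)
    is_edge = uniq < interior_offset
    eids = uniq[is_edge]
    axis = eids // nvox
    lin = eids % nvox
    vi = lin // (n1 * n2)
    vj = (lin // n2) % n1
    vk = lin % n2
    base = np.stack([vi, vj, vk], axis=1).astype(np.float64)
    step = np.zeros_like(base)
    step[np.arange(len(eids)), axis] = 1.0
    other = (base + step).astype(np.int64)
    phi_a = data[vi, vj, vk]
    phi_b = data[other[:, 0], other[:, 1], other[:, 2]]
    t = phi_a / (phi_a - phi_b)
    pos_idx[is_edge] = base + t[:, None] * step
    if not np.all(is_edge):
        gids = np.concatenate(interior_gids)
        poss = np.concatenate(interior_pos, axis=0)
        order = np.argsort(gids)
        lookup = np.searchsorted(gids[order], uniq[~is_edge])
        pos_idx[~is_edge] = poss[order][lookup]

    A = np.asarray(affine, dtype=np.float64)
    verts = (pos_idx - pad) @ A[:3, :3].T + A[:3, 3]
    if flip:
        faces = faces[:, ::-1]
    return verts, faces
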