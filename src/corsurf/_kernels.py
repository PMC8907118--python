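"""Numba kernels for exact point-triangle distance queries.

The scalar closest-point-on-triangle routine follows the Voronoi-region
case analysis (Ericson); the pair kernel reduces variable-length candidate
lists (sorted by query point) to the per-point minimum in one pass.
"""

import numba
import numpy as np

__all__ = ["pair_min_distance", "column_parity"]


@numba.njit(cache=True, fastmath=False)
def _closest_on_tri(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return ax + v * abx, ay + v * aby, az + v * abz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return ax + w * acx, ay + w * acy, az + w * acz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return bx + w * (cx - bx), by + w * (cy - by), bz + w * (cz - bz)
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    return (
        ax + abx * v + acx * w,
        ay + aby * v + acy * w,
        az + abz * v + acz * w,
    )


@numba.njit(cache=True)
def pair_min_distance(points, tri, pt_idx, face_idx):
    """Minimum distance per query point over candidate (point, face) pairs.

    ``pt_idx`` must be nondecreasing and every point in ``range(len(points))``
    must appear at least once.  Returns squared distances, closest points and
    winning face ids.
    """
    n = points.shape[0]
    best_d2 = np.full(n, np.inf)
    best_face = np.full(n, -1, dtype=np.int64)
    best_cp = np.zeros((n, 3))
    for k in range(pt_idx.shape[0]):
        i = pt_idx[k]
        f = face_idx[k]
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        qx, qy, qz = _closest_on_tri(
            px, py, pz,
            tri[f, 0, 0], tri[f, 0, 1], tri[f, 0, 2],
            tri[f, 1, 0], tri[f, 1, 1], tri[f, 1, 2],
            tri[f, 2, 0], tri[f, 2, 1], tri[f, 2, 2],
        )
        d2 = (px - qx) ** 2 + (py - qy) ** 2 + (pz - qz) ** 2
        if d2 < best_d2[i]:
            best_d2[i] = d2
            best_face[i] = f
            best_cp[i, 0] = qx
            best_cp[i, 1] = qy
            best_cp[i, 2] = qz
    return best_d2, best_cp, best_face


@numba.njit(cache=True)
def column_parity(origins, d, v0, e1, e2, nk, step):
    """Even-odd inside classification for voxel columns.

    Each origin is the world position of voxel (i, j, 0); voxel k lies at
    parameter ``k * step`` along unit direction ``d``.  Returns a boolean
    (n_columns, nk) array: voxel is inside iff an odd number of ray-triangle
    crossings lie strictly beyond it (Möller–Trumbore, half-open rule).
    """
    m = v0.shape[0]
    ncol = origins.shape[0]
    pvx = np.empty(m)
    pvy = np.empty(m)
    pvz = np.empty(m)
    inv_det = np.empty(m)
    ok = np.empty(m, dtype=np.bool_)
    for f in range(m):
        px = d[1] * e2[f, 2] - d[2] * e2[f, 1]
        py = d[2] * e2[f, 0] - d[0] * e2[f, 2]
        pz = d[0] * e2[f, 1] - d[1] * e2[f, 0]
        det = e1[f, 0] * px + e1[f, 1] * py + e1[f, 2] * pz
        ok[f] = abs(det) > 1e-14
        inv_det[f] = 1.0 / det if ok[f] else 0.0
        pvx[f], pvy[f], pvz[f] = px, py, pz

    inside = np.zeros((ncol, nk), dtype=np.bool_)
    cnt = np.zeros(nk + 1, dtype=np.int64)
    for c in range(ncol):
        cnt[:] = 0
        ox, oy, oz = origins[c, 0], origins[c, 1], origins[c, 2]
        any_hit = False
        for f in range(m):
            if not ok[f]:
                continue
            tx = ox - v0[f, 0]
            ty = oy - v0[f, 1]
            tz = oz - v0[f, 2]
            u = (tx * pvx[f] + ty * pvy[f] + tz * pvz[f]) * inv_det[f]
            if u < 0.0 or u > 1.0:
                continue
            qx = ty * e1[f, 2] - tz * e1[f, 1]
            qy = tz * e1[f, 0] - tx * e1[f, 2]
            qz = tx * e1[f, 1] - ty * e1[f, 0]
            v = (d[0] * qx + d[1] * qy + d[2] * qz) * inv_det[f]
            if v < 0.0 or u + v >= 1.0:
                continue
            t = (e2[f, 0] * qx + e2[f, 1] * qy + e2[f, 2] * qz) * inv_det[f]
            if t <= 1e-12:
                continue
            kmax = int(np.ceil(t / step - 1e-12))
            if kmax > nk:
                kmax = nk
            cnt[kmax] += 1
            any_hit = True
        if not any_hit:
            continue
        beyond = 0
        for k in range(nk - 1, -1, -1):
            beyond += cnt[k + 1]
            inside[c, k] = (beyond % 2) == 1
    return inside


@numba.njit(cache=True)
def _component_count(cells, use18, six_adjacency, require_center_adjacent):
    """Count connected components of True cells in a 3x3x3 neighborhood.

    ``cells`` is a flat length-27 boolean array indexed by 9*x + 3*y + z.
    The center (index 13) is always excluded.  ``use18`` restricts the domain
    to the 18-neighborhood (no corners); ``six_adjacency`` selects 6- vs
    26-adjacency between cells; ``require_center_adjacent`` counts only
    components containing a 6-neighbor of the center.
    """
    in_domain = np.zeros(27, dtype=np.bool_)
    for i in range(27):
        if i == 13 or not cells[i]:
            continue
        dx = i // 9 - 1
        dy = (i // 3) % 3 - 1
        dz = i % 3 - 1
        manh = abs(dx) + abs(dy) + abs(dz)
        if use18 and manh > 2:
            continue
        in_domain[i] = True
    visited = np.zeros(27, dtype=np.bool_)
    stack = np.empty(27, dtype=np.int64)
    n_comp = 0
    for start in range(27):
        if not in_domain[start] or visited[start]:
            continue
        # BFS/DFS over this component
        top = 0
        stack[top] = start
        top += 1
        visited[start] = True
        touches_center = False
        while top > 0:
            top -= 1
            i = stack[top]
            xi = i // 9
            yi = (i // 3) % 3
            zi = i % 3
            if abs(xi - 1) + abs(yi - 1) + abs(zi - 1) == 1:
                touches_center = True
            for j in range(27):
                if visited[j] or not in_domain[j]:
                    continue
                ddx = abs(j // 9 - xi)
                ddy = abs((j // 3) % 3 - yi)
                ddz = abs(j % 3 - zi)
                if max(ddx, ddy, ddz) != 1:
                    continue
                if six_adjacency and ddx + ddy + ddz != 1:
                    continue
                visited[j] = True
                stack[top] = j
                top += 1
        if (not require_center_adjacent) or touches_center:
            n_comp += 1
    return n_comp


@numba.njit(cache=True)
def is_simple_point(nbhd, fg_connectivity):
    """Simple-point test on a flat 27-cell foreground neighborhood.

    For the compatible pair (6, 26): simple iff T6(fg) == 1 and T26(bg) == 1;
    for (26, 6): simple iff T26(fg) == 1 and T6(bg) == 1, with T6 counting
    6-components in the 18-neighborhood that are 6-adjacent to the center and
    T26 counting 26-components in the 26-neighborhood.
    """
    bg = np.empty(27, dtype=np.bool_)
    for i in range(27):
        bg[i] = not nbhd[i]
    if fg_connectivity == 6:
        t_fg = _component_count(nbhd, True, True, True)
        t_bg = _component_count(bg, False, False, False)
    else:
        t_fg = _component_count(nbhd, False, False, False)
        t_bg = _component_count(bg, True, True, True)
    return t_fg == 1 and t_bg == 1
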