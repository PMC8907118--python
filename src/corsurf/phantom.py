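"""Synthetic brain phantoms with exact ground truth.

A phantom is a two-tissue "brain": a folded genus-0 inner ("white") surface
built as a radially perturbed sphere, an outer ("pial") surface obtained by
displacing the white surface outward along its vertex normals by a known
cortical thickness, the exact signed-distance level sets of both, a tissue
label volume, and a T1-like intensity image with a smooth multiplicative bias
field and additive Gaussian noise.  Because every quantity is known in closed
form (true thickness, true surfaces, true level sets), phantoms serve as
ground truth for the full reconstruction and evaluation pipeline.

Folding is band-limited: the white surface radius is
``r(theta, phi) = R + a * f(theta, phi) / max|f|`` where ``f`` is a random
spherical-harmonic series over degrees ``2..fold_degree``, so the surface is
genus 0 by construction and the fold scale is controlled by one amplitude.

Randomness is organized as named streams derived from one integer seed
(harmonic coefficients / bias field / noise / parcellation), so sub-results
are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import trimesh
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.special import sph_harm_y

from .io_formats import LabelMap, SurfaceMesh, Volume
from .levelset import DEFAULT_TRUNCATION, LevelSet, encode_levelset

__all__ = [
    "PhantomParams",
    "Phantom",
    "HemisphereTruth",
    "generate_phantom",
    "phantom_sessions",
    "phantom_parcellation",
]

_STREAMS = {"harmonics": 0, "bias": 1, "noise": 2, "parcellation": 3}

# tissue label codes: background 0; per hemisphere (left, right): GM, WM
GM_LEFT, WM_LEFT, GM_RIGHT, WM_RIGHT = 1, 2, 3, 4


def _stream(seed: int, name: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[name], *map(int, extra)])


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters; defaults describe a desk-scale 1 mm phantom."""

    grid_shape: tuple = (48, 48, 48)
    voxel_size: float = 1.0  # mm, isotropic
    base_radius: float = 14.0  # mm
    fold_amplitude: float = 3.0  # mm
    fold_degree: int = 6  # spherical-harmonic band limit
    cortical_thickness_true: float = 2.5  # mm
    intensity_means: tuple = (10.0, 70.0, 110.0)  # background, GM, WM
    noise_sd: float = 5.0  # intensity units
    bias_field_amplitude: float = 0.1  # fraction of the tissue mean
    n_hemispheres: int = 1
    mesh_subdivisions: int = 4  # icosphere refinement level
    truncation: float = DEFAULT_TRUNCATION  # mm, level-set clamp

    def __post_init__(self):
        if self.fold_amplitude < 0:
            raise ValueError("fold_amplitude must be >= 0")
        if self.fold_amplitude >= self.base_radius / 2:
            raise ValueError("fold_amplitude must be < base_radius / 2")
        if self.cortical_thickness_true <= self.voxel_size:
            raise ValueError("cortical_thickness_true must exceed voxel_size")
        if self.n_hemispheres not in (1, 2):
            raise ValueError("n_hemispheres must be 1 or 2")
        if self.fold_amplitude > 0 and self.fold_degree < 2:
            raise ValueError("fold_degree must be >= 2 when fold_amplitude > 0")

    @property
    def outer_radius(self) -> float:
        return self.base_radius + self.fold_amplitude + self.cortical_thickness_true

    def hemisphere_centers(self) -> list[np.ndarray]:
        extent = np.array(self.grid_shape, float) * self.voxel_size
        center = extent / 2.0
        if self.n_hemispheres == 1:
            centers = [center]
        else:
            # two disjoint blobs offset along x with a gap >= 4 voxels
            dx = self.outer_radius + 2.0 * self.voxel_size
            centers = [center - np.array([dx, 0, 0]), center + np.array([dx, 0, 0])]
        margin = 3.0 * self.voxel_size
        for c in centers:
            if np.any(c - self.outer_radius < margin) or np.any(
                c + self.outer_radius > extent - margin
            ):
                raise ValueError(
                    "grid too small: phantom needs base_radius + fold_amplitude + "
                    "cortical_thickness_true plus a 3-voxel margin"
                )
        return centers


class HemisphereTruth:
    """One hemisphere's ground truth; level sets are encoded on first access."""

    def __init__(self, side, white_mesh, pial_mesh, grid, truncation):
        self.side = side  # "left" or "right"
        self.white_mesh = white_mesh
        self.pial_mesh = pial_mesh
        self._grid = grid
        self._truncation = truncation
        self._white_ls = None
        self._pial_ls = None

    @property
    def white_levelset(self) -> LevelSet:
        if self._white_ls is None:
            self._white_ls = encode_levelset(
                self.white_mesh, self._grid, truncation=self._truncation
            )
        return self._white_ls

    @property
    def pial_levelset(self) -> LevelSet:
        if self._pial_ls is None:
            self._pial_ls = encode_levelset(
                self.pial_mesh, self._grid, truncation=self._truncation
            )
        return self._pial_ls


class Phantom:
    """Paired synthetic ground truth: intensities, tissue labels, surfaces.

    The intensity image and tissue labels are derived lazily from the exact
    level sets, so workflows touching only the meshes never pay for encoding.
    """

    def __init__(self, params, seed, hemispheres, grid, session=None):
        self.params = params
        self.seed = int(seed)
        self.hemispheres = hemispheres
        self.grid = grid
        self.session = session  # repeated-scan index, None for a single scan
        self._tissue = None
        self._image = None

    @property
    def tissue_labels(self) -> Volume:
        if self._tissue is None:
            self._tissue = self.grid.like(_tissue_labels(self.hemispheres, self.grid))
        return self._tissue

    @property
    def image(self) -> Volume:
        if self._image is None:
            noise_stream = (
                _stream(self.seed, "noise")
                if self.session is None
                else _stream(self.seed, "noise", self.session)
            )
            self._image = self.grid.like(
                _render_image(
                    self.params,
                    self.tissue_labels.data,
                    _stream(self.seed, "bias"),
                    noise_stream,
                )
            )
        return self._image

    def _single(self) -> HemisphereTruth:
        if len(self.hemispheres) != 1:
            raise ValueError(
                "phantom has multiple hemispheres; use .hemispheres explicitly"
            )
        return self.hemispheres[0]

    @property
    def white_mesh(self) -> SurfaceMesh:
        return self._single().white_mesh

    @property
    def pial_mesh(self) -> SurfaceMesh:
        return self._single().pial_mesh

    @property
    def white_levelset(self) -> LevelSet:
        return self._single().white_levelset

    @property
    def pial_levelset(self) -> LevelSet:
        return self._single().pial_levelset

    def wm_mask(self, side: str | None = None) -> Volume:
        codes = {None: (WM_LEFT, WM_RIGHT), "left": (WM_LEFT,), "right": (WM_RIGHT,)}[side]
        return self.tissue_labels.like(
            np.isin(self.tissue_labels.data, codes).astype(np.uint8)
        )


def _grid(params: PhantomParams) -> Volume:
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = params.voxel_size
    return Volume(data=np.zeros(params.grid_shape, dtype=np.float32), affine=affine)


def _real_harmonic_series(dirs: np.ndarray, degree: int, rng: np.random.Generator):
    """Random real spherical-harmonic series over degrees 2..degree at unit dirs."""
    x, y, z = dirs.T
    theta = np.arccos(np.clip(z, -1, 1))
    phi = np.arctan2(y, x)
    total = np.zeros(len(dirs))
    for ell in range(2, degree + 1):
        for m in range(0, ell + 1):
            ylm = sph_harm_y(ell, m, theta, phi)
            if m == 0:
                total += rng.normal() * ylm.real
            else:
                total += np.sqrt(2.0) * (
                    rng.normal() * ylm.real + rng.normal() * ylm.imag
                )
    return total


def _white_mesh(params: PhantomParams, center: np.ndarray, rng) -> SurfaceMesh:
    base = trimesh.creation.icosphere(
        subdivisions=params.mesh_subdivisions, radius=1.0
    )
    dirs = np.asarray(base.vertices, dtype=np.float64)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    r = np.full(len(dirs), params.base_radius)
    if params.fold_amplitude > 0:
        f = _real_harmonic_series(dirs, params.fold_degree, rng)
        r = r + params.fold_amplitude * f / np.abs(f).max()
    verts = center[None, :] + r[:, None] * dirs
    return SurfaceMesh(vertices=verts, faces=np.asarray(base.faces, dtype=np.int64))


def _offset_pial(white: SurfaceMesh, thickness: float) -> SurfaceMesh:
    normals = white.vertex_normals()
    return SurfaceMesh(vertices=white.vertices + thickness * normals, faces=white.faces.copy())


def _build_hemisphere(
    params: PhantomParams, center: np.ndarray, grid: Volume, rng, side: str
) -> HemisphereTruth:
    tol = 1.5 * params.voxel_size
    p = params
    for attempt in range(3):
        white = _white_mesh(p, center, rng)
        pial = _offset_pial(white, p.cortical_thickness_true)
        # validity: the normal offset must not fold the pial surface back
        # through the white surface (pial vertices sit at +thickness)
        from ._geometry import SurfaceQuery

        _, d_pial, _ = SurfaceQuery(white.vertices, white.faces).query(pial.vertices)
        ok = (
            np.all(np.abs(d_pial - p.cortical_thickness_true) < tol)
            and pial.enclosed_volume() > white.enclosed_volume()
        )
        if ok:
            return HemisphereTruth(
                side=side,
                white_mesh=white,
                pial_mesh=pial,
                grid=grid,
                truncation=p.truncation,
            )
        p = replace(p, fold_amplitude=p.fold_amplitude * 0.7)
    raise RuntimeError(
        "pial surface self-intersects after normal displacement; "
        "3 amplitude-reduction attempts exhausted"
    )


def _bias_field(shape, amplitude: float, rng) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape)
    raw = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(raw, sigma=np.array(shape) / 6.0)
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * smooth / peak


def _render_image(
    params: PhantomParams, tissue: np.ndarray, bias_rng, noise_rng
) -> np.ndarray:
    bg, gm, wm = params.intensity_means
    intensity = np.full(tissue.shape, float(bg))
    intensity[np.isin(tissue, (GM_LEFT, GM_RIGHT))] = gm
    intensity[np.isin(tissue, (WM_LEFT, WM_RIGHT))] = wm
    img = intensity * _bias_field(tissue.shape, params.bias_field_amplitude, bias_rng)
    if params.noise_sd > 0:
        img = img + noise_rng.normal(scale=params.noise_sd, size=tissue.shape)
    return img.astype(np.float32)


def _tissue_labels(hemis: Sequence[HemisphereTruth], grid: Volume) -> np.ndarray:
    tissue = np.zeros(grid.shape, dtype=np.int16)
    for h in hemis:
        gm_code, wm_code = (GM_LEFT, WM_LEFT) if h.side == "left" else (GM_RIGHT, WM_RIGHT)
        inside_pial = h.pial_levelset.data < 0
        inside_white = h.white_levelset.data < 0
        tissue[inside_pial & ~inside_white] = gm_code
        tissue[inside_white] = wm_code
    return tissue


def generate_phantom(params: PhantomParams = PhantomParams(), seed: int = 0) -> Phantom:
    """Generate one phantom; deterministic for fixed ``(params, seed)``."""
    centers = params.hemisphere_centers()
    grid = _grid(params)
    harm_rng = _stream(seed, "harmonics")
    sides = ["left"] if params.n_hemispheres == 1 else ["left", "right"]
    hemis = [
        _build_hemisphere(params, c, grid, harm_rng, side)
        for c, side in zip(centers, sides)
    ]
    return Phantom(params=params, seed=seed, hemispheres=hemis, grid=grid)


def phantom_sessions(
    params: PhantomParams,
    seed: int,
    n_sessions: int,
    session_noise_sd: float | None = None,
) -> list[Phantom]:
    """Repeated "scans" of one phantom subject.

    All sessions share identical ground-truth meshes, level sets and bias
    field (subject-level properties); only the additive noise realization
    differs between sessions.
    """
    if n_sessions < 2:
        raise ValueError("n_sessions must be >= 2")
    base = generate_phantom(params, seed)
    noise_sd = params.noise_sd if session_noise_sd is None else float(session_noise_sd)
    sess_params = replace(params, noise_sd=noise_sd)
    return [
        Phantom(
            params=sess_params,
            seed=seed,
            hemispheres=base.hemispheres,
            grid=base.grid,
            session=s,
        )
        for s in range(n_sessions)
    ]


def phantom_parcellation(mesh: SurfaceMesh, n_regions: int, seed: int = 0) -> LabelMap:
    """Contiguous surface parcellation: farthest-point seeds + geodesic labels."""
    n = mesh.n_vertices
    if not 1 <= n_regions <= n:
        raise ValueError("n_regions must be between 1 and the vertex count")
    edges = np.unique(mesh.edges_sorted(), axis=0)
    w = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    graph = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([edges[:, 0], edges[:, 1]]),
                                  np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp != 1:
        raise ValueError(f"mesh is disconnected ({n_comp} components)")

    rng = _stream(seed, "parcellation")
    seeds = [int(rng.integers(n))]
    dmin = dijkstra(graph, directed=False, indices=seeds[0])
    while len(seeds) < n_regions:
        nxt = int(np.argmax(dmin))
        seeds.append(nxt)
        dmin = np.minimum(dmin, dijkstra(graph, directed=False, indices=nxt))
    _, _, sources = dijkstra(
        graph, directed=False, indices=seeds, min_only=True, return_predecessors=True
    )
    seed_to_region = {s: i for i, s in enumerate(seeds)}
    labels = np.array([seed_to_region[int(s)] for s in sources], dtype=np.int64)
    names = {i: f"region_{i:02d}" for i in range(n_regions)}
    return LabelMap(labels=labels, names=names)
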