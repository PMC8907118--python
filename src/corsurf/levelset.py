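"""Signed-distance level-set representation of surfaces.

A level set here is a truncated signed Euclidean distance sampled on a voxel
grid: negative inside the surface, zero on it, positive outside, clamped to
``+-truncation`` (mm).  Encoding a closed mesh embeds it exactly: within the
band the value at a voxel center is the true distance to the nearest point of
the mesh, signed by ray-parity inside/outside classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._geometry import SurfaceQuery, grid_inside_mask
from .io_formats import SurfaceMesh, Volume

__all__ = [
    "LevelSet",
    "DEFAULT_TRUNCATION",
    "encode_levelset",
    "resample_levelset",
    "hemisphere_split",
    "read_levelset",
    "write_levelset",
]

logger = logging.getLogger(__name__)

#: Default truncation band half-width (mm): generously covers the cortical
#: ribbon while keeping regression targets bounded.
DEFAULT_TRUNCATION = 8.0


@dataclass
class LevelSet:
    """Truncated signed-distance volume; negative inside, positive outside."""

    volume: Volume
    truncation: float

    def __post_init__(self):
        if self.truncation <= 0:
            raise ValueError("truncation must be positive (mm)")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def affine(self) -> np.ndarray:
        return self.volume.affine

    @property
    def voxel_size(self) -> np.ndarray:
        return self.volume.voxel_size

    def foreground(self) -> np.ndarray:
        """Binary inside region (phi < 0)."""
        return self.data < 0

    def band_mask(self, margin: float = 0.0) -> np.ndarray:
        return np.abs(self.data) < (self.truncation - margin)

    def with_data(self, data: np.ndarray) -> "LevelSet":
        return LevelSet(volume=self.volume.like(data), truncation=self.truncation)


def encode_levelset(
    mesh: SurfaceMesh, grid: Volume, truncation: float = DEFAULT_TRUNCATION
) -> LevelSet:
    """Encode a closed oriented mesh as a truncated signed distance on a grid.

    The value at each voxel center is the exact Euclidean distance (mm) to the
    nearest point on the mesh surface, negated inside (ray-crossing parity),
    clamped to ``+-truncation``.  Exact point-to-triangle distances are used
    inside the band; outside, a nearest-vertex bound suffices because values
    clamp anyway.
    """
    if not mesh.is_edge_manifold():
        raise ValueError("mesh is not closed (boundary or non-manifold edge); inside/outside undefined")
    centers = grid.voxel_centers().reshape(-1, 3)

    vtree = cKDTree(mesh.vertices)
    d_ub, _ = vtree.query(centers, k=1)
    edges = mesh.vertices[mesh.faces[:, [0, 1]]]
    max_edge = float(
        np.linalg.norm(
            mesh.vertices[mesh.faces[:, 1]] - mesh.vertices[mesh.faces[:, 0]], axis=1
        ).max()
    )
    del edges

    dist = np.minimum(d_ub, truncation)
    # d_true >= d_ub - max_edge, so only these voxels can be inside the band
    band = d_ub <= truncation + max_edge
    if np.any(band):
        sq = SurfaceQuery(mesh.vertices, mesh.faces)
        _, d_exact, _ = sq.query(centers[band])
        dist[band] = np.minimum(d_exact, truncation)

    inside = grid_inside_mask(grid.shape, grid.affine, mesh.vertices, mesh.faces)
    phi = np.where(inside.reshape(-1), -dist, dist).reshape(grid.shape)
    return LevelSet(volume=grid.like(phi.astype(np.float64)), truncation=truncation)


def resample_levelset(ls: LevelSet, target_grid: Volume) -> LevelSet:
    """Trilinearly resample a level set onto another grid.

    Target voxels outside the source domain are set to ``+truncation``
    (outside).  Raises if the grids are disjoint.
    """
    src = ls.volume
    centers = target_grid.voxel_centers().reshape(-1, 3)
    ijk = src.world_to_voxel(centers)
    inside_src = np.all((ijk > -0.5) & (ijk < np.array(src.shape) - 0.5), axis=1)
    if not np.any(inside_src):
        raise ValueError("target grid is disjoint from the level-set domain")
    values = ndimage.map_coordinates(
        src.data.astype(np.float64),
        ijk.T,
        order=1,
        mode="constant",
        cval=ls.truncation,
    )
    values[~inside_src] = ls.truncation
    return LevelSet(
        volume=target_grid.like(values.reshape(target_grid.shape)),
        truncation=ls.truncation,
    )


def hemisphere_split(mask: Volume, n_expected: int = 2) -> tuple[Volume, Volume]:
    """Split a binary mask into left/right hemisphere masks by world-x centroid.

    Components are found with 26-connectivity.  With more than two components
    the two largest are kept and each smaller one is merged into the nearest
    of the two by centroid distance (a warning is logged).  RAS convention:
    +x is right, so the component with the smaller world-x centroid is left.
    """
    data = np.asarray(mask.data)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary (0/1)")
    labeled, n = ndimage.label(data > 0, structure=np.ones((3, 3, 3), dtype=bool))
    if n < n_expected:
        raise ValueError(
            f"expected {n_expected} connected components, found {n}"
        )
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1  # component labels, largest first
    keep = order[:2]
    centroids_ijk = np.array(ndimage.center_of_mass(data > 0, labeled, index=list(order)))
    centroids_world = mask.voxel_to_world(centroids_ijk)

    assignment = {}
    for rank, comp in enumerate(order):
        if rank < 2:
            assignment[comp] = comp
        else:
            d = np.linalg.norm(centroids_world[rank] - centroids_world[:2], axis=1)
            assignment[comp] = keep[int(np.argmin(d))]
            logger.warning(
                "hemisphere_split: merging extra component %d (size %d) into nearest kept component",
                comp,
                int(sizes[comp - 1]),
            )
    merged = np.zeros_like(labeled)
    for comp, target in assignment.items():
        merged[labeled == comp] = target

    keep_x = [centroids_world[list(order).index(k)][0] for k in keep]
    left_comp, right_comp = (
        (keep[0], keep[1]) if keep_x[0] < keep_x[1] else (keep[1], keep[0])
    )
    left = mask.like((merged == left_comp).astype(np.uint8))
    right = mask.like((merged == right_comp).astype(np.uint8))
    return left, right


# ---------------------------------------------------------------------------
# On-disk representation: NIfTI float32 + YAML sidecar


def write_levelset(ls: LevelSet, path) -> Path:
    import nibabel as nib
    import yaml

    path = Path(path)
    img = nib.Nifti1Image(ls.data.astype(np.float32), ls.affine)
    img.header["descrip"] = f"corsurf levelset inside<0 trunc={ls.truncation}mm".encode()
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar = sidecar.parent / (sidecar.name + ".levelset.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"truncation_mm": float(ls.truncation), "sign_convention": "inside_negative"},
            fh,
        )
    return path


def read_levelset(path, truncation: float | None = None) -> LevelSet:
    from .io_formats import read_volume

    path = Path(path)
    vol = read_volume(path)
    if truncation is None:
        sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
        sidecar = sidecar.parent / (sidecar.name + ".levelset.yaml")
        if sidecar.exists():
            import yaml

            with open(sidecar) as fh:
                meta = yaml.safe_load(fh)
            truncation = float(meta["truncation_mm"])
        else:
            truncation = float(np.abs(vol.data).max())
    return LevelSet(volume=vol, truncation=truncation)
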