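"""Domain containers and on-disk formats.

Volumes are NIfTI-1 (via nibabel); surfaces are FreeSurfer binary triangle
files, ASCII OFF or ASCII PLY; per-vertex scalar overlays are FreeSurfer
"curv"-style binary or one-value-per-line text; label maps are one-integer-
per-line text with a tab-separated id->name table.

Conventions: meshes live in world millimetre coordinates; voxel<->world goes
through the volume affine with 0-based indices and voxel centers at integer
index coordinates; FreeSurfer binary files are big-endian.  Surface files are
written without the optional volume-geometry footer, and readers ignore one
if present.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Volume",
    "SurfaceMesh",
    "LabelMap",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_surface",
    "write_surface",
    "read_overlay",
    "write_overlay",
    "read_labelmap",
    "write_labelmap",
]

SURFACE_FORMATS = ("freesurfer", "off", "ply")

_TRIANGLE_MAGIC = b"\xff\xff\xfe"
_CURV_MAGIC = b"\xff\xff\xff"


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


@dataclass
class Volume:
    """A 3D scalar grid with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self):
        return self.data.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx).reshape(*self.shape, 3)

    def like(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, affine=self.affine.copy())


@dataclass
class SurfaceMesh:
    """Triangle mesh: vertices in world mm, faces counter-clockwise outside."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.vertices) == 0:
            raise ValueError("empty mesh (no vertices)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")
        if self.faces.size:
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("degenerate face (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_sorted(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    def euler_characteristic(self) -> int:
        n_edges = len(np.unique(self.edges_sorted(), axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def is_edge_manifold(self) -> bool:
        """Every edge shared by exactly two faces (closed surface)."""
        _, counts = np.unique(self.edges_sorted(), axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def is_oriented(self) -> bool:
        """Each shared edge traversed once in each direction."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 1))

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norm, 1e-300)

    def vertex_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.maximum(norm, 1e-300)

    def area(self) -> float:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(n, axis=1).sum())

    def enclosed_volume(self) -> float:
        """Signed volume (positive for outward-oriented closed meshes)."""
        tri = self.vertices[self.faces]
        return float(
            np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
        )


@dataclass
class LabelMap:
    """Per-vertex integer region ids with an id -> region-name table."""

    labels: np.ndarray
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1D")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("label ids must be >= 0")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"label ids missing from name table: {sorted(missing)}")

    def region_ids(self) -> np.ndarray:
        return np.unique(self.labels)


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path) -> Volume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return Volume(data=data, affine=img.affine)


def write_volume(volume: Volume, path) -> Path:
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_data_dtype(volume.data.dtype)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Surfaces


def write_surface(mesh: SurfaceMesh, path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _guess_surface_format(path)
    if fmt not in SURFACE_FORMATS:
        raise ValueError(f"unknown surface format {fmt!r}; choose from {SURFACE_FORMATS}")
    if mesh.n_faces == 0:
        raise ValueError("refusing to write a mesh with no faces")
    if fmt == "freesurfer":
        _write_fs_surface(mesh, path)
    elif fmt == "off":
        _write_off(mesh, path)
    else:
        _write_ply(mesh, path)
    return path


def read_surface(path, format: str | None = None) -> SurfaceMesh:
    path = Path(path)
    fmt = format or _guess_surface_format(path)
    if fmt not in SURFACE_FORMATS:
        raise ValueError(f"unknown surface format {fmt!r}; choose from {SURFACE_FORMATS}")
    if fmt == "freesurfer":
        return _read_fs_surface(path)
    if fmt == "off":
        return _read_off(path)
    return _read_ply(path)


def _guess_surface_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".off":
        return "off"
    if suffix == ".ply":
        return "ply"
    return "freesurfer"


def _write_fs_surface(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "wb") as fh:
        fh.write(_TRIANGLE_MAGIC)
        fh.write(b"created by corsurf\n\n")
        fh.write(struct.pack(">ii", mesh.n_vertices, mesh.n_faces))
        fh.write(mesh.vertices.astype(">f4").tobytes())
        fh.write(mesh.faces.astype(">i4").tobytes())


def _read_fs_surface(path: Path) -> SurfaceMesh:
    with open(path, "rb") as fh:
        magic = fh.read(3)
        if magic != _TRIANGLE_MAGIC:
            raise FormatError(
                f"{path}: bad magic {magic!r}, expected FreeSurfer triangle file"
            )
        # comment: terminated by "\n\n"
        comment = b""
        while not comment.endswith(b"\n\n"):
            ch = fh.read(1)
            if not ch:
                raise FormatError(f"{path}: truncated comment")
            comment += ch
        nv, nf = struct.unpack(">ii", fh.read(8))
        if nv <= 0 or nf < 0:
            raise FormatError(f"{path}: invalid counts vertices={nv} faces={nf}")
        verts = np.frombuffer(fh.read(12 * nv), dtype=">f4").reshape(nv, 3)
        faces = np.frombuffer(fh.read(12 * nf), dtype=">i4").reshape(nf, 3)
        # optional volume-geometry footer, ignored
    return SurfaceMesh(vertices=verts.astype(np.float64), faces=faces.astype(np.int64))


def _write_off(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_off(path: Path) -> SurfaceMesh:
    with open(path) as fh:
        tokens = []
        first = fh.readline().strip()
        if not first.startswith("OFF"):
            raise FormatError(f"{path}: missing OFF header")
        rest = first[3:].split()
        tokens.extend(rest)
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if len(tokens) < 3:
        raise FormatError(f"{path}: truncated OFF file")
    nv, nf = int(tokens[0]), int(tokens[1])
    pos = 3
    verts = np.array(tokens[pos : pos + 3 * nv], dtype=np.float64).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise FormatError(f"{path}: only triangle faces supported, got {k}-gon")
        faces.append([int(t) for t in tokens[pos + 1 : pos + 4]])
        pos += 1 + k
    return SurfaceMesh(vertices=verts, faces=np.array(faces, dtype=np.int64))


def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment corsurf\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_ply(path: Path) -> SurfaceMesh:
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise FormatError(f"{path}: missing ply magic")
        nv = nf = None
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: truncated header")
            line = line.strip()
            if line.startswith("format") and "ascii" not in line:
                raise FormatError(f"{path}: only ascii PLY supported")
            if line.startswith("element vertex"):
                nv = int(line.split()[-1])
            elif line.startswith("element face"):
                nf = int(line.split()[-1])
            elif line == "end_header":
                break
        if nv is None or nf is None:
            raise FormatError(f"{path}: header missing vertex/face elements")
        verts = np.array(
            [fh.readline().split()[:3] for _ in range(nv)], dtype=np.float64
        )
        faces = []
        for _ in range(nf):
            parts = fh.readline().split()
            if int(parts[0]) != 3:
                raise FormatError(f"{path}: only triangle faces supported")
            faces.append([int(p) for p in parts[1:4]])
    return SurfaceMesh(vertices=verts, faces=np.array(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# Overlays (per-vertex scalars) and label maps


def write_overlay(values: np.ndarray, path, format: str | None = None) -> Path:
    path = Path(path)
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("refusing to write an empty overlay")
    fmt = format or ("text" if path.suffix.lower() in (".txt", ".csv", ".asc") else "curv")
    if fmt == "text":
        with open(path, "w") as fh:
            for v in values:
                fh.write(f"{v:.17g}\n")
    elif fmt == "curv":
        with open(path, "wb") as fh:
            fh.write(_CURV_MAGIC)
            fh.write(struct.pack(">iii", len(values), 0, 1))
            fh.write(values.astype(">f4").tobytes())
    else:
        raise ValueError(f"unknown overlay format {fmt!r}")
    return path


def read_overlay(path, format: str | None = None) -> np.ndarray:
    path = Path(path)
    fmt = format or ("text" if path.suffix.lower() in (".txt", ".csv", ".asc") else "curv")
    if fmt == "text":
        vals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    vals.append(float(line))
        if not vals:
            raise FormatError(f"{path}: empty overlay")
        return np.array(vals, dtype=np.float64)
    with open(path, "rb") as fh:
        magic = fh.read(3)
        if magic != _CURV_MAGIC:
            raise FormatError(f"{path}: bad curv magic {magic!r}")
        n, _fnum, vpv = struct.unpack(">iii", fh.read(12))
        if n <= 0:
            raise FormatError(f"{path}: invalid vertex count {n}")
        if vpv != 1:
            raise FormatError(f"{path}: values-per-vertex {vpv} unsupported")
        return np.frombuffer(fh.read(4 * n), dtype=">f4").astype(np.float64)


def write_labelmap(labelmap: LabelMap, labels_path, names_path) -> tuple[Path, Path]:
    labels_path, names_path = Path(labels_path), Path(names_path)
    with open(labels_path, "w") as fh:
        for v in labelmap.labels:
            fh.write(f"{int(v)}\n")
    with open(names_path, "w") as fh:
        for k in sorted(labelmap.names):
            fh.write(f"{int(k)}\t{labelmap.names[k]}\n")
    return labels_path, names_path


def read_labelmap(labels_path, names_path) -> LabelMap:
    labels = []
    with open(labels_path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                labels.append(int(line))
    names = {}
    with open(names_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                k, name = line.split("\t", 1)
                names[int(k)] = name
    return LabelMap(labels=np.array(labels, dtype=np.int64), names=names)
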