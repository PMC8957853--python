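"""Surface meshes of nuclei: marching cubes, normal-direction smoothing,
and enclosed-volume measurement.

Meshes are extracted from binarised label (or thresholded probability)
volumes with the topology-consistent Lewiner marching-cubes tables, which
guarantees closed, consistently oriented surfaces after padding the volume
with one layer of background. Smoothing displaces each vertex only along
its normal, by the normal component of the uniform-Laplacian vector — a
discrete mean-curvature step normalised by the local neighbourhood scale —
so that the characteristic shape of the structure is preserved while rough
voxelisation edges are relaxed. Enclosed volume follows from the
divergence theorem as the sum of signed tetrahedra against the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .grid import LabelVolume

__all__ = [
    "SurfaceMesh",
    "extract_mesh",
    "smooth_mesh",
    "mesh_volume",
    "write_mesh_obj",
    "write_mesh_ply",
    "read_mesh_obj",
]


@dataclass
class SurfaceMesh:
    """Triangulated surface in world mm."""

    vertices: np.ndarray     # (n, 3) float
    faces: np.ndarray        # (m, 3) int, counter-clockwise seen from outside
    structure: str = "structure"
    space_id: str = "native"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must have shape (m, 3)")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    # -- topology ---------------------------------------------------------

    def _directed_edges(self) -> np.ndarray:
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    @property
    def is_closed(self) -> bool:
        """Every undirected edge shared by exactly two faces."""
        e = np.sort(self._directed_edges(), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    @property
    def is_oriented(self) -> bool:
        """Each directed edge appears exactly once (consistent winding)."""
        e = self._directed_edges()
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 1))

    @property
    def euler_characteristic(self) -> int:
        n_v = len(np.unique(self.faces))
        n_e = len(np.unique(np.sort(self._directed_edges(), axis=1), axis=0))
        n_f = len(self.faces)
        return n_v - n_e + n_f

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        v = self.vertices
        f = self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        normals = np.zeros_like(v)
        for c in range(3):
            np.add.at(normals, f[:, c], fn)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return normals / norm


def extract_mesh(volume: LabelVolume, labels: int | list[int],
                 level: float = 0.5, structure: str | None = None) -> SurfaceMesh:
    """Marching-cubes isosurface of a (binarised) structure, in world mm.

    The structure mask is padded by one background voxel so the surface is
    always closed; the Lewiner case tables avoid the ambiguous-face holes
    of the classical algorithm.
    """
    labs = [int(l) for l in np.atleast_1d(labels)]
    mask = np.isin(volume.labels, labs)
    if not mask.any():
        raise ValueError(f"labels {labs} absent from volume {volume.space_id}")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=level,
                                                method="lewiner")
    verts -= 1.0  # undo padding offset, back to voxel-index coordinates
    world = verts @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    mesh = SurfaceMesh(world, faces,
                       structure=structure or "+".join(map(str, labs)),
                       space_id=volume.space_id)
    if np.linalg.det(volume.affine[:3, :3]) > 0 and _signed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def _signed_volume(mesh: SurfaceMesh) -> float:
    v = mesh.vertices
    f = mesh.faces
    return float(np.einsum("ij,ij->i", v[f[:, 0]],
                           np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume in mm^3 via the divergence theorem.

    Requires a closed, consistently oriented mesh; the absolute value is
    returned so the winding convention does not matter.
    """
    if not mesh.is_closed:
        raise ValueError("mesh_volume requires a closed mesh")
    if not mesh.is_oriented:
        raise ValueError("mesh_volume requires consistent face orientation")
    return abs(_signed_volume(mesh))


def _vertex_adjacency(mesh: SurfaceMesh):
    """CSR-style neighbour lists (offsets, flat neighbour indices)."""
    e = np.unique(np.sort(mesh._directed_edges(), axis=1), axis=0)
    both = np.concatenate([e, e[:, ::-1]])
    order = np.argsort(both[:, 0], kind="stable")
    both = both[order]
    counts = np.bincount(both[:, 0], minlength=len(mesh.vertices))
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return offsets, both[:, 1]


def smooth_mesh(mesh: SurfaceMesh, n_iter: int = 10,
                step: float = 0.1) -> SurfaceMesh:
    """Normal-direction curvature smoothing; connectivity is unchanged.

    Each iteration moves every vertex by ``step`` times the normal
    component of its uniform-Laplacian vector (mean of neighbours minus the
    vertex), along the vertex normal. Tangential drift is suppressed by
    construction, so the structure's shape is preserved while curvature
    extremes relax. ``n_iter=0`` returns an identical copy.
    """
    if not 0 < step <= 1:
        raise ValueError("step must lie in (0, 1]")
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if not mesh.is_closed:
        raise ValueError("smooth_mesh requires a closed mesh")
    out = SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy(),
                      structure=mesh.structure, space_id=mesh.space_id)
    offsets, nbrs = _vertex_adjacency(out)
    deg = np.diff(offsets).astype(float)
    deg[deg == 0] = 1.0
    for it in range(n_iter):
        v = out.vertices
        sums = np.zeros_like(v)
        np.add.at(sums, np.repeat(np.arange(len(v)), np.diff(offsets)), v[nbrs])
        lap = sums / deg[:, None] - v
        normals = out.vertex_normals()
        disp = step * np.einsum("ij,ij->i", lap, normals)[:, None] * normals
        out.vertices = v + disp
        # abort if the step collapsed any face
        f = out.faces
        areas = 0.5 * np.linalg.norm(
            np.cross(out.vertices[f[:, 1]] - out.vertices[f[:, 0]],
                     out.vertices[f[:, 2]] - out.vertices[f[:, 0]]), axis=1)
        if np.any(areas <= 1e-14):
            raise RuntimeError(
                f"smoothing created degenerate faces at iteration {it + 1}")
    return out


# -- ASCII mesh I/O --------------------------------------------------------

def write_mesh_obj(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {mesh.structure} ({mesh.space_id})\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def write_mesh_ply(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment {mesh.structure} ({mesh.space_id})\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh_obj(path, structure: str = "structure",
                  require_closed: bool = True) -> SurfaceMesh:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    mesh = SurfaceMesh(np.array(verts), np.array(faces), structure=structure)
    if require_closed and not mesh.is_closed:
        raise ValueError(f"{path}: mesh is not closed")
    return mesh
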