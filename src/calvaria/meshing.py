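"""Surface extraction and tetrahedral meshing of labeled volumes.

Surfaces come from per-region marching cubes (scikit-image) with optional
Gaussian pre-smoothing and vertex-clustering decimation.  Volume meshes are
structured Kuhn (Freudenthal) subdivisions of the voxel grid — six
tetrahedra per voxel with a translation-invariant diagonal pattern, so
meshes are conforming across region interfaces by construction and
per-region volumes are conserved exactly.

Units: voxel volumes are in µm, mesh coordinates in mm (mm–N–MPa system).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .volume import LabeledVolume

# Kuhn subdivision: six tetra as vertex chains 0 → +e_a → +e_b → +e_c over
# the six axis permutations; odd permutations are swapped to positive volume.
_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _corner_offsets():
    """Per-tet 4×3 corner offsets within the unit cube, positively oriented."""
    tets = []
    for perm in _PERMS:
        pts = [np.zeros(3, dtype=np.int64)]
        for ax in perm:
            nxt = pts[-1].copy()
            nxt[ax] += 1
            pts.append(nxt)
        pts = np.array(pts)
        if np.linalg.det((pts[1:] - pts[0]).astype(float)) < 0:
            pts = pts[[0, 1, 3, 2]]
        tets.append(pts)
    return np.array(tets)  # (6, 4, 3)


_TET_OFFSETS = _corner_offsets()


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm with per-vertex and per-face region ids."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_region: np.ndarray
    face_region: np.ndarray

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.faces.copy(),
            self.vertex_region.copy(), self.face_region.copy(),
        )

    def region(self, label: int) -> "SurfaceMesh":
        """Sub-mesh of one region, vertices renumbered."""
        fsel = self.face_region == label
        faces = self.faces[fsel]
        used = np.unique(faces)
        remap = np.full(self.vertices.shape[0], -1, dtype=np.int64)
        remap[used] = np.arange(used.size)
        return SurfaceMesh(
            self.vertices[used], remap[faces],
            self.vertex_region[used], self.face_region[fsel],
        )

    @property
    def n_triangles(self) -> int:
        return int(self.faces.shape[0])

    def area(self) -> float:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())

    def to_ply(self, path) -> None:
        """Binary little-endian PLY with a per-vertex integer bone label."""
        import trimesh

        mesh = trimesh.Trimesh(self.vertices, self.faces, process=False)
        mesh.vertex_attributes["region"] = self.vertex_region.astype(np.int32)
        mesh.export(str(path), encoding="binary")


@dataclass
class TetMesh:
    """Conforming tetrahedral mesh with per-element region labels (mm)."""

    nodes: np.ndarray           # (n, 3) mm
    tets: np.ndarray            # (m, 4) node indices, positive volume
    region: np.ndarray          # (m,) voxel label per tet
    label_roles: dict[int, str] = field(default_factory=dict)
    node_index: np.ndarray | None = None  # (n, 3) integer grid coordinates

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_tets(self) -> int:
        return int(self.tets.shape[0])

    def volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d) / 6.0

    def edge_lengths(self) -> np.ndarray:
        x = self.nodes[self.tets]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        return np.stack(
            [np.linalg.norm(x[:, a] - x[:, b], axis=1) for a, b in pairs], axis=1
        )

    def mean_element_size(self, label: int | None = None) -> float:
        """Mean edge length, optionally restricted to one region."""
        e = self.edge_lengths()
        if label is not None:
            e = e[self.region == label]
        return float(e.mean())

    def min_dihedral_angle_deg(self) -> float:
        x = self.nodes[self.tets]
        faces = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
        normals = []
        for a, b, c in faces:
            n = np.cross(x[:, b] - x[:, a], x[:, c] - x[:, a])
            normals.append(n / np.linalg.norm(n, axis=1, keepdims=True))
        worst = np.pi
        for i in range(4):
            for j in range(i + 1, 4):
                cosang = np.clip((normals[i] * normals[j]).sum(axis=1), -1, 1)
                ang = np.pi - np.arccos(cosang)  # interior dihedral
                worst = min(worst, float(ang.min()))
        return float(np.degrees(worst))

    def boundary_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Faces appearing exactly once, with their owning tet index."""
        f = self.tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]]
        f = f.reshape(-1, 3)
        owner = np.repeat(np.arange(self.n_tets), 4)
        key = np.sort(f, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        sel = counts[inv] == 1
        return f[sel], owner[sel]

    def surface_nodes(self, labels=None) -> np.ndarray:
        """Node indices on the boundary, optionally of given regions only."""
        faces, owner = self.boundary_faces()
        if labels is not None:
            faces = faces[np.isin(self.region[owner], np.asarray(labels))]
        return np.unique(faces)

    def region_nodes(self, labels) -> np.ndarray:
        sel = np.isin(self.region, np.asarray(labels))
        return np.unique(self.tets[sel])

    def to_vtk(self, path, cell_data: dict | None = None,
               point_data: dict | None = None) -> None:
        write_vtk(path, self, cell_data, point_data)


def extract_surface(
    model: LabeledVolume,
    presmooth: float = 0.0,
    target_triangles: int | None = None,
    labels: list[int] | None = None,
) -> SurfaceMesh:
    """Marching-cubes surface per region at the 0.5 iso-level (mm).

    ``presmooth`` is a smoothing extent in voxels (Gaussian σ =
    presmooth/2); with ``presmooth=0`` the raw binary mask is contoured.
    ``target_triangles`` bounds the *total* triangle count via
    vertex-clustering decimation, region ids preserved.
    """
    if labels is None:
        labels = sorted(l for l in model.label_roles if (model.labels == l).any())
    verts, faces, vreg, freg = [], [], [], []
    offset = 0
    scale = model.voxel_size * 1e-3
    for lab in labels:
        mask = model.labels == lab
        if not mask.any():
            continue
        if presmooth > 0:
            f = ndi.gaussian_filter(mask.astype(np.float32), sigma=presmooth / 2.0)
            if f.max() <= 0.5:
                raise ValueError(f"region {lab} vanishes under presmoothing")
        else:
            f = mask.astype(np.float32)
        f = np.pad(f, 1)
        v, fc, _, _ = measure.marching_cubes(f, level=0.5)
        v = (v.astype(np.float64) - 0.5) * scale  # un-pad; centers at (i+0.5)·h
        verts.append(v)
        faces.append(fc + offset)
        vreg.append(np.full(v.shape[0], lab, dtype=np.int32))
        freg.append(np.full(fc.shape[0], lab, dtype=np.int32))
        offset += v.shape[0]
    if not verts:
        raise ValueError("no regions to extract")
    surf = SurfaceMesh(
        np.vstack(verts), np.vstack(faces).astype(np.int64),
        np.concatenate(vreg), np.concatenate(freg),
    )
    if target_triangles is not None and surf.n_triangles > target_triangles:
        surf = decimate(surf, target_triangles)
    return surf


def decimate(surf: SurfaceMesh, target_triangles: int) -> SurfaceMesh:
    """Vertex-clustering decimation to at most ``target_triangles``.

    Vertices of each region are snapped to their cluster mean on a uniform
    grid whose cell size grows until the triangle budget is met; degenerate
    faces are dropped.  Regions never merge.
    """
    if target_triangles < 4:
        raise ValueError("target_triangles must be >= 4")
    lo = surf.vertices.min(axis=0)
    span = float((surf.vertices.max(axis=0) - lo).max()) or 1.0
    cell = span / 256.0
    out = surf
    for _ in range(40):
        out = _cluster_once(surf, lo, cell)
        if out.n_triangles <= target_triangles:
            return out
        cell *= 1.35
    return out


def _cluster_once(surf: SurfaceMesh, lo: np.ndarray, cell: float) -> SurfaceMesh:
    key = np.floor((surf.vertices - lo) / cell).astype(np.int64)
    # cluster id: grid cell + region (regions stay separate)
    combo = np.column_stack([key, surf.vertex_region.astype(np.int64)])
    uniq, inv = np.unique(combo, axis=0, return_inverse=True)
    n = uniq.shape[0]
    pos = np.zeros((n, 3))
    cnt = np.zeros(n)
    np.add.at(pos, inv, surf.vertices)
    np.add.at(cnt, inv, 1.0)
    pos /= cnt[:, None]
    faces = inv[surf.faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[ok]
    return SurfaceMesh(
        pos, faces, uniq[:, 3].astype(np.int32), surf.face_region[ok]
    )


def tetrahedralize(
    model: LabeledVolume,
    labels: list[int] | None = None,
    max_edge_mm: float | None = None,
    refine: int = 1,
) -> TetMesh:
    """Kuhn 6-tet-per-voxel mesh of the selected regions (mm).

    ``refine`` subdivides every voxel into ``refine³`` subvoxels first;
    alternatively ``max_edge_mm`` picks the smallest refinement whose
    longest tet edge (the voxel diagonal, √3·h) stays below the bound.
    Conforming across regions, exact per-region volume conservation,
    deterministic.
    """
    if labels is None:
        labels = sorted(model.label_roles)
    h_mm = model.voxel_size * 1e-3
    if max_edge_mm is not None:
        need = int(np.ceil(np.sqrt(3.0) * h_mm / max_edge_mm))
        refine = max(refine, need)
    if refine < 1:
        raise ValueError("refine must be >= 1")
    lab = model.labels
    if refine > 1:
        lab = np.repeat(np.repeat(np.repeat(lab, refine, 0), refine, 1), refine, 2)
        h_mm /= refine

    sel = np.isin(lab, np.asarray(labels)) & (lab > 0)
    vox = np.argwhere(sel)
    if vox.size == 0:
        raise ValueError("no voxels selected for meshing")
    regions = lab[sel]

    corners = vox[:, None, None, :] + _TET_OFFSETS[None]  # (nv, 6, 4, 3)
    shape = np.asarray(lab.shape) + 1
    flat = (
        corners[..., 0] * (shape[1] * shape[2])
        + corners[..., 1] * shape[2]
        + corners[..., 2]
    ).reshape(-1, 4)
    used, tets = np.unique(flat, return_inverse=True)
    tets = tets.reshape(-1, 4)
    gi = np.empty((used.size, 3), dtype=np.int64)
    gi[:, 0] = used // (shape[1] * shape[2])
    gi[:, 1] = (used // shape[2]) % shape[1]
    gi[:, 2] = used % shape[2]
    nodes = gi.astype(float) * h_mm
    region = np.repeat(regions, 6)
    mesh = TetMesh(nodes, tets, region, dict(model.label_roles), gi)
    if (mesh.volumes() <= 0).any():
        raise AssertionError("inverted element in structured mesh")
    return mesh


def write_vtk(path, mesh: TetMesh, cell_data=None, point_data=None) -> None:
    """Minimal legacy-ASCII VTK unstructured-grid writer."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncalvaria mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} float\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        f.write(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}\n")
        cells = np.column_stack(
            [np.full(mesh.n_tets, 4, dtype=np.int64), mesh.tets]
        )
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(f, np.full(mesh.n_tets, 10, dtype=np.int64), fmt="%d")
        f.write(f"CELL_DATA {mesh.n_tets}\n")
        f.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.region, fmt="%d")
        for name, arr in (cell_data or {}).items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%.9g")
            else:
                f.write(f"VECTORS {name} float\n")
                np.savetxt(f, arr, fmt="%.9g")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.9g")
                else:
                    f.write(f"VECTORS {name} float\n")
                    np.savetxt(f, arr, fmt="%.9g")
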