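"""Rigid registration of bone surfaces (point-to-point ICP).

Skull bones deform far less than sutures under external load, so the
loaded state of each bone is well described by a rigid motion of its
unloaded surface.  Per-bone ICP recovers those motions; the suture strain
estimator turns the relative motions into a strain field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .meshing import SurfaceMesh
from .transforms import Rigid, rotation_about_axis


@dataclass
class BoneAlignment:
    """Rigid transform mapping unloaded → loaded, with fit diagnostics."""

    transform: Rigid
    rms: float
    iterations: int


def kabsch(src: np.ndarray, dst: np.ndarray) -> Rigid:
    """Least-squares rigid transform taking ``src`` onto ``dst`` (paired)."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return Rigid(R, dc - R @ sc)


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fn = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def _plane_step(moved: np.ndarray, q: np.ndarray, n: np.ndarray) -> Rigid:
    """Linearized point-to-plane least squares: one rigid update."""
    a = np.hstack([np.cross(moved, n), n])          # (m, 6)
    b = -np.einsum("ij,ij->i", moved - q, n)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    w, t = x[:3], x[3:]
    ang = np.linalg.norm(w)
    R = np.eye(3) if ang < 1e-15 else rotation_about_axis(w, ang)
    return Rigid(R, t)


def icp(
    src: np.ndarray,
    dst: np.ndarray,
    max_iterations: int = 200,
    tol: float = 1e-6,
    method: str = "plane",
    dst_normals: np.ndarray | None = None,
) -> BoneAlignment:
    """Iterative closest point, src → dst.

    ``method='plane'`` (default) minimizes point-to-plane distances using
    destination normals — required to recover tangential slides smaller
    than the surface sampling spacing, where pure point-to-point locks
    onto the sampling lattice.  ``method='point'`` is classic ICP.
    Converges when the RMS residual changes by less than ``tol`` (mm) or
    after ``max_iterations``.  Raises for surfaces that do not overlap at
    all (initial RMS beyond half the bounding-box diagonal).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    tree = cKDTree(dst)
    bbox = np.vstack([src, dst])
    diag = np.linalg.norm(bbox.max(axis=0) - bbox.min(axis=0))
    d0, _ = tree.query(src)
    if np.sqrt((d0**2).mean()) > diag / 2.0:
        raise ValueError("surfaces do not overlap; rigid ICP cannot start")
    if method == "plane" and dst_normals is None:
        raise ValueError("point-to-plane ICP needs destination normals")

    T = Rigid.identity()
    moved = src
    prev = np.inf
    rms = float(np.sqrt((d0**2).mean()))
    it = 0
    for it in range(1, max_iterations + 1):
        d, j = tree.query(moved)
        if method == "plane":
            n = dst_normals[j]
            resid = np.einsum("ij,ij->i", moved - dst[j], n)
            rms = float(np.sqrt((resid**2).mean()))
            step = _plane_step(moved, dst[j], n)
        elif method == "point":
            rms = float(np.sqrt((d**2).mean()))
            step = kabsch(moved, dst[j])
        else:
            raise ValueError(f"unknown ICP method {method!r}")
        T = step.compose(T)
        moved = step.apply(moved)
        if abs(prev - rms) < tol:
            break
        prev = rms
    return BoneAlignment(T, rms, it)


def align_bone(unloaded: SurfaceMesh, loaded: SurfaceMesh, label: int | None = None,
               **kw) -> BoneAlignment:
    """ICP-align one bone's unloaded surface to its loaded surface.

    With ``label`` given, both meshes are restricted to that region first;
    both surfaces must carry the bone (≥ 100 vertices each).
    """
    if label is not None:
        unloaded = unloaded.region(label)
        loaded = loaded.region(label)
    if unloaded.vertices.shape[0] < 100 or loaded.vertices.shape[0] < 100:
        raise ValueError("need at least 100 vertices per bone surface")
    if kw.get("method", "plane") == "plane" and "dst_normals" not in kw:
        kw["dst_normals"] = _vertex_normals(loaded.vertices, loaded.faces)
    return icp(unloaded.vertices, loaded.vertices, **kw)


def align_all_bones(unloaded: SurfaceMesh, loaded: SurfaceMesh, **kw):
    """Per-bone alignments for every region present in both surfaces."""
    labels = sorted(
        set(np.unique(unloaded.vertex_region)) & set(np.unique(loaded.vertex_region))
    )
    return {int(l): align_bone(unloaded, loaded, label=int(l), **kw) for l in labels}


def assembly_pose(reference: SurfaceMesh, observed: SurfaceMesh, **kw) -> BoneAlignment:
    """Global rigid pose of an observed surface relative to a reference
    (e.g. scanner repositioning between sessions), via whole-assembly ICP."""
    if kw.get("method", "plane") == "plane" and "dst_normals" not in kw:
        kw["dst_normals"] = _vertex_normals(observed.vertices, observed.faces)
    return icp(reference.vertices, observed.vertices, **kw)
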