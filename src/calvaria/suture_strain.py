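"""Suture strain estimation from per-bone rigid alignments.

Given a bone+suture model and a rigid transform per bone (unloaded →
loaded), the suture region is meshed, every suture node in contact with a
bone inherits that bone's rigid displacement, and the suture interior is
filled by solving the linear-elastic problem with those Dirichlet data
(unit modulus — with pure Dirichlet boundaries the strain field does not
depend on the modulus).  Element strains are then averaged per suture,
volume-weighted, as von Mises and 1st/3rd principal values.

Strain magnitudes across neonatal sutures reach order 1–10, so the
reported principal values use the nominal (small-strain) tensor of the
displacement field, for which a uniform opening Δ across a width w reads
exactly Δ/w; the Green–Lagrange measure is available as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fem
from .meshing import tetrahedralize
from .morphology import segment_sutures
from .registration import BoneAlignment
from .transforms import Rigid
from .volume import LabeledVolume


def _as_rigid(a) -> Rigid:
    return a.transform if isinstance(a, BoneAlignment) else a


def estimate_suture_strain(
    model: LabeledVolume,
    alignments: dict[int, "Rigid | BoneAlignment"],
    poisson: float = 0.3,
    measure: str = "small",
    frame: "Rigid | BoneAlignment | None" = None,
    include_cover: bool = False,
    refine: int = 1,
) -> pd.DataFrame:
    """Per-suture averaged strain measures from per-bone rigid motions.

    Parameters
    ----------
    model
        Bone+suture labeled volume (the unloaded state).
    alignments
        Rigid transform per structural label, acting on mm coordinates in
        the frame of the *surfaces* the alignment was computed from.
    frame
        Optional rigid pose of that surface frame relative to the model
        frame; alignments are conjugated into the model frame, which makes
        the estimate invariant under a common rigid motion applied to both
        loaded and unloaded data.
    measure
        'small' (default) or 'green'.

    Returns a DataFrame indexed by bone pair with columns
    ``von_mises, e1, e3, volume_mm3`` plus a ``__all__`` row.
    """
    transforms = {l: _as_rigid(a) for l, a in alignments.items()}
    if frame is not None:
        F = _as_rigid(frame)
        transforms = {l: T.conjugate(F) for l, T in transforms.items()}

    suture_label = model.labels_with_role("suture")
    mesh_labels = list(suture_label)
    if include_cover:
        mesh_labels += model.labels_with_role("cover")
    if not mesh_labels:
        raise ValueError("model has no suture label")

    pair_vol, pair_to_index = segment_sutures(model, include_cover=include_cover)
    mesh = tetrahedralize(model, labels=mesh_labels, refine=refine)

    # Dirichlet nodes: mesh nodes incident to at least one bone voxel.
    # Each node takes the transform of the bone owning most of its
    # incident voxels (smallest label on ties — deterministic).
    gi = mesh.node_index
    lab = model.labels
    if refine > 1:
        lab = np.repeat(np.repeat(np.repeat(lab, refine, 0), refine, 1), refine, 2)
    shape = lab.shape
    structural = model.structural_labels
    incident = np.zeros((8, mesh.n_nodes), dtype=np.int64)
    k = 0
    for dx in (-1, 0):
        for dy in (-1, 0):
            for dz in (-1, 0):
                vi = gi + np.array([dx, dy, dz])
                ok = ((vi >= 0) & (vi < np.asarray(shape))).all(axis=1)
                incident[k, ok] = lab[vi[ok, 0], vi[ok, 1], vi[ok, 2]]
                k += 1
    # node takes the bone owning most incident voxels; smallest label wins ties
    owner = np.zeros(mesh.n_nodes, dtype=np.int64)
    best = np.zeros(mesh.n_nodes, dtype=np.int64)
    for l in structural:
        c = (incident == l).sum(axis=0)
        better = c > best
        owner[better] = l
        best[better] = c[better]
    dirichlet = owner > 0

    needed = sorted(set(owner[dirichlet].tolist()))
    missing = [l for l in needed if l not in transforms]
    if missing:
        raise ValueError(f"no alignment for bones {missing} adjacent to the suture")

    voxel_mm = model.voxel_size * 1e-3 / refine
    sysm = fem.assemble(
        mesh,
        fem.MaterialSet({r: 1.0 for r in ("bone", "suture", "brain", "cover")}, poisson),
    )
    u_fix = np.zeros((mesh.n_nodes, 3))
    for l in needed:
        sel = owner == l
        x = mesh.nodes[sel]
        u_fix[sel] = transforms[l].apply(x) - x
    ids = np.where(dirichlet)[0]
    sysm.fix_dofs(ids, values=u_fix[ids])
    if not dirichlet.any() or len(needed) < 2:
        raise ValueError("suture has fewer than 2 adjacent aligned bones")
    res = fem.solve(sysm, measure=measure)

    # map voxel pair indices onto tets (tet centroid → voxel index)
    cent = mesh.nodes[mesh.tets].mean(axis=1) / voxel_mm
    vox = np.floor(cent).astype(int)
    if refine > 1:
        vox //= refine
    tet_pair = pair_vol[vox[:, 0], vox[:, 1], vox[:, 2]]

    vols = mesh.volumes()
    rows = []
    for pair, idx in sorted(pair_to_index.items()):
        sel = tet_pair == idx
        if not sel.any():
            continue
        w = vols[sel]
        w = w / w.sum()
        rows.append(
            {
                "bone_a": pair[0],
                "bone_b": pair[1],
                "von_mises": float(res.von_mises[sel] @ w),
                "e1": float(res.e1[sel] @ w),
                "e3": float(res.e3[sel] @ w),
                "volume_mm3": float(vols[sel].sum()),
            }
        )
    w = vols / vols.sum()
    rows.append(
        {
            "bone_a": -1,
            "bone_b": -1,
            "von_mises": float(res.von_mises @ w),
            "e1": float(res.e1 @ w),
            "e3": float(res.e3 @ w),
            "volume_mm3": float(vols.sum()),
        }
    )
    df = pd.DataFrame(rows).set_index(["bone_a", "bone_b"])
    return df
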