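"""End-to-end wiring: phantom → sutures → endocast → mesh → FE → strains.

This is the rapid model-development path in miniature: build a bone+suture
+endocast+cover model from a labeled volume, mesh it, and run the four
standard dorsoventral load locations (frontal, anterior-parietal,
posterior-parietal, interparietal analogues — one per plate, posterior →
anterior) with a chosen material set, reporting per-suture von Mises / e1
/ e3 averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fem
from .endocast import extract_endocast, generate_covers
from .meshing import TetMesh, tetrahedralize
from .morphology import MorphParams, segment_sutures, synthesize_sutures
from .phantom import PhantomSpec, generate_phantom
from .volume import LabeledVolume


@dataclass
class SkullModel:
    """A meshed bone+suture+endocast model ready for FE load cases."""

    volume: LabeledVolume
    mesh: TetMesh
    tet_pair_index: np.ndarray
    pair_names: dict


def build_model(
    vol: LabeledVolume,
    morph: MorphParams | None = None,
    closing_radius: float | None = None,
    refine: int = 1,
    with_endocast: bool = True,
) -> SkullModel:
    """Synthesize sutures (and endocast + covers), then mesh everything."""
    model = synthesize_sutures(vol, morph)
    if with_endocast:
        if closing_radius is None:
            closing_radius = 4.0
        model = extract_endocast(model, closing_radius)
        model = generate_covers(model)
    pair_vol, pair_names = segment_sutures(model, include_cover=False)
    mesh = tetrahedralize(model, refine=refine)
    tet_pair = _map_to_tets(mesh, pair_vol, refine)
    return SkullModel(model, mesh, tet_pair, pair_names)


def _map_to_tets(mesh: TetMesh, voxel_field: np.ndarray, refine: int) -> np.ndarray:
    h = None
    # node spacing of the (possibly refined) grid:
    gi = mesh.node_index
    span = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
    gspan = gi.max(axis=0) - gi.min(axis=0)
    h = float((span / np.maximum(gspan, 1)).max())
    cent = mesh.nodes[mesh.tets].mean(axis=1) / h
    vox = np.floor(cent).astype(int) // refine
    return voxel_field[vox[:, 0], vox[:, 1], vox[:, 2]]


def demo_spec() -> PhantomSpec:
    """Compact dome phantom whose full pipeline mesh stays desk-scale
    (~50k tets): 4 mm dome, 0.32 mm shell, 2-voxel gaps at 160 µm."""
    return PhantomSpec(
        outer_radius=2000.0, shell_thickness=320.0, gap_width=320.0,
        n_plates=4, voxel_size=160.0,
    )


def demo_morph() -> MorphParams:
    """Recipe counts matching the coarse demo voxel size."""
    return MorphParams(2, 1, 3, 1, 3)


def default_morph_params(spec: PhantomSpec) -> MorphParams:
    """Recipe counts scaled to the phantom's gap width in voxels.

    The canonical 5/5/9/1/9 counts assume micrometre voxels; a coarse
    phantom uses the same recipe scaled so the bone expansion still spans
    half the gap plus one voxel.
    """
    gap_vox = spec.gap_width / spec.voxel_size
    expand = max(2, int(np.ceil(gap_vox / 2)) + 1)
    smooth = 2 * expand - 1
    return MorphParams(expand, expand, smooth, 1, smooth)


def build_phantom_model(
    spec: PhantomSpec | None = None,
    morph: MorphParams | None = None,
    refine: int = 1,
) -> SkullModel:
    spec = spec or PhantomSpec()
    vol = generate_phantom(spec)
    morph = morph or default_morph_params(spec)
    # after suture synthesis the gaps are filled; a closing of one gap
    # width tidies residual pinholes without swallowing the cavity
    gap_vox = max(spec.gap_width / spec.voxel_size, 1.0)
    return build_model(vol, morph, closing_radius=gap_vox, refine=refine)


def default_load_points(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Dorsal midline load points, one per plate, posterior → anterior.

    Named after the calvarial analogues (interparietal … frontal) so the
    most posterior plate is the interparietal and the most anterior the
    frontal, matching the wedge ordering of the phantom.
    """
    names = ["interparietal", "posterior-parietal", "anterior-parietal", "frontal"]
    n = spec.n_plates
    if n != 4:
        names = [f"plate-{k + 1}" for k in range(n)]
    # plate angular centres in the (z, y) plane, pulled slightly away from
    # the rim so the terminal discs clear the constraint patches
    phis = -np.pi / 2 + (np.arange(n) + 0.5) * np.pi / n
    phi_max = np.radians(52.0)
    phis = np.clip(phis, -phi_max, phi_max)
    r_mid = spec.outer_radius  # on the outer surface
    from .phantom import MARGIN_VOX

    v = spec.voxel_size
    rv = spec.outer_radius / v
    m = MARGIN_VOX
    nx = int(np.ceil(2 * rv)) + 2 * m
    cx_mm = nx / 2.0 * v * 1e-3
    cy_mm = m * v * 1e-3
    out = {}
    for k, phi in enumerate(phis):
        y = r_mid * np.cos(phi) * 1e-3 + cy_mm
        z = r_mid * np.sin(phi) * 1e-3 + cx_mm
        out[names[k]] = np.array([cx_mm, y, z])
    return out


def run_load_location(
    skull: SkullModel,
    load_point,
    mats: fem.MaterialSet | None = None,
    force: float = 0.1,
    disc_diameter: float = 1.0,
) -> pd.DataFrame:
    """Solve one dorsoventral load case; per-suture averaged strains."""
    mats = mats or fem.MaterialSet.adjusted()
    system = fem.assemble(skull.mesh, mats)
    lc = fem.LoadCase(np.asarray(load_point, float), disc_diameter, force)
    fem.apply_load_case(system, lc)
    res = fem.solve(system)
    vols = skull.mesh.volumes()
    rows = []
    for pair, idx in sorted(skull.pair_names.items()):
        sel = skull.tet_pair_index == idx
        if not sel.any():
            continue
        w = vols[sel]
        w = w / w.sum()
        rows.append(
            {
                "suture": str(pair),
                "bone_a": pair[0],
                "bone_b": pair[1],
                "von_mises": float(res.von_mises[sel] @ w),
                "e1": float(res.e1[sel] @ w),
                "e3": float(res.e3[sel] @ w),
            }
        )
    return pd.DataFrame(rows).set_index("suture")


def run_all_locations(
    skull: SkullModel,
    spec: PhantomSpec,
    mats: fem.MaterialSet | None = None,
) -> dict[str, pd.DataFrame]:
    return {
        name: run_load_location(skull, pt, mats)
        for name, pt in default_load_points(spec).items()
    }


def nearest_suture(skull: SkullModel, load_point, labels=None) -> tuple:
    """Bone pair of the suture region closest to a load point.

    ``labels`` restricts the candidate pairs to sutures between those
    bones (e.g. the calvarial plates, excluding basal ring segments).
    """
    cent = skull.mesh.nodes[skull.mesh.tets].mean(axis=1)
    best, best_d = None, np.inf
    for pair, idx in skull.pair_names.items():
        if labels is not None and not (pair[0] in labels and pair[1] in labels):
            continue
        sel = skull.tet_pair_index == idx
        if not sel.any():
            continue
        d = np.linalg.norm(cent[sel] - np.asarray(load_point), axis=1).min()
        if d < best_d:
            best, best_d = pair, d
    return best
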