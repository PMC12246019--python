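"""Endocast (intracranial volume) extraction and cover generation.

The endocast is found on the voxel grid: the solid mask (every nonzero
label) is morphologically closed so that suture-scale gaps disappear, and
the enclosed cavity is recovered by flood fill.  Remaining large openings —
through which the cavity would leak to the exterior — are sealed by "cover"
voxels, which downstream receive suture material properties.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .volume import LabeledVolume

_FACE = ndi.generate_binary_structure(3, 1)


def _ball_close(mask: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean closing via two distance transforms (fast for any radius)."""
    if radius <= 0:
        return mask.copy()
    dil = ndi.distance_transform_edt(~mask) <= radius
    ero = ndi.distance_transform_edt(dil) > radius  # erosion of the dilation
    return mask | ero


def extract_endocast(
    model: LabeledVolume,
    closing_radius: float,
    seed: tuple[int, int, int] | None = None,
) -> LabeledVolume:
    """Add an ``endocast`` label filling the enclosed cavity.

    The non-background mask is closed with a Euclidean ball of
    ``closing_radius`` voxels; interior connected components of the
    complement (face connectivity) that do not reach the volume boundary
    are cavity candidates.  With ``seed`` given, the component containing
    it is used, otherwise the largest interior component.  Raises if the
    cavity connects to the exterior at this radius.
    """
    solid = model.labels > 0
    closed = _ball_close(solid, closing_radius)
    comp, n = ndi.label(~closed, structure=_FACE)
    if n == 0:
        raise ValueError("cavity not closable at this radius: no empty space")
    border = np.unique(
        np.concatenate(
            [
                comp[0].ravel(), comp[-1].ravel(),
                comp[:, 0].ravel(), comp[:, -1].ravel(),
                comp[:, :, 0].ravel(), comp[:, :, -1].ravel(),
            ]
        )
    )
    exterior = set(border.tolist()) - {0}
    if seed is not None:
        c = int(comp[tuple(seed)])
        if c == 0:
            raise ValueError("seed lies inside the solid after closing")
        if c in exterior:
            raise ValueError("cavity not closable at this radius: seed escapes")
        cavity_id = c
    else:
        counts = np.bincount(comp.ravel())
        counts[0] = 0
        for e in exterior:
            counts[e] = 0
        if counts.max() == 0:
            raise ValueError("cavity not closable at this radius")
        cavity_id = int(counts.argmax())

    cavity = (comp == cavity_id) & (model.labels == 0)
    out = model.copy()
    lab = out.next_free_label()
    out.labels[cavity] = lab
    out.label_roles[lab] = "endocast"
    return out


def generate_covers(model: LabeledVolume) -> LabeledVolume:
    """Seal exterior-exposed endocast surface with ``cover`` voxels.

    Exterior background is flood-filled from the volume boundary (face
    connectivity); background voxels of the exterior that are face-adjacent
    to the endocast become cover, one voxel-shell thick — enough to block
    any face-connected path from outside into the cavity.  A fully shielded
    endocast yields zero cover voxels.
    """
    endo = model.mask("endocast")
    if not endo.any():
        raise ValueError("endocast label missing; run extract_endocast first")
    bg = model.labels == 0
    exterior = bg & ~ndi.binary_fill_holes(~bg, structure=None)
    # binary_fill_holes fills cavities; exterior = bg not in any cavity
    exposed = exterior & ndi.binary_dilation(endo, structure=_FACE)
    out = model.copy()
    if exposed.any():
        lab = out.next_free_label()
        out.labels[exposed] = lab
        out.label_roles[lab] = "cover"
    return out


def endocast_sealed(model: LabeledVolume) -> bool:
    """True if exterior flood fill (face connectivity) cannot reach the
    endocast — i.e. covers plus skull shell enclose the cavity."""
    bg = model.labels == 0
    endo = model.mask("endocast")
    free = bg | endo
    comp, n = ndi.label(free, structure=_FACE)
    border = np.unique(
        np.concatenate(
            [
                comp[0].ravel(), comp[-1].ravel(),
                comp[:, 0].ravel(), comp[:, -1].ravel(),
                comp[:, :, 0].ravel(), comp[:, :, -1].ravel(),
            ]
        )
    )
    exterior_ids = set(border.tolist()) - {0}
    endo_ids = set(np.unique(comp[endo]).tolist()) - {0}
    return not (endo_ids & exterior_ids)
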