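"""Morphological suture synthesis.

Converts a fully disarticulated bone label volume into a bone+suture model:
bones are grown until they meet, the meeting voxels are declared suture
material, and the suture is grown and smoothed so that it fills the
inter-bone gaps without extruding over the bone.

Conventions (used everywhere in the package):

* "expansion of n voxels" = n iterations of unit dilation with a full
  3×3×3 structuring element (Chebyshev ball); label growth claims
  background only, and a voxel reachable by two labels in the same
  iteration is assigned to neither — it is recorded as a *contact* voxel.
* "contact" between labels means 26-connectivity unless face adjacency is
  explicitly required (suture bridging checks use face adjacency).
* smoothing counts (the 9/1/9 recipe) are kernel *sizes*: a smoothing of
  9 voxels votes in a 9×9×9 window (radius 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume import LabeledVolume

_CUBE = np.ones((3, 3, 3), dtype=bool)
_FACE = ndi.generate_binary_structure(3, 1)
_BIG = np.iinfo(np.int32).max


@dataclass
class MorphParams:
    """Suture-synthesis recipe parameters (all in voxels).

    ``bone_expand``/``suture_expand`` are dilation iteration counts;
    ``smooth_a``/``smooth_b`` are majority-vote kernel sizes (window side
    lengths); ``grow`` is the expansion between the two smoothing passes.
    """

    bone_expand: int = 5
    suture_expand: int = 5
    smooth_a: int = 9
    grow: int = 1
    smooth_b: int = 9
    restore_bones: bool = True
    smooth_mode: str = "solid"

    def __post_init__(self) -> None:
        for name in ("bone_expand", "suture_expand", "smooth_a", "grow", "smooth_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _box_count(mask: np.ndarray, radius: int) -> np.ndarray:
    """Exact integer count of True voxels in a (2r+1)^3 window.

    Edges are replicated so that a flat half-space remains a majority
    fixed point up to the volume boundary."""
    if radius == 0:
        return mask.astype(np.int32)
    kernel = np.ones(2 * radius + 1, dtype=np.int32)
    out = mask.astype(np.int32)
    for axis in range(3):
        out = ndi.correlate1d(out, kernel, axis=axis, mode="nearest")
    return out


def dilate_labels(
    vol: LabeledVolume,
    n: int,
    labels: list[int] | None = None,
    return_ties: bool = False,
):
    """Grow each selected label ``n`` voxels (Chebyshev) into background.

    Voxels claimable by two or more distinct labels in the same iteration
    are assigned to neither and frozen; with ``return_ties=True`` the
    frozen tie mask is returned alongside the volume.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    sel = vol.structural_labels if labels is None else list(labels)
    work = np.where(np.isin(vol.labels, sel), vol.labels, 0).astype(np.int32)
    other = vol.labels.copy()
    other[work > 0] = 0  # non-participating labels block growth
    ties = np.zeros(vol.shape, dtype=bool)

    for _ in range(n):
        lo = np.where(work > 0, work, _BIG)
        maxl = ndi.maximum_filter(work, footprint=_CUBE, mode="constant", cval=0)
        minl = ndi.minimum_filter(lo, footprint=_CUBE, mode="constant", cval=_BIG)
        cand = (work == 0) & (other == 0) & ~ties & (maxl > 0)
        tie = cand & (minl != maxl)
        ties |= tie
        grow = cand & ~tie
        work[grow] = maxl[grow]

    out_labels = vol.labels.copy()
    grown = (work > 0) & (vol.labels == 0)
    out_labels[grown] = work[grown]
    out = LabeledVolume(out_labels, vol.voxel_size, dict(vol.label_roles))
    if return_ties:
        return out, ties
    return out


def detect_contacts(
    vol_expanded: LabeledVolume,
    ties: np.ndarray | None = None,
    labels: list[int] | None = None,
) -> np.ndarray:
    """Mask of voxels where two or more distinct (expanded) bone labels meet.

    The mask is the union of dilation tie voxels and of voxels face-adjacent
    to a voxel carrying a different label from the selected set.
    """
    sel = vol_expanded.structural_labels if labels is None else list(labels)
    if not sel:
        raise ValueError("no bone labels present")
    lab = np.where(np.isin(vol_expanded.labels, sel), vol_expanded.labels, 0)
    mask = np.zeros(vol_expanded.shape, dtype=bool)
    for axis in range(3):
        a = np.swapaxes(lab, 0, axis)
        m = np.swapaxes(mask, 0, axis)
        diff = (a[:-1] != a[1:]) & (a[:-1] > 0) & (a[1:] > 0)
        m[:-1] |= diff
        m[1:] |= diff
    if ties is not None:
        mask |= ties
    return mask


def _binary_expand(mask: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return mask.copy()
    return ndi.binary_dilation(mask, structure=_CUBE, iterations=n)


def smooth_label(
    vol: LabeledVolume, label: int, radius: int, mode: str = "majority"
) -> LabeledVolume:
    """Neighbourhood-vote smoothing of one label.

    ``majority``
        Strict majority of the label's own binary mask in the
        (2·radius+1)³ window.  A flat half-space is a fixed point and a
        single protruding voxel on a plane is removed.
    ``solid``
        Vote on label ∪ structural-labels (treats bone as interior), with
        the extra requirement that the window contains at least one voxel
        of the label.  This keeps a suture confined to a thin inter-bone
        gap — where air would out-vote it — while still trimming
        protrusions into free space.
    ``gaussian``
        Gaussian blur (σ = radius/2) of the mask, rethresholded at 0.5.

    In every mode, additions are restricted to background voxels and no
    other label is ever modified.
    """
    if label not in vol.label_roles:
        raise ValueError(f"unknown label {label}")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    out = vol.copy()
    if radius == 0:
        return out
    m = vol.labels == label
    bg = vol.labels == 0
    win = (2 * radius + 1) ** 3

    if mode == "majority":
        new = 2 * _box_count(m, radius) > win
    elif mode == "solid":
        protect = np.isin(vol.labels, vol.structural_labels) & ~m
        occ = m | protect
        new = (2 * _box_count(occ, radius) > win) & (_box_count(m, radius) >= 1)
    elif mode == "gaussian":
        new = ndi.gaussian_filter(m.astype(np.float32), sigma=radius / 2.0) > 0.5
    else:
        raise ValueError(f"unknown smoothing mode {mode!r}")

    new &= m | bg  # additions only claim background
    out.labels[m & ~new] = 0
    out.labels[new & bg] = label
    return out


def nearest_pair_distance(vol: LabeledVolume, labels: list[int]) -> tuple:
    """Closest pair of labels and their surface distance in voxels."""
    best = (None, np.inf)
    for i, a in enumerate(labels):
        da = ndi.distance_transform_edt(vol.labels != a)
        for b in labels[i + 1 :]:
            d = da[vol.labels == b].min() if (vol.labels == b).any() else np.inf
            if d < best[1]:
                best = ((a, b), float(d))
    return best


def synthesize_sutures(
    vol: LabeledVolume, p: MorphParams | None = None
) -> LabeledVolume:
    """Run the full suture-generation recipe on a disarticulated model.

    Order: dilate bones ``bone_expand`` → record contacts → dilate contacts
    ``suture_expand`` (restricted to original background) → smooth
    (``smooth_a`` kernel) → grow ``grow`` → smooth (``smooth_b`` kernel).
    Bones are restored to their original extent (``restore_bones``), the
    suture occupies former background only, and every surviving suture
    component is face-adjacent to at least two bones.
    """
    p = p or MorphParams()
    bones = vol.structural_labels
    if len(bones) < 2:
        raise ValueError("need at least 2 bone labels to synthesize sutures")

    expanded, ties = dilate_labels(vol, p.bone_expand, labels=bones, return_ties=True)
    contacts = detect_contacts(expanded, ties, labels=bones)
    if not contacts.any():
        pair, dist = nearest_pair_distance(vol, bones)
        raise ValueError(
            f"disjoint model: no contacts after expanding {p.bone_expand} "
            f"voxels; nearest pair {pair} is {dist:.1f} voxels apart"
        )

    # the suture must follow the shell: keep it inside the Euclidean
    # envelope of the bones so it never wanders into the cavity or free air
    envelope = ndi.distance_transform_edt(
        ~np.isin(vol.labels, bones)
    ) <= (p.bone_expand + 1)
    bg0 = (vol.labels == 0) & envelope
    suture = _binary_expand(contacts, p.suture_expand) & bg0

    suture_label = vol.next_free_label()
    roles = dict(vol.label_roles)
    roles[suture_label] = "suture"

    def _with_suture(mask: np.ndarray) -> LabeledVolume:
        lab = vol.labels.copy()
        lab[mask] = suture_label
        return LabeledVolume(lab, vol.voxel_size, roles)

    r_a = (p.smooth_a - 1) // 2
    r_b = (p.smooth_b - 1) // 2
    work = smooth_label(_with_suture(suture), suture_label, r_a, mode=p.smooth_mode)
    suture = work.labels == suture_label
    suture = _binary_expand(suture, p.grow) & bg0
    work = smooth_label(_with_suture(suture), suture_label, r_b, mode=p.smooth_mode)
    suture = (work.labels == suture_label) & bg0

    # drop any suture component not bridging at least two bones
    comp, n_comp = ndi.label(suture, structure=_FACE)
    if n_comp:
        keep = np.zeros(n_comp + 1, dtype=bool)
        bone_arr = np.where(np.isin(vol.labels, bones), vol.labels, 0)
        for c in range(1, n_comp + 1):
            touching = set()
            cm = comp == c
            for axis in range(3):
                a = np.swapaxes(bone_arr, 0, axis)
                m = np.swapaxes(cm, 0, axis)
                touching.update(np.unique(a[:-1][m[1:]]))
                touching.update(np.unique(a[1:][m[:-1]]))
            touching.discard(0)
            keep[c] = len(touching) >= 2
        suture &= keep[comp]

    out = vol.copy() if p.restore_bones else expanded.copy()
    out.labels[suture] = suture_label
    out.label_roles = roles
    return out


def segment_sutures(
    vol: LabeledVolume, include_cover: bool = False
) -> tuple[np.ndarray, dict[tuple[int, int], int]]:
    """Partition soft (suture/cover) voxels by their two nearest bones.

    Returns ``(pair_index_volume, pair_to_index)`` where the volume holds,
    per soft voxel, a 1-based index into the sorted list of bone-label
    pairs and 0 elsewhere.  This is how "the coronal suture", "the
    basal ring" etc. are told apart in a model with a single suture label.
    """
    roles = ["suture", "cover"] if include_cover else ["suture"]
    soft = vol.mask(roles[0])
    for r in roles[1:]:
        soft |= vol.mask(r)
    bones = vol.structural_labels
    if len(bones) < 2:
        raise ValueError("need at least 2 bone labels")
    idx = np.argwhere(soft)
    dists = np.empty((len(bones), idx.shape[0]))
    for i, b in enumerate(bones):
        dt = ndi.distance_transform_edt(vol.labels != b)
        dists[i] = dt[soft]
    order = np.argsort(dists, axis=0, kind="stable")
    a = np.minimum(order[0], order[1])
    b = np.maximum(order[0], order[1])
    pair_codes = a * len(bones) + b
    uniq = np.unique(pair_codes)
    pair_to_index = {}
    code_to_idx = np.zeros(uniq.max() + 1, dtype=np.int32)
    for k, code in enumerate(uniq.tolist(), start=1):
        pair = (bones[code // len(bones)], bones[code % len(bones)])
        pair_to_index[pair] = k
        code_to_idx[code] = k
    out = np.zeros(vol.shape, dtype=np.int32)
    out[soft] = code_to_idx[pair_codes]
    return out, pair_to_index
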