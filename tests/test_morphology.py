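"""Suture synthesis morphology: dilation, contacts, smoothing, full recipe.

The dilation and smoothing operators are checked against brute-force
implementations that examine every voxel's neighbourhood explicitly
(shift-and-stack, plus pure-Python spot checks), independent of the
ndimage-filter implementations they validate.
"""

import numpy as np
import pytest
from scipy import ndimage as ndi

from calvaria.morphology import (
    MorphParams,
    detect_contacts,
    dilate_labels,
    segment_sutures,
    smooth_label,
    synthesize_sutures,
)
from calvaria.volume import LabeledVolume


# --------------------------------------------------------------------------
# brute-force oracles
# --------------------------------------------------------------------------

def _shifts(radius):
    r = range(-radius, radius + 1)
    return [(dx, dy, dz) for dx in r for dy in r for dz in r]


def _shifted(arr, d, fill=0):
    out = np.full_like(arr, fill)
    src = [slice(max(-d[i], 0), arr.shape[i] - max(d[i], 0)) for i in range(3)]
    dst = [slice(max(d[i], 0), arr.shape[i] - max(-d[i], 0)) for i in range(3)]
    out[tuple(dst)] = arr[tuple(src)]
    return out


def oracle_dilate(labels, n):
    """Brute-force multi-label dilation with tie → frozen contact."""
    work = labels.copy()
    ties = np.zeros(labels.shape, dtype=bool)
    for _ in range(n):
        stack = np.stack([_shifted(work, d) for d in _shifts(1)])
        hi = stack.max(axis=0)
        second = np.where(stack == hi[None], 0, stack).max(axis=0)
        cand = (work == 0) & ~ties & (hi > 0)
        tie = cand & (second > 0)
        ties |= tie
        grow = cand & ~tie
        work[grow] = hi[grow]
    return work, ties


def oracle_box_count(mask, radius):
    """Window sum with edge replication, via explicit offset accumulation."""
    pad = np.pad(mask.astype(np.int64), radius, mode="edge")
    out = np.zeros(mask.shape, dtype=np.int64)
    sx, sy, sz = mask.shape
    for dx, dy, dz in _shifts(radius):
        out += pad[
            radius + dx : radius + dx + sx,
            radius + dy : radius + dy + sy,
            radius + dz : radius + dz + sz,
        ]
    return out


def oracle_smooth(vol, label, radius, mode):
    m = vol.labels == label
    bg = vol.labels == 0
    win = (2 * radius + 1) ** 3
    if mode == "majority":
        new = 2 * oracle_box_count(m, radius) > win
    else:  # solid
        protect = np.isin(vol.labels, vol.structural_labels) & ~m
        new = (2 * oracle_box_count(m | protect, radius) > win) & (
            oracle_box_count(m, radius) >= 1
        )
    new &= m | bg
    out = vol.labels.copy()
    out[m & ~new] = 0
    out[new & bg] = label
    return out


def random_label_volume(rng, shape, n_labels=4):
    noise = ndi.gaussian_filter(rng.standard_normal(shape), 2.0)
    mask = noise > np.quantile(noise, 0.75)
    comp, n = ndi.label(mask)
    labels = np.where(comp > 0, (comp - 1) % n_labels + 1, 0).astype(np.int32)
    roles = {l: "bone" for l in np.unique(labels) if l != 0}
    return LabeledVolume(labels, 25.0, roles)


# --------------------------------------------------------------------------
# dilation
# --------------------------------------------------------------------------

class TestDilateLabels:
    def test_zero_iterations_is_identity(self):
        lab = np.zeros((8, 8, 8), np.int32)
        lab[3, 3, 3] = 1
        vol = LabeledVolume(lab, 10.0, {1: "bone"})
        out = dilate_labels(vol, 0)
        assert np.array_equal(out.labels, lab)

    def test_isolated_cube_grows_to_125(self):
        lab = np.zeros((11, 11, 11), np.int32)
        lab[4:7, 4:7, 4:7] = 1
        vol = LabeledVolume(lab, 10.0, {1: "bone"})
        out = dilate_labels(vol, 1)
        assert (out.labels == 1).sum() == 125

    def test_two_labels_four_apart_meet_without_overlap(self):
        lab = np.zeros((9, 9, 20), np.int32)
        lab[:, :, 2:4] = 1
        lab[:, :, 8:10] = 2   # 4 background voxels between
        vol = LabeledVolume(lab, 10.0, {1: "bone", 2: "bone"})
        out, ties = dilate_labels(vol, 5, return_ties=True)
        contacts = detect_contacts(out, ties)
        assert contacts.any()
        # each voxel carries exactly one label
        assert ((out.labels == 1) & (out.labels == 2)).sum() == 0
        # original labels unchanged
        assert (out.labels[vol.labels > 0] == vol.labels[vol.labels > 0]).all()

    def test_matches_bruteforce_on_random_volumes(self, rng):
        """Exhaustive per-voxel oracle equivalence (dilation)."""
        for k in range(8):
            shape = tuple(rng.integers(10, 40, 3))
            vol = random_label_volume(rng, shape)
            n = int(rng.integers(1, 4))
            out, ties = dilate_labels(
                vol, n, labels=vol.structural_labels, return_ties=True
            )
            ref, ref_ties = oracle_dilate(vol.labels, n)
            assert np.array_equal(out.labels, ref), f"case {k}"
            assert np.array_equal(ties, ref_ties), f"case {k}"

    def test_python_spot_check_single_step(self, rng):
        """Pure-Python neighbourhood audit of a one-step dilation."""
        vol = random_label_volume(rng, (16, 16, 16))
        out, ties = dilate_labels(vol, 1, return_ties=True)
        lab = vol.labels
        for _ in range(100):
            p = tuple(rng.integers(1, 15, 3))
            if lab[p] != 0:
                continue
            neigh = {
                int(lab[p[0] + dx, p[1] + dy, p[2] + dz])
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            } - {0}
            if len(neigh) == 0:
                assert out.labels[p] == 0 and not ties[p]
            elif len(neigh) == 1:
                assert out.labels[p] == neigh.pop() and not ties[p]
            else:
                assert out.labels[p] == 0 and ties[p]


# --------------------------------------------------------------------------
# contacts
# --------------------------------------------------------------------------

class TestDetectContacts:
    def test_single_label_empty(self):
        lab = np.zeros((6, 6, 6), np.int32)
        lab[2:4, 2:4, 2:4] = 1
        vol = LabeledVolume(lab, 10.0, {1: "bone"})
        assert not detect_contacts(vol).any()

    def test_no_bone_labels_rejected(self):
        vol = LabeledVolume(np.zeros((4, 4, 4), np.int32), 10.0, {})
        with pytest.raises(ValueError, match="no bone labels"):
            detect_contacts(vol)

    def test_bridged_gap_contact_is_connected_sheet(self):
        lab = np.zeros((9, 9, 20), np.int32)
        lab[:, :, 2:4] = 1
        lab[:, :, 8:10] = 2
        vol = LabeledVolume(lab, 10.0, {1: "bone", 2: "bone"})
        out, ties = dilate_labels(vol, 5, return_ties=True)
        mask = detect_contacts(out, ties)
        comp, n = ndi.label(mask, structure=np.ones((3, 3, 3), bool))
        assert n == 1
        # the sheet spans the former gap region
        assert mask[:, :, 4:8].any()

    def test_triple_junction_detected(self):
        # three wedge labels around the volume axis, meeting at a line
        n = 21
        lab = np.zeros((5, n, n), np.int32)
        y, z = np.mgrid[0:n, 0:n] - n // 2
        ang = np.arctan2(z, y)
        for i, (lo, hi) in enumerate([(-np.pi, -np.pi / 3), (-np.pi / 3, np.pi / 3),
                                      (np.pi / 3, np.pi)]):
            lab[:, (ang >= lo) & (ang < hi)] = i + 1
        lab[:, n // 2, n // 2] = 0
        vol = LabeledVolume(lab, 10.0, {1: "bone", 2: "bone", 3: "bone"})
        mask = detect_contacts(vol)
        assert mask[:, n // 2 - 1 : n // 2 + 2, n // 2 - 1 : n // 2 + 2].any()


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

class TestSmoothLabel:
    def _plane(self):
        lab = np.zeros((12, 12, 12), np.int32)
        lab[:, :, :6] = 1
        return LabeledVolume(lab, 10.0, {1: "suture"})

    def test_radius_zero_identity(self):
        vol = self._plane()
        assert np.array_equal(smooth_label(vol, 1, 0).labels, vol.labels)

    def test_half_space_is_fixed_point(self):
        vol = self._plane()
        out = smooth_label(vol, 1, 2)
        assert np.array_equal(out.labels, vol.labels)

    def test_protrusion_removed(self):
        lab = np.zeros((12, 12, 12), np.int32)
        lab[:, :, :6] = 1
        lab[6, 6, 6] = 1  # single protruding voxel
        vol = LabeledVolume(lab, 10.0, {1: "suture"})
        out = smooth_label(vol, 1, 1)
        assert out.labels[6, 6, 6] == 0
        assert (out.labels[:, :, :6] == 1).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            smooth_label(self._plane(), 9, 1)

    @pytest.mark.parametrize("mode", ["majority", "solid"])
    def test_matches_bruteforce(self, rng, mode):
        """Exhaustive per-voxel oracle equivalence (smoothing)."""
        for k in range(6):
            shape = tuple(rng.integers(12, 34, 3))
            vol = random_label_volume(rng, shape, n_labels=3)
            # re-role one label as the suture being smoothed
            labs = sorted(set(np.unique(vol.labels)) - {0})
            if not labs:
                continue
            vol.label_roles[labs[0]] = "suture"
            radius = int(rng.integers(1, 3))
            out = smooth_label(vol, labs[0], radius, mode=mode)
            ref = oracle_smooth(vol, labs[0], radius, mode)
            assert np.array_equal(out.labels, ref), f"case {k} mode {mode}"

    def test_solid_mode_keeps_thin_gap_suture(self):
        # suture confined to a 3-voxel slot between bone slabs survives a
        # window larger than the slot; plain majority would erase it
        lab = np.zeros((15, 15, 15), np.int32)
        lab[:, :, :6] = 1
        lab[:, :, 9:] = 2
        lab[:, :, 6:9] = 3
        vol = LabeledVolume(lab, 10.0, {1: "bone", 2: "bone", 3: "suture"})
        out = smooth_label(vol, 3, 4, mode="solid")
        assert (out.labels[:, :, 6:9] == 3).all()
        gone = smooth_label(vol, 3, 4, mode="majority")
        assert not (gone.labels == 3).any()


# --------------------------------------------------------------------------
# full recipe
# --------------------------------------------------------------------------

class TestSynthesizeSutures:
    def _two_slabs(self, gap):
        lab = np.zeros((12, 12, 24 + gap), np.int32)
        lab[2:10, 2:10, 2:12] = 1
        lab[2:10, 2:10, 12 + gap : 22 + gap] = 2
        return LabeledVolume(lab, 10.0, {1: "bone", 2: "bone"})

    def test_gap_fully_bridged(self):
        vol = self._two_slabs(4)
        out = synthesize_sutures(vol, MorphParams(5, 5, 9, 1, 9))
        s = out.labels_with_role("suture")[0]
        # every former-gap voxel between the slabs is suture
        assert (out.labels[2:10, 2:10, 12:16] == s).all()
        # bones untouched, suture only in former background
        assert (out.labels[vol.labels > 0] == vol.labels[vol.labels > 0]).all()
        assert ((out.labels == s) & (vol.labels > 0)).sum() == 0

    def test_touching_plates_get_interface_collar(self):
        vol = self._two_slabs(0)
        out = synthesize_sutures(vol, MorphParams(2, 1, 3, 1, 3))
        s = out.labels_with_role("suture")[0]
        sut = out.labels == s
        assert sut.any()
        # collar touches both bones (face adjacency)
        grown = ndi.binary_dilation(sut, ndi.generate_binary_structure(3, 1))
        assert (vol.labels[grown] == 1).any() and (vol.labels[grown] == 2).any()
        assert (out.labels[vol.labels > 0] == vol.labels[vol.labels > 0]).all()

    def test_distant_bones_give_disjoint_error(self):
        vol = self._two_slabs(12)  # 12 > 2 × 5
        with pytest.raises(ValueError, match="disjoint model"):
            synthesize_sutures(vol, MorphParams(5, 5, 9, 1, 9))

    def test_distant_pair_not_bridged_when_another_is(self):
        lab = np.zeros((12, 12, 44), np.int32)
        lab[2:10, 2:10, 2:12] = 1
        lab[2:10, 2:10, 16:26] = 2    # 4 from label 1
        lab[2:10, 2:10, 38:42] = 3    # 12 from label 2
        vol = LabeledVolume(lab, 10.0, {1: "bone", 2: "bone", 3: "bone"})
        out = synthesize_sutures(vol, MorphParams(5, 5, 9, 1, 9))
        s = out.labels_with_role("suture")[0]
        assert (out.labels[2:10, 2:10, 12:16] == s).all()
        assert not (out.labels[2:10, 2:10, 27:37] == s).any()

    def test_single_bone_rejected(self):
        lab = np.zeros((8, 8, 8), np.int32)
        lab[2:6, 2:6, 2:6] = 1
        with pytest.raises(ValueError, match="at least 2"):
            synthesize_sutures(LabeledVolume(lab, 10.0, {1: "bone"}))

    def test_suture_monotone_in_expansion(self):
        vol = self._two_slabs(4)
        counts = []
        for se in (1, 3, 5):
            out = synthesize_sutures(vol, MorphParams(5, se, 3, 1, 3))
            s = out.labels_with_role("suture")[0]
            counts.append(int((out.labels == s).sum()))
        assert counts[0] <= counts[1] <= counts[2]

    def test_bridging_connectivity(self):
        vol = self._two_slabs(4)
        out = synthesize_sutures(vol, MorphParams(5, 5, 9, 1, 9))
        s = out.labels_with_role("suture")[0]
        path_mask = np.isin(out.labels, [1, 2, s])
        _, n = ndi.label(path_mask, ndi.generate_binary_structure(3, 1))
        assert n == 1  # bone–suture–bone is one face-connected component


def test_segment_sutures_pairs():
    lab = np.zeros((8, 8, 20), np.int32)
    lab[2:6, 2:6, 2:6] = 1
    lab[2:6, 2:6, 8:10] = 9     # suture between 1 and 2
    lab[2:6, 2:6, 12:16] = 2
    vol = LabeledVolume(lab, 10.0, {1: "bone", 2: "bone", 9: "suture"})
    pair_vol, pairs = segment_sutures(vol)
    assert pairs == {(1, 2): 1}
    assert (pair_vol[lab == 9] == 1).all()
    assert (pair_vol[lab != 9] == 0).all()
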