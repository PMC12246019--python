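"""Coronal-suture gap measurement and unloaded/loaded comparison.

The gap between two bones is measured per mediolateral CT slice: within a
window around the inter-bone interface, the most dorsal voxel of each bone
is located and the in-slice distance between them — corrected by one voxel
so that an n-voxel gap reads n voxel sizes — is recorded in mm.  Slices
where the bones touch (zero gap, i.e. fused) are excluded but counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volume import LabeledVolume


@dataclass
class GapMeasurementSet:
    """Per-slice gap distances (mm) plus exclusion bookkeeping."""

    slice_indices: np.ndarray
    distances: np.ndarray            # mm, strictly positive
    n_excluded_fused: int
    side: str = "left"
    state: str = "unloaded"
    stride: int = 10

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.slice_indices = np.asarray(self.slice_indices, dtype=int)
        if (self.distances <= 0).any():
            raise ValueError("zero/negative gaps must be excluded, not stored")
        if self.slice_indices.size > 1:
            d = np.diff(self.slice_indices)
            # strictly increasing on the sampling comb (excluded slices
            # leave holes, so differences are positive stride multiples)
            if (d <= 0).any() or (d % max(self.stride, 1) != 0).any():
                raise ValueError("slice indices must increase along the stride")

    @property
    def n_measured(self) -> int:
        return int(self.distances.size)

    def mean(self) -> float:
        return float(self.distances.mean())


def _dorsal_edge(slice2d: np.ndarray, label: int, z_window: tuple[int, int]):
    """(y, z) of the most dorsal voxel of ``label`` within the window;
    ties broken toward the window centre (the interface)."""
    ys, zs = np.nonzero(slice2d == label)
    ok = (zs >= z_window[0]) & (zs <= z_window[1])
    if not ok.any():
        return None
    ys, zs = ys[ok], zs[ok]
    top = ys == ys.max()
    ys, zs = ys[top], zs[top]
    mid = 0.5 * (z_window[0] + z_window[1])
    j = int(np.argmin(np.abs(zs - mid)))
    return float(ys[j]), float(zs[j])


def measure_gap(
    vol: LabeledVolume,
    bone_a: int,
    bone_b: int,
    slice_range: tuple[int, int] | None = None,
    stride: int = 10,
    window_vox: int = 20,
    side: str = "left",
    state: str = "unloaded",
) -> GapMeasurementSet:
    """Measure the dorsal-edge gap between two bones every ``stride``
    mediolateral slices over ``slice_range``.

    Per sampled slice the interface position is the midpoint between the
    facing extents of the bones; dorsal edges are searched within
    ``±window_vox`` voxels of it along the anteroposterior axis.  Slices
    where the bones touch (face adjacency, or sub-voxel separation) are
    excluded as fused and counted.
    """
    labels = vol.labels
    if slice_range is None:
        slice_range = (0, labels.shape[0])
    lo, hi = slice_range
    sampled = list(range(lo, hi, stride))
    v_mm = vol.voxel_size * 1e-3

    idx, dist = [], []
    n_fused = 0
    n_absent = 0
    for i in sampled:
        sl = labels[i]
        a_mask = sl == bone_a
        b_mask = sl == bone_b
        if not a_mask.any() or not b_mask.any():
            n_absent += 1
            continue
        # interface: midpoint between facing anteroposterior extents
        za = np.nonzero(a_mask.any(axis=0))[0]
        zb = np.nonzero(b_mask.any(axis=0))[0]
        if za.mean() <= zb.mean():
            zi = 0.5 * (za.max() + zb.min())
        else:
            zi = 0.5 * (zb.max() + za.min())
        win = (int(np.floor(zi - window_vox)), int(np.ceil(zi + window_vox)))
        ea = _dorsal_edge(sl, bone_a, win)
        eb = _dorsal_edge(sl, bone_b, win)
        if ea is None or eb is None:
            n_absent += 1
            continue
        center_d = float(np.hypot(ea[0] - eb[0], ea[1] - eb[1]))
        gap = (center_d - 1.0) * v_mm  # face-to-face: n-voxel gap reads n·h
        touching = _touch_in_window(sl, bone_a, bone_b, win)
        if touching or gap <= 0:
            n_fused += 1
            continue
        idx.append(i)
        dist.append(gap)
    if n_absent > len(sampled) / 2:
        raise ValueError(
            f"bones {bone_a}/{bone_b} absent in {n_absent} of {len(sampled)} slices"
        )
    return GapMeasurementSet(
        np.asarray(idx), np.asarray(dist), n_fused, side, state, stride
    )


def _touch_in_window(sl, a, b, win) -> bool:
    sub = sl[:, max(win[0], 0) : win[1] + 1]
    am = sub == a
    bm = sub == b
    for axis in (0, 1):
        aa = np.swapaxes(am, 0, axis)
        bb = np.swapaxes(bm, 0, axis)
        if (aa[:-1] & bb[1:]).any() or (bb[:-1] & aa[1:]).any():
            return True
    return False


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's one-way ANOVA (unequal variances), returning (F*, p)."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    A = (w * (m - mw) ** 2).sum() / (k - 1)
    B = 1 + (2 * (k - 2) / (k**2 - 1)) * ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    F = A / B
    df2 = (k**2 - 1) / (3 * ((1 - w / w.sum()) ** 2 / (n - 1)).sum())
    p = float(stats.f.sf(F, k - 1, df2))
    return float(F), p


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_states(
    unloaded: GapMeasurementSet, loaded: GapMeasurementSet
) -> dict:
    """Loaded-vs-unloaded gap change with one-way ANOVA and Levene's test.

    Change ratio is (mean_loaded − mean_unloaded)/mean_unloaded — "times
    the original length".  Levene's test uses the median-centred
    (Brown–Forsythe) variant; when it rejects homogeneity at p < 0.05,
    Welch's ANOVA is reported alongside the classic one rather than
    silently replacing it.
    """
    if unloaded.n_measured == 0 or loaded.n_measured == 0:
        raise ValueError("both measurement sets must be non-empty")
    u, l = unloaded.distances, loaded.distances
    ratio = (l.mean() - u.mean()) / u.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(u, l)
        W, p_lev = stats.levene(u, l, center="median")
    if not np.isfinite(F):  # zero within-group variance
        F, p = (0.0, 1.0) if np.isclose(u.mean(), l.mean()) else (np.inf, 0.0)
    if not np.isfinite(W):
        W, p_lev = 0.0, 1.0
    out = {
        "ratio": float(ratio),
        "anova_F": float(F),
        "anova_p": float(p),
        "levene_W": float(W),
        "levene_p": float(p_lev),
        "stars": significance_stars(float(p)),
        "mean_unloaded_mm": float(u.mean()),
        "mean_loaded_mm": float(l.mean()),
        "n_unloaded": unloaded.n_measured,
        "n_loaded": loaded.n_measured,
    }
    if p_lev < 0.05:
        Fw, pw = welch_anova([u, l])
        out["welch_F"] = Fw
        out["welch_p"] = pw
    return out
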