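"""Synthetic calvaria phantoms and ground-truth deformations.

Real neonatal-mouse micro-CT data cannot be redistributed, so every
downstream stage (suture synthesis, endocast extraction, meshing, FE, strain
estimation, gap measurement, calibration) is exercised on phantoms generated
here: a thin hemispherical multi-plate "calvaria" with micrometre-scale
planar inter-plate gaps (sutures), an optional basal plate sealing the
cavity (endocast), two constraint patches (anterior, mimicking incisor
contact; posterior-ventral, mimicking basioccipital fixation), and
loaded/unloaded surface pairs produced by known per-plate rigid motions.

The dome axis is dorsoventral (axis 1); plates are spherical wedges about
the mediolateral axis (axis 0), ordered posterior → anterior, so the
inter-plate gaps are "coronal-like": planar, containing the mediolateral
axis.  Gap widths are analytically exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import Rigid
from .volume import LabeledVolume

MARGIN_VOX = 3  # empty border around the phantom, voxels


@dataclass
class PhantomSpec:
    """Geometry of a synthetic hemispherical multi-plate calvaria.

    All lengths in µm.  ``seed`` is stored for provenance; the construction
    itself is deterministic.
    """

    outer_radius: float = 2000.0
    shell_thickness: float = 200.0
    gap_width: float = 50.0
    n_plates: int = 4
    voxel_size: float = 25.0
    cavity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.outer_radius > self.shell_thickness > 0:
            raise ValueError("need outer_radius > shell_thickness > 0")
        if self.gap_width < 0:
            raise ValueError("gap_width must be >= 0")
        if self.n_plates < 2:
            raise ValueError("need at least 2 plates")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        arc = (np.pi / self.n_plates) * (self.outer_radius - self.shell_thickness / 2)
        if self.gap_width >= arc:
            raise ValueError(
                f"degenerate plate: gap_width {self.gap_width} µm >= plate "
                f"angular extent (~{arc:.0f} µm arc at mid-shell)"
            )

    # label book-keeping ------------------------------------------------
    @property
    def plate_labels(self) -> list[int]:
        return list(range(1, self.n_plates + 1))

    @property
    def base_label(self) -> int | None:
        return self.n_plates + 1 if self.cavity else None

    @property
    def anterior_label(self) -> int:
        return self.n_plates + (2 if self.cavity else 1)

    @property
    def posterior_label(self) -> int:
        return self.anterior_label + 1


@dataclass
class GroundTruthDeformation:
    """Known per-plate rigid motions plus nominal suture geometry.

    ``transforms`` act on physical µm coordinates (voxel-corner origin).
    ``nominal_opening`` / ``nominal_width`` record, per bone-label pair, the
    prescribed normal opening and the undeformed gap width in µm.
    """

    transforms: dict[int, Rigid] = field(default_factory=dict)
    nominal_opening: dict[tuple[int, int], float] = field(default_factory=dict)
    nominal_width: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.nominal_width.values():
            if w <= 0:
                raise ValueError("nominal width must be > 0")


def _grids(spec: PhantomSpec):
    v = spec.voxel_size
    rv = spec.outer_radius / v
    m = MARGIN_VOX
    nx = int(np.ceil(2 * rv)) + 2 * m
    ny = int(np.ceil(rv)) + 2 * m
    nz = nx
    # voxel-center physical coordinates relative to the dome center,
    # which sits on the y = 0 equatorial plane
    cx = nx / 2.0
    cy = float(m)
    cz = nz / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    x = (ii + 0.5 - cx) * v
    y = (jj + 0.5 - cy) * v
    z = (kk + 0.5 - cz) * v
    return (nx, ny, nz), x, y, z


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Voxelize the phantom described by ``spec``.

    Returns a fully disarticulated model: ``n_plates`` wedge plates
    (labels 1..n), an optional basal plate sealing the cavity, and two
    constraint patches carved out of the most anterior / most
    posterior-ventral solid voxels.  No two structural labels touch when
    ``gap_width > 0``.
    """
    v = spec.voxel_size
    shape, x, y, z = _grids(spec)
    r = np.sqrt(x * x + y * y + z * z)
    r_in = spec.outer_radius - spec.shell_thickness

    shell = (r <= spec.outer_radius) & (r >= r_in) & (y >= 0)

    # wedge partition about the mediolateral axis: angle in the (z, y)
    # plane from posterior (-z) through dorsal to anterior (+z)
    cuts = -np.pi / 2 + np.arange(1, spec.n_plates) * np.pi / spec.n_plates
    plate_idx = np.zeros(shape, dtype=np.int32)
    in_gap = np.zeros(shape, dtype=bool)
    for phi in cuts:
        s = z * np.cos(phi) - y * np.sin(phi)  # signed distance to cut plane
        plate_idx += (s > 0).astype(np.int32)
        in_gap |= np.abs(s) < spec.gap_width / 2.0

    labels = np.zeros(shape, dtype=np.int32)
    labels[shell & ~in_gap] = plate_idx[shell & ~in_gap] + 1
    roles = {l: "bone" for l in spec.plate_labels}

    if spec.cavity:
        rho = np.sqrt(x * x + z * z)
        rb = r_in - spec.gap_width
        base = (y >= 0) & (y < spec.shell_thickness) & (rho <= rb) & (r < r_in)
        base &= labels == 0
        labels[base] = spec.base_label
        roles[spec.base_label] = "bone"

    # constraint patches: carved from the solid, at the anterior and the
    # posterior-ventral extremes (stand-ins for incisor / basioccipital)
    solid = labels > 0
    patch = 2.5 * v
    zs = z[solid]
    ant = solid & (z >= zs.max() - patch)
    post = solid & (z <= zs.min() + patch) & (y < spec.shell_thickness + patch)
    if ant.any():
        labels[ant] = spec.anterior_label
        roles[spec.anterior_label] = "constraint"
    if post.any():
        labels[post] = spec.posterior_label
        roles[spec.posterior_label] = "constraint"

    return LabeledVolume(labels, v, roles)


def cut_normals(spec: PhantomSpec) -> list[np.ndarray]:
    """Unit normals (pointing anterior) of the inter-plate gap planes,
    ordered posterior → anterior; suture k separates plates k+1 and k+2."""
    cuts = -np.pi / 2 + np.arange(1, spec.n_plates) * np.pi / spec.n_plates
    return [np.array([0.0, -np.sin(phi), np.cos(phi)]) for phi in cuts]


def opening_ground_truth(
    spec: PhantomSpec, suture_index: int, opening_um: float
) -> GroundTruthDeformation:
    """Rigid-translation ground truth that opens one inter-plate gap.

    Every plate anterior of cut plane ``suture_index`` (0-based) moves by
    ``opening_um`` along that plane's normal; everything else stays put.
    """
    normals = cut_normals(spec)
    n = normals[suture_index]
    gt = GroundTruthDeformation()
    for lab in spec.plate_labels:
        moving = (lab - 1) > suture_index
        gt.transforms[lab] = (
            Rigid.translation(opening_um * n) if moving else Rigid.identity()
        )
    if spec.cavity:
        gt.transforms[spec.base_label] = Rigid.identity()
    gt.transforms[spec.anterior_label] = gt.transforms.get(
        spec.plate_labels[-1], Rigid.identity()
    )
    gt.transforms[spec.posterior_label] = Rigid.identity()
    pair = (suture_index + 1, suture_index + 2)
    gt.nominal_opening[pair] = opening_um
    gt.nominal_width[pair] = max(spec.gap_width, spec.voxel_size)
    return gt


def generate_loaded_pair(
    vol: LabeledVolume, gt: GroundTruthDeformation, presmooth: float = 2.0
):
    """Extract per-bone surfaces and their rigidly moved counterparts.

    Returns ``(unloaded, loaded)`` surface meshes (mm) with identical
    topology and per-vertex bone labels; the loaded surface is the exact
    image of the unloaded one under the stored per-bone transforms, so the
    pair carries perfect vertex correspondence.
    """
    from .meshing import extract_surface

    present = vol.structural_labels
    missing = [l for l in present if l not in gt.transforms]
    if missing:
        raise ValueError(f"missing transform for labels {missing}")

    unloaded = extract_surface(vol, presmooth=presmooth, labels=present)
    loaded = unloaded.copy()
    for lab in present:
        T = gt.transforms[lab].scale_translation(1e-3)  # µm → mm translation
        sel = loaded.vertex_region == lab
        loaded.vertices[sel] = T.apply(loaded.vertices[sel])
    return unloaded, loaded


def generate_gap_stack(
    gap_profile_um, voxel_size: float, height_vox: int = 12, block_vox: int = 20
) -> LabeledVolume:
    """Two-bone fixture with a per-slice prescribed dorsal-edge gap.

    Slice ``i`` (mediolateral axis 0) contains two rectangular bone blocks
    separated along the anteroposterior axis by ``round(gap_profile[i] /
    voxel_size)`` background voxels, so the dorsal-edge face-to-face
    separation equals the profile to within half a voxel.  A zero profile
    value produces face-contact (a fused slice).
    """
    profile = np.asarray(gap_profile_um, dtype=float)
    if (profile < 0).any():
        raise ValueError("gap profile values must be >= 0")
    n_gap = np.rint(profile / voxel_size).astype(int)
    n_slices = profile.size
    m = 2
    z0 = m + block_vox
    nz = z0 + int(n_gap.max()) + block_vox + m
    ny = m + height_vox + m
    labels = np.zeros((n_slices + 2 * m, ny, nz), dtype=np.int32)
    for i in range(n_slices):
        sl = labels[m + i]
        sl[m : m + height_vox, m:z0] = 1
        b0 = z0 + n_gap[i]
        sl[m : m + height_vox, b0 : b0 + block_vox] = 2
    return LabeledVolume(labels, voxel_size, {1: "bone", 2: "bone"})


def calibration_rig(
    voxel_size: float = 100.0,
    plate_half_lengths=(120, 60, 30),
    width_vox: int = 6,
    thickness_vox: int = 2,
    gap_vox: int = 2,
    clamp_vox: int = 4,
) -> tuple[LabeledVolume, np.ndarray]:
    """Three clamped beam pairs joined by thin sutures, for modulus sweeps.

    Each pair is two slender plates (clamped at their outer ends) meeting
    at a mid-span suture; the three spans are staggered so that bone
    bending compliance crosses over suture compliance at different moduli
    — together the per-suture strains stay sensitive to the bone modulus
    over the whole 10–7000 MPa sweep range, which a dome phantom with
    fat compliant sutures is not.

    Returns the labeled volume and the load point (mm) of a dorsoventral
    disc load that engages all three beams.
    """
    halves = sorted(plate_half_lengths, reverse=True)
    m = 2
    span = 2 * max(halves) + gap_vox + 2 * clamp_vox
    nz = span + 2 * m
    ny = thickness_vox + 2 * 3
    nx = m + len(halves) * (width_vox + 3) + m
    lab = np.zeros((nx, ny, nz), np.int32)
    y0 = 3
    zc = nz // 2  # suture centre plane
    roles: dict[int, str] = {}
    clamp_l, clamp_r = 2 * len(halves) + 2, 2 * len(halves) + 3
    for i, L in enumerate(halves):
        x0 = m + i * (width_vox + 3)
        xs = slice(x0, x0 + width_vox)
        ys = slice(y0, y0 + thickness_vox)
        a, b = 2 * i + 1, 2 * i + 2
        g0 = zc - gap_vox // 2
        lab[xs, ys, g0 - L : g0] = a
        lab[xs, ys, g0 : g0 + gap_vox] = 2 * len(halves) + 1  # suture
        lab[xs, ys, g0 + gap_vox : g0 + gap_vox + L] = b
        lab[xs, ys, g0 - L - clamp_vox : g0 - L] = clamp_l
        lab[xs, ys, g0 + gap_vox + L : g0 + gap_vox + L + clamp_vox] = clamp_r
        roles[a] = roles[b] = "bone"
    roles[2 * len(halves) + 1] = "suture"
    roles[clamp_l] = roles[clamp_r] = "constraint"
    vol = LabeledVolume(lab, voxel_size, roles)
    v_mm = voxel_size * 1e-3
    load_point = np.array(
        [nx / 2 * v_mm, (y0 + thickness_vox) * v_mm,
         (zc - gap_vox // 2 - min(halves) // 3) * v_mm]
    )
    return vol, load_point


def suture_slab(
    gap_vox: int = 4,
    plate_vox: int = 6,
    lateral_vox: int = 20,
    voxel_size: float = 25.0,
) -> LabeledVolume:
    """Planar bone–suture–bone sandwich for strain-recovery tests.

    Two bone slabs (labels 1, 2) separated along the anteroposterior axis
    by a suture slab (label 3) of width ``gap_vox`` voxels.
    """
    if gap_vox < 1:
        raise ValueError("gap_vox must be >= 1")
    nz = 2 * plate_vox + gap_vox
    labels = np.zeros((lateral_vox, lateral_vox, nz), dtype=np.int32)
    labels[:, :, :plate_vox] = 1
    labels[:, :, plate_vox : plate_vox + gap_vox] = 3
    labels[:, :, plate_vox + gap_vox :] = 2
    return LabeledVolume(
        labels, voxel_size, {1: "bone", 2: "bone", 3: "suture"}
    )
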