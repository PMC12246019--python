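"""Labeled voxel volumes.

A :class:`LabeledVolume` is the central container of the pipeline: a 3-D
integer label grid with a physical voxel size (µm) and a role for every
nonzero label.  The axis convention is fixed once and used everywhere:

* axis 0 — mediolateral (x)
* axis 1 — dorsoventral (y, dorsal = increasing index)
* axis 2 — anteroposterior (z, anterior = increasing index)

Voxel indices are 0-based and physical coordinates are ``index × voxel_size``
with the origin at the corner of voxel ``(0, 0, 0)``.  Voxel *centers* are at
``(index + 0.5) × voxel_size``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: valid roles a nonzero label may carry
ROLES = ("bone", "suture", "endocast", "cover", "constraint", "background")

#: roles that form the rigid/structural skeleton (participate in contacts)
STRUCTURAL_ROLES = ("bone", "constraint")


@dataclass
class LabeledVolume:
    """3-D integer label grid with physical voxel size and label roles.

    Parameters
    ----------
    labels
        Integer array, background is 0.
    voxel_size
        Isotropic voxel edge length in µm.
    label_roles
        Maps every nonzero label that occurs to one of :data:`ROLES`.
    """

    labels: np.ndarray
    voxel_size: float
    label_roles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive (µm)")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_roles)
        if missing:
            raise ValueError(f"labels without a role: {sorted(missing)}")
        bad = {l: r for l, r in self.label_roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown roles: {bad}")

    # -- convenience -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def physical_extent(self) -> np.ndarray:
        """Physical size of the grid per axis, in µm."""
        return np.asarray(self.shape, dtype=float) * self.voxel_size

    def labels_with_role(self, *roles: str) -> list[int]:
        return sorted(l for l, r in self.label_roles.items() if r in roles)

    @property
    def bone_labels(self) -> list[int]:
        return self.labels_with_role("bone")

    @property
    def structural_labels(self) -> list[int]:
        """Bone plus constraint-patch labels (the rigid skeleton)."""
        return self.labels_with_role(*STRUCTURAL_ROLES)

    def mask(self, label_or_role) -> np.ndarray:
        """Boolean mask for a label (int) or every label of a role (str)."""
        if isinstance(label_or_role, str):
            sel = self.labels_with_role(label_or_role)
            return np.isin(self.labels, sel)
        return self.labels == label_or_role

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(
            self.labels.copy(), self.voxel_size, dict(self.label_roles)
        )

    def next_free_label(self) -> int:
        used = set(self.label_roles) | {0}
        return max(used) + 1

    # -- I/O -------------------------------------------------------------
    def to_nifti(self, path) -> None:
        """Write as NIfTI with the voxel size (mm) in the affine; roles go
        to a JSON sidecar next to the image."""
        import nibabel as nib

        vmm = self.voxel_size * 1e-3
        affine = np.diag([vmm, vmm, vmm, 1.0])
        img = nib.Nifti1Image(self.labels.astype(np.int16), affine)
        img.header.set_zooms((vmm, vmm, vmm))
        nib.save(img, str(path))
        sidecar = Path(str(path)).with_suffix("").with_suffix("")
        roles_path = Path(str(sidecar) + ".roles.json")
        roles_path.write_text(
            json.dumps({str(k): v for k, v in self.label_roles.items()})
        )

    @classmethod
    def from_nifti(cls, path, label_roles: dict[int, str] | None = None):
        import nibabel as nib

        img = nib.load(str(path))
        voxel_um = float(img.header.get_zooms()[0]) * 1e3
        labels = np.asarray(img.dataobj).astype(np.int32)
        if label_roles is None:
            sidecar = Path(str(path)).with_suffix("").with_suffix("")
            roles_path = Path(str(sidecar) + ".roles.json")
            if roles_path.exists():
                label_roles = {
                    int(k): v for k, v in json.loads(roles_path.read_text()).items()
                }
            else:  # default every present label to bone
                label_roles = {
                    int(l): "bone" for l in np.unique(labels) if l != 0
                }
        return cls(labels, voxel_um, label_roles)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.labels.astype(np.int16), photometric="minisblack")
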