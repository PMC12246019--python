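"""Proper rigid (rotation + translation) transforms.

Rotations are 3×3 orthonormal matrices with determinant +1; translations are
in the length unit of the points they act on (the pipeline uses mm for mesh
coordinates and µm for voxel-space ground truth — callers convert).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def rotation_about_axis(axis, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, Rodrigues form."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("zero rotation axis")
    a = a / n
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


@dataclass
class Rigid:
    """x ↦ R @ x + t."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if self.R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "Rigid":
        return cls()

    @classmethod
    def translation(cls, t) -> "Rigid":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def about_point(cls, R, center) -> "Rigid":
        """Rotation ``R`` applied about ``center`` instead of the origin."""
        c = np.asarray(center, dtype=float)
        return cls(R, c - np.asarray(R) @ c)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.R.T + self.t

    def compose(self, other: "Rigid") -> "Rigid":
        """self ∘ other (apply ``other`` first)."""
        return Rigid(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "Rigid":
        return Rigid(self.R.T, -self.R.T @ self.t)

    def conjugate(self, frame: "Rigid") -> "Rigid":
        """Express this transform, given in ``frame`` coordinates, in the
        base coordinates: frame⁻¹ ∘ self ∘ frame."""
        return frame.inverse().compose(self).compose(frame)

    def scale_translation(self, factor: float) -> "Rigid":
        """Unit change for the translation part (e.g. µm → mm)."""
        return Rigid(self.R.copy(), self.t * factor)
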