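"""Rigid-body transforms shared by the orientation, insertion and docking stages.

Convention: right-handed Cartesian frame in Å, membrane/interface normal along
+z, hydrophobic side at z < 0, membrane (or interface) plane at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def rotation_z(angle_deg: float) -> np.ndarray:
    """3×3 rotation matrix about the z axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_y(angle_deg: float) -> np.ndarray:
    """3×3 rotation matrix about the y axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_x(angle_deg: float) -> np.ndarray:
    """3×3 rotation matrix about the x axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def euler_zyz(alpha_deg: float, beta_deg: float, gamma_deg: float) -> np.ndarray:
    """Proper rotation R = Rz(gamma) · Ry(beta) · Rz(alpha)."""
    return rotation_z(gamma_deg) @ rotation_y(beta_deg) @ rotation_z(alpha_deg)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation followed by translation: x ↦ R·x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    def is_identity(self, atol: float = 1e-8) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()


def rotation_aligning(vec: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit-normalized ``vec`` onto ``target``.

    Rodrigues construction; for anti-parallel inputs an arbitrary orthogonal
    180° axis is used.
    """
    v = np.asarray(vec, dtype=float)
    t = np.asarray(target, dtype=float)
    v = v / np.linalg.norm(v)
    t = t / np.linalg.norm(t)
    c = float(np.dot(v, t))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis orthogonal to v
        axis = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(v, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array(
            [
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ]
        )
        return np.eye(3) + 2.0 * K @ K
    axis = np.cross(v, t)
    s = np.linalg.norm(axis)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + K + K @ K * ((1.0 - c) / (s * s))
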