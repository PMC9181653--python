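"""Minimal rigid-transform algebra used by the geometry builders.

A :class:`Frame` is a right-handed orthonormal basis plus an origin, i.e. a
rigid placement of a local coordinate system in the lab (fiber) frame.  The
rotation matrix holds the local basis vectors as columns, so
``frame.apply(p_local)`` maps local coordinates to lab coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Frame", "identity_frame", "rot_z", "rotation_about_axis"]


def rot_z(angle_rad: float) -> np.ndarray:
    """Rotation matrix about the local z axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about an arbitrary (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)


@dataclass(frozen=True)
class Frame:
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def compose(self, other: "Frame") -> "Frame":
        """``self ∘ other``: apply *other* in this frame's coordinates."""
        return Frame(self.rotation @ other.rotation, self.rotation @ other.origin + self.origin)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map local coordinates to lab coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.origin

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Map lab coordinates into this frame."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) @ self.rotation

    def inverse(self) -> "Frame":
        return Frame(self.rotation.T, -self.rotation.T @ self.origin)

    @property
    def x_axis(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.rotation[:, 2]

    def almost_equal(self, other: "Frame", tol_nm: float = 1e-6, tol_rad: float = 1e-6) -> bool:
        if np.linalg.norm(self.origin - other.origin) > tol_nm:
            return False
        # rotation distance: angle of R1^T R2
        r = self.rotation.T @ other.rotation
        cos_angle = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
        return bool(np.arccos(cos_angle) <= tol_rad)


def identity_frame() -> Frame:
    return Frame()
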