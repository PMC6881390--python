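"""Core geometric data model shared by all pipeline stages.

All coordinates are millimetres in a right-handed Cartesian frame. The
package-internal orientation convention is LPS; files using RAS (e.g.
Slicer markups) are converted on read/write by the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ValidationError",
    "FrameMismatchError",
    "RigidTransform",
    "LandmarkSet",
    "TriangleMesh",
]

_ORTHO_TOL = 1e-8


class ValidationError(ValueError):
    """Raised when a data structure violates its invariants."""


class FrameMismatchError(ValueError):
    """Raised when two objects expressed in different frames are combined."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``y = R @ x + t`` between two coordinate frames.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Proper orthonormal rotation matrix (``det == +1``).
    translation : (3,) ndarray
        Translation in millimetres.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValidationError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValidationError("transform contains non-finite values")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValidationError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls,
        axis: np.ndarray,
        angle_deg: float,
        translation: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` followed by a translation."""
        axis = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValidationError("axis must be non-zero")
        k = axis / norm
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector) of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass
class LandmarkSet:
    """Labeled 3D points (mm) in a named coordinate frame."""

    labels: list[str]
    points: np.ndarray
    frame: str = "image"

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must be (N, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValidationError("landmark set must contain at least one point")
        if len(self.labels) != pts.shape[0]:
            raise ValidationError("labels and points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValidationError(f"duplicate landmark labels: {dupes}")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("landmark coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.points[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None

    def match(self, other: "LandmarkSet") -> tuple[list[str], np.ndarray, np.ndarray]:
        """Label-matched ordered correspondence with another set.

        Returns the common labels (in this set's order) and the two
        coordinate arrays in that order.
        """
        common = [l for l in self.labels if l in set(other.labels)]
        idx_self = [self.labels.index(l) for l in common]
        idx_other = [other.labels.index(l) for l in common]
        return common, self.points[idx_self], other.points[idx_other]

    def transformed(self, transform: RigidTransform, frame: str | None = None) -> "LandmarkSet":
        return LandmarkSet(
            list(self.labels),
            transform.apply(self.points),
            frame if frame is not None else self.frame,
        )

    def subset(self, labels: list[str]) -> "LandmarkSet":
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not present: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return LandmarkSet(list(labels), self.points[idx], self.frame)


@dataclass
class TriangleMesh:
    """Triangle surface mesh: V×3 vertices (mm) and F×3 vertex indices.

    ``region`` optionally tags each vertex with an anatomical region name.
    ``frame`` names the coordinate frame; ``None`` disables frame checks.
    """

    vertices: np.ndarray
    faces: np.ndarray
    region: np.ndarray | None = None
    frame: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError(f"vertices must be (V, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValidationError(f"faces must be (F, 3), got {f.shape}")
        if v.shape[0] == 0 or f.shape[0] == 0:
            raise ValidationError("mesh has no vertices or no faces")
        if not np.all(np.isfinite(v)):
            raise ValidationError("mesh vertices must be finite")
        if f.min() < 0 or f.max() >= v.shape[0]:
            raise ValidationError("face index out of range")
        degen = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if np.any(degen):
            raise ValidationError(
                f"degenerate faces (repeated vertex index): {np.nonzero(degen)[0].tolist()}"
            )
        if self.region is not None and len(self.region) != v.shape[0]:
            raise ValidationError("region tags must be per-vertex")
        self.vertices = v
        self.faces = f

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def edges(self) -> np.ndarray:
        """All undirected edges, one row per face edge (3F, 2), sorted per row."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        return np.sort(e, axis=1)

    def boundary_edges(self) -> np.ndarray:
        """Undirected edges used by exactly one face, shape (B, 2)."""
        e = self.edges()
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def nonmanifold_edges(self) -> np.ndarray:
        e = self.edges()
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts > 2]

    def is_closed(self) -> bool:
        return len(self.boundary_edges()) == 0

    def transformed(self, transform: RigidTransform, frame: str | None = None) -> "TriangleMesh":
        return replace(
            self,
            vertices=transform.apply(self.vertices),
            frame=frame if frame is not None else self.frame,
        )

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.region is None else np.array(self.region),
            self.frame,
        )
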