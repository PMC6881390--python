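"""Navigation-accuracy evaluation against an intraoperative surface scan.

The scan acts as a gold standard: it is rigidly registered to the
navigation data through the pin fiducials, after which every recorded
navigation point is scored by its unsigned minimum Euclidean distance to
the scanned surface. Distances handle all point-triangle Voronoi regions
exactly (face interior, edges, vertices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    FrameMismatchError,
    LandmarkSet,
    RigidTransform,
    TriangleMesh,
    ValidationError,
)
from .registration import NavigationSession, RegistrationError, fit_rigid

__all__ = [
    "ErrorSummary",
    "point_to_mesh_distance",
    "register_scan",
    "navigation_error",
    "summarize_distances",
]


@dataclass(frozen=True)
class ErrorSummary:
    """Distribution statistics of unsigned point-to-surface distances (mm)."""

    region: str
    n_points: int
    mean: float
    sd: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        if not (0 <= self.q1 <= self.median <= self.q3 <= self.max + 1e-12):
            raise ValidationError("quartiles out of order")
        if self.mean < 0:
            raise ValidationError("mean distance must be >= 0")

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "n_points": self.n_points,
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "q1_mm": self.q1,
            "median_mm": self.median,
            "q3_mm": self.q3,
            "max_mm": self.max,
        }


def summarize_distances(distances: np.ndarray, region: str = "pooled") -> ErrorSummary:
    """Summary statistics of a distance sample.

    Quartiles use linear interpolation between order statistics
    (numpy's default, the common "type 7" convention).
    """
    d = np.asarray(distances, float)
    if d.size == 0:
        raise ValidationError("no distances to summarize")
    if np.any(d < 0):
        raise ValidationError("distances must be unsigned")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return ErrorSummary(
        region=region,
        n_points=int(d.size),
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(d.max()),
    )


def _point_segment_sqdist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared distance from points ``p`` (..., 3) to segments a-b (..., 3)."""
    ab = b - a
    denom = np.einsum("...i,...i", ab, ab)
    t = np.einsum("...i,...i", p - a, ab) / np.where(denom > 0, denom, 1.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[..., None] * ab
    diff = p - closest
    return np.einsum("...i,...i", diff, diff)


def _points_to_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from (n, 3) points to (m, 3, 3) triangles -> (n, m).

    Projects each point onto each triangle's plane; if the projection's
    barycentric coordinates are all non-negative the plane distance is the
    answer, otherwise the minimum over the three edge segments is.
    """
    p = points[:, None, :]  # (n, 1, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]  # (m, 3)
    e0 = b - a
    e1 = c - a
    nrm = np.cross(e0, e1)  # (m, 3)
    w = p - a  # (n, m, 3)

    d00 = np.einsum("mi,mi->m", e0, e0)
    d01 = np.einsum("mi,mi->m", e0, e1)
    d11 = np.einsum("mi,mi->m", e1, e1)
    d20 = np.einsum("nmi,mi->nm", w, e0)
    d21 = np.einsum("nmi,mi->nm", w, e1)
    denom = d00 * d11 - d01 * d01  # (m,)
    safe = np.where(denom > 0, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / safe
    u = (d00 * d21 - d01 * d20) / safe
    inside = (v >= 0) & (u >= 0) & (v + u <= 1) & (denom > 0)

    nn = np.einsum("mi,mi->m", nrm, nrm)
    plane_sq = np.einsum("nmi,mi->nm", w, nrm) ** 2 / np.where(nn > 0, nn, 1.0)

    edge_sq = np.minimum(
        _point_segment_sqdist(p, a, b),
        np.minimum(_point_segment_sqdist(p, b, c), _point_segment_sqdist(p, c, a)),
    )
    return np.sqrt(np.where(inside, plane_sq, edge_sq))


def point_to_mesh_distance(
    points: LandmarkSet | np.ndarray,
    mesh: TriangleMesh,
    method: str = "auto",
) -> np.ndarray:
    """Unsigned minimum Euclidean distance from each point to the mesh surface.

    ``method`` is ``"auto"`` (KD-tree-pruned exact query), ``"accelerated"``
    (same, forced), or ``"bruteforce"`` (all triangles, no pruning). Both
    paths use the same exact point-triangle primitive and agree to
    floating-point precision; pruning only skips triangles that provably
    cannot contain the minimum.
    """
    if isinstance(points, LandmarkSet):
        if mesh.frame is not None and points.frame != mesh.frame:
            raise FrameMismatchError(
                f"points in frame {points.frame!r} but mesh in {mesh.frame!r}"
            )
        pts = points.points
    else:
        pts = np.asarray(points, float)
        if pts.ndim == 1:
            pts = pts[None, :]
    if pts.shape[0] == 0:
        raise ValidationError("no query points")
    tri = mesh.triangles()

    if method == "bruteforce" or (method == "auto" and tri.shape[0] * pts.shape[0] <= 200_000):
        out = np.empty(pts.shape[0])
        chunk = max(1, 2_000_000 // max(tri.shape[0], 1))
        for lo in range(0, pts.shape[0], chunk):
            out[lo : lo + chunk] = _points_to_triangles(pts[lo : lo + chunk], tri).min(axis=1)
        return out
    if method not in ("auto", "accelerated"):
        raise ValidationError(f"unknown method {method!r}")

    # prune with a KD-tree: nearest-vertex distance is an upper bound u on
    # the true distance; any triangle whose centroid is farther than
    # u + (its circumscribing vertex radius) cannot beat it.
    centroids = tri.mean(axis=1)
    radii = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    r_max = radii.max()
    vtree = cKDTree(mesh.vertices)
    ctree = cKDTree(centroids)
    upper, _ = vtree.query(pts)
    out = np.empty(pts.shape[0])
    for i, (p, u) in enumerate(zip(pts, upper)):
        cand = ctree.query_ball_point(p, u + r_max + 1e-9)
        out[i] = _points_to_triangles(p[None, :], tri[cand]).min()
    return out


def register_scan(scan_pins: LandmarkSet, nav_pins: LandmarkSet) -> RigidTransform:
    """Point-based rigid transform aligning the scan frame with the
    navigation (reference) frame via the pin fiducials."""
    return fit_rigid(scan_pins, nav_pins).transform


def navigation_error(
    session: NavigationSession,
    scan: TriangleMesh,
    scan_pins: LandmarkSet,
    return_distances: bool = False,
):
    """Per-region and pooled navigation error of a session against a scan.

    Recorded tracker-frame points are mapped back to the image frame using
    the registration that was in force when each batch was recorded. The
    scan is aligned to the image frame by point-based registration of its
    pins against the session's pin reference, and every point is scored by
    its unsigned distance to the scanned surface.
    """
    if not session.recorded:
        raise RegistrationError(f"session {session.case_id!r} has no recorded points")
    if session.pin_reference is None:
        raise RegistrationError(f"session {session.case_id!r} has no pin reference")
    scan_to_image = register_scan(scan_pins, session.pin_reference)
    scan_image = scan.transformed(scan_to_image, frame=session.pin_reference.frame)

    region_dists: dict[str, list[np.ndarray]] = {}
    rows: list[tuple[str, str, np.ndarray, float]] = []
    for rec in session.recorded:
        to_image = session.transform_in_force(rec.registration_index).inverse()
        pts_image = to_image.apply(rec.points.points)
        d = point_to_mesh_distance(pts_image, scan_image)
        region_dists.setdefault(rec.region, []).append(d)
        for label, p, di in zip(rec.points.labels, pts_image, d):
            rows.append((label, rec.region, p, float(di)))

    summaries = {
        region: summarize_distances(np.concatenate(chunks), region)
        for region, chunks in sorted(region_dists.items())
    }
    all_d = np.concatenate([d for chunks in region_dists.values() for d in chunks])
    summaries["pooled"] = summarize_distances(all_d, "pooled")
    if return_distances:
        return summaries, rows
    return summaries
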