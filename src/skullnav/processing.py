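"""Mesh post-processing: uniform Laplacian smoothing and hole filling.

Smoothing uses the umbrella operator with an explicit relaxation step:
each iteration moves every interior vertex toward the unweighted average
of its edge neighbors by the relaxation fraction, with all updates based
on the previous iteration's positions. Boundary vertices are held fixed.
Hole filling triangulates every boundary loop with a fan from the loop
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TriangleMesh, ValidationError

__all__ = ["SmoothingParams", "laplacian_smooth", "fill_holes"]


@dataclass(frozen=True)
class SmoothingParams:
    iterations: int = 10
    relaxation: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValidationError("iterations must be >= 0")
        if not (0 < self.relaxation <= 1):
            raise ValidationError("relaxation must be in (0, 1]")


def _vertex_adjacency(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CSR-ish neighbor arrays: (indptr, indices) plus boundary-vertex mask."""
    e = mesh.edges()
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    boundary_mask = np.zeros(mesh.n_vertices, dtype=bool)
    be = uniq[counts == 1]
    if len(be):
        boundary_mask[be.ravel()] = True
    both = np.concatenate([uniq, uniq[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    indptr = np.searchsorted(both[:, 0], np.arange(mesh.n_vertices + 1))
    return indptr, both[:, 1], boundary_mask


def laplacian_smooth(
    mesh: TriangleMesh, params: SmoothingParams = SmoothingParams()
) -> TriangleMesh:
    """Smooth a mesh in place of stair-step artifacts; topology unchanged."""
    if params.iterations == 0:
        return mesh.copy()
    indptr, indices, boundary = _vertex_adjacency(mesh)
    degree = np.diff(indptr).astype(float)
    movable = (~boundary) & (degree > 0)
    v = mesh.vertices.copy()
    for _ in range(params.iterations):
        neighbor_sum = np.zeros_like(v)
        np.add.at(neighbor_sum, np.repeat(np.arange(mesh.n_vertices), np.diff(indptr)), v[indices])
        avg = neighbor_sum[movable] / degree[movable, None]
        new_v = v.copy()
        new_v[movable] = v[movable] + params.relaxation * (avg - v[movable])
        v = new_v
    out = mesh.copy()
    out.vertices = v
    return out


def _group_loops(boundary_edges: np.ndarray) -> list[np.ndarray]:
    """Group undirected boundary edges into connected loops of vertex ids."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in boundary_edges:
        parent[find(int(i))] = find(int(j))
    groups: dict[int, set[int]] = {}
    for i, j in boundary_edges:
        groups.setdefault(find(int(i)), set()).update((int(i), int(j)))
    return [np.array(sorted(g)) for g in groups.values()]


def fill_holes(mesh: TriangleMesh) -> TriangleMesh:
    """Close every boundary loop with a centroid fan (one new vertex per loop).

    New triangles take the winding opposite to the existing face along each
    boundary edge, so orientation stays consistent.
    """
    nm = mesh.nonmanifold_edges()
    if len(nm):
        raise ValidationError(
            f"non-manifold edges (used by >2 faces): {nm.tolist()}"
        )
    b_undirected = mesh.boundary_edges()
    if len(b_undirected) == 0:
        return mesh.copy()

    # recover boundary edges in their in-face direction
    f = mesh.faces
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    key_und = {tuple(e) for e in b_undirected}
    b_directed = np.array(
        [e for e in directed if (min(e), max(e)) in key_und], dtype=np.int64
    )

    loops = _group_loops(b_undirected)
    loop_of_vertex = {}
    for li, verts in enumerate(loops):
        for vid in verts:
            loop_of_vertex[int(vid)] = li

    new_vertices = [mesh.vertices]
    centroid_index = {}
    next_id = mesh.n_vertices
    for li, verts in enumerate(loops):
        new_vertices.append(mesh.vertices[verts].mean(axis=0, keepdims=True))
        centroid_index[li] = next_id
        next_id += 1

    new_faces = [mesh.faces]
    fan = np.empty((len(b_directed), 3), dtype=np.int64)
    for k, (i, j) in enumerate(b_directed):
        c = centroid_index[loop_of_vertex[int(i)]]
        fan[k] = (j, i, c)  # opposite winding to the face owning edge (i, j)
    new_faces.append(fan)

    out = TriangleMesh(
        np.concatenate(new_vertices),
        np.concatenate(new_faces),
        frame=mesh.frame,
    )
    return out
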