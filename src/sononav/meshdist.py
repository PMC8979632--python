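"""Exact point-to-mesh distances.

Closest-point queries against triangle meshes, computed with the exact
point-triangle projection (Ericson's region decomposition) rather than a
vertex-only approximation.  A KD-tree over face centroids prunes the
candidate set: a face can only beat the best candidate found among the
``k`` nearest centroids if its centroid lies within that bound plus the
face's own circumradius, so the pruning is conservative and the result is
exact.  Ties between faces are broken by the lowest face index.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = ["closest_point_on_mesh", "point_triangle_distance", "contains_points"]


def point_triangle_distance(
    points: np.ndarray, tri_a: np.ndarray, tri_b: np.ndarray, tri_c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closest points on triangles (a, b, c) for paired query points.

    All arguments are (n, 3); returns (distances, closest points), computed
    with the standard closest-point-on-triangle case analysis.
    """
    p = np.asarray(points, dtype=float)
    a, b, c = (np.asarray(t, dtype=float) for t in (tri_a, tri_b, tri_c))
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(p.shape[0], dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    closest[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    closest[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    closest[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # face interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    return np.linalg.norm(p - closest, axis=1), closest


class _MeshDistance:
    def __init__(self, mesh: trimesh.Trimesh, k: int = 24):
        self.tri = mesh.triangles.view(np.ndarray)
        self.centroids = self.tri.mean(axis=1)
        self.radius = np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(k, self.tri.shape[0])

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = pts.shape[0]
        max_r = float(self.radius.max())

        # stage 1: upper bound from the k nearest face centroids
        _, ci = self.tree.query(pts, k=self.k)
        ci = np.atleast_2d(ci)
        kk = ci.shape[1]
        flat = ci.ravel()
        rep = np.repeat(pts, kk, axis=0)
        d1, _ = point_triangle_distance(rep, self.tri[flat, 0], self.tri[flat, 1], self.tri[flat, 2])
        d_up = d1.reshape(n, kk).min(axis=1)

        # stage 2: every face that could possibly beat the bound has its
        # centroid within d_up + circumradius of the query
        lists = self.tree.query_ball_point(pts, d_up + max_r + 1e-9)
        counts = np.fromiter((len(l) for l in lists), dtype=int, count=n)
        seg = np.repeat(np.arange(n), counts)
        cand = np.fromiter((f for l in lists for f in l), dtype=int, count=int(counts.sum()))
        d2, cp2 = point_triangle_distance(
            pts[seg], self.tri[cand, 0], self.tri[cand, 1], self.tri[cand, 2]
        )

        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        dist = np.minimum.reduceat(d2, starts)
        # ties -> lowest face index: mask non-minimal candidates, reduce faces
        is_min = d2 <= dist[seg] + 0.0
        face_masked = np.where(is_min, cand, np.iinfo(np.int64).max)
        face_id = np.minimum.reduceat(face_masked, starts)
        # closest point of the chosen face
        chosen = is_min & (cand == face_id[seg])
        closest = np.empty((n, 3))
        closest[seg[chosen]] = cp2[chosen]
        return closest, dist, face_id


def closest_point_on_mesh(
    mesh: trimesh.Trimesh, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest points on a mesh surface for an (n, 3) query array.

    Returns (closest points, distances, face indices).  The KD-tree built
    for a mesh is cached on the mesh object across calls.
    """
    cache_key = "_sononav_meshdist"
    engine = getattr(mesh, cache_key, None)
    if engine is None or engine.tri.shape[0] != mesh.faces.shape[0]:
        engine = _MeshDistance(mesh)
        try:
            setattr(mesh, cache_key, engine)
        except AttributeError:
            pass
    return engine.query(points)


def contains_points(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Inside test for a closed, outward-oriented mesh.

    A point is inside iff the vector from its closest surface point back to
    it opposes the angle-weighted pseudo-normal there (the normal convention
    that is exact for closest-point sidedness tests on watertight meshes).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    closest, _, face_id = closest_point_on_mesh(mesh, pts)
    tri = mesh.triangles.view(np.ndarray)[face_id]
    bary = trimesh.triangles.points_to_barycentric(tri, closest)
    # blend vertex normals by barycentric weight: smooth across edges/vertices
    vn = mesh.vertex_normals.view(np.ndarray)[mesh.faces[face_id]]
    normal = np.einsum("ij,ijk->ik", bary, vn)
    return np.einsum("ij,ij->i", pts - closest, normal) < 0
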