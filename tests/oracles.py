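"""Independent brute-force oracles used by the test suite.

Everything here is written against the textbook definitions with plain
loops, deliberately sharing no code with the package implementation, so
that agreement between the two is evidence rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Local outlier factor, straight from the definition (O(n^2) loops)


def brute_force_lof(p, pts, k: int) -> float:
    p = np.asarray(p, float)
    pts = np.asarray(pts, float)
    n = len(pts)

    def dist(a, b):
        return float(np.sqrt(((a - b) ** 2).sum()))

    def k_distance(center, others):
        ds = sorted(dist(center, o) for o in others)
        return ds[k - 1]

    def neighbourhood(center, others_idx, coords):
        kd = k_distance(center, [coords[j] for j in others_idx])
        return [j for j in others_idx if dist(center, coords[j]) <= kd], kd

    kdist = {}
    hoods = {}
    for i in range(n):
        others = [j for j in range(n) if j != i]
        hoods[i], kdist[i] = neighbourhood(pts[i], others, pts)

    def lrd(center, hood):
        reach = [max(dist(center, pts[j]), kdist[j]) for j in hood]
        m = sum(reach) / len(reach)
        return float("inf") if m == 0 else 1.0 / m

    hood_p, _ = neighbourhood(p, list(range(n)), pts)
    lrd_p = lrd(p, hood_p)
    ratios = []
    for j in hood_p:
        lrd_j = lrd(pts[j], hoods[j])
        if lrd_j == float("inf") and lrd_p == float("inf"):
            ratios.append(1.0)
        else:
            ratios.append(lrd_j / lrd_p)
    return sum(ratios) / len(ratios)


# ---------------------------------------------------------------------------
# Graph-cut energy: independent recomputation + exhaustive minimisation


def labeling_energy(problem, mask: np.ndarray) -> int:
    """Energy of a labelling recomputed from the problem's raw arrays."""
    lab = np.asarray(mask).reshape(-1).astype(bool)
    e = 0
    for i in range(lab.size):
        e += int(problem.data_fg[i]) if lab[i] else int(problem.data_bg[i])
    for i, j, w in zip(problem.pair_i, problem.pair_j, problem.pair_w):
        if lab[i] != lab[j]:
            e += int(w)
    return e


def exhaustive_min_energy(problem) -> tuple[int, np.ndarray]:
    """Enumerate every labelling consistent with the hard constraints."""
    n = problem.data_fg.size
    free = np.flatnonzero(~(problem.hard_fg | problem.hard_bg))
    if free.size > 16:
        raise ValueError("exhaustive oracle limited to 16 free pixels")
    base = problem.hard_fg.copy()
    best_e, best_lab = None, None
    for bits in itertools.product([False, True], repeat=free.size):
        lab = base.copy()
        lab[free] = bits
        e = labeling_energy(problem, lab)
        if best_e is None or e < best_e:
            best_e, best_lab = e, lab.copy()
    return best_e, best_lab.reshape(problem.shape)


# ---------------------------------------------------------------------------
# Point-to-mesh distance: plane projection with barycentric test, else
# minimum over the three edge segments — an independent formulation


def _point_segment_distance(p, a, b) -> float:
    ab = b - a
    t = float(np.dot(p - a, ab) / np.dot(ab, ab))
    t = min(1.0, max(0.0, t))
    return float(np.linalg.norm(p - (a + t * ab)))


def point_triangle_distance_oracle(p, tri) -> float:
    a, b, c = (np.asarray(v, float) for v in tri)
    p = np.asarray(p, float)
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    if nn > 0:
        q = p - np.dot(p - a, n) / nn * n
        # barycentric coordinates of the projection
        v0, v1, v2 = b - a, c - a, q - a
        d00, d01, d11 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v1, v1)
        d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
        den = d00 * d11 - d01 * d01
        if den != 0:
            v = (d11 * d20 - d01 * d21) / den
            w = (d00 * d21 - d01 * d20) / den
            if v >= 0 and w >= 0 and v + w <= 1:
                return float(np.linalg.norm(p - q))
    return min(
        _point_segment_distance(p, a, b),
        _point_segment_distance(p, b, c),
        _point_segment_distance(p, c, a),
    )


def min_distance_to_mesh_oracle(points, mesh) -> np.ndarray:
    tris = mesh.triangles.view(np.ndarray)
    out = np.empty(len(points))
    for i, p in enumerate(np.atleast_2d(points)):
        out[i] = min(point_triangle_distance_oracle(p, t) for t in tris)
    return out


# ---------------------------------------------------------------------------
# Cone geometry closed form


def cone_sphere_clearance(apex, axis, half_angle, center, radius) -> float:
    """Closed-form distance from a sphere to an infinite cone's lateral surface.

    Valid for sphere centres on the cone's axis side (inside the cone),
    which is the planner's regime: distance from centre to the lateral
    surface is h*sin(theta) for a centre at height h above the apex.
    """
    h = float(np.dot(np.asarray(center) - np.asarray(apex), np.asarray(axis)))
    return h * np.sin(half_angle) - radius
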