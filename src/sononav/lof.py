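"""Local outlier factor for streaming surface-point filtering.

During surface scanning, tracking glitches and probe slips produce isolated
3D points far from the sweep.  The local outlier factor (LOF) scores a new
candidate point against the recent buffer: a point as locally dense as its
neighbours scores ~1, an isolated point scores well above 1.

This is the definitional LOF of Breunig et al.: k-distance neighbourhoods
(including ties at the k-distance), reachability distances, local
reachability density (lrd), and the ratio of the neighbours' mean lrd to
the query's lrd.  The buffers involved hold at most a few dozen points, so
distances are computed exactly with no spatial index.
"""

from __future__ import annotations

import numpy as np

__all__ = ["local_outlier_factor"]


def _k_neighbourhood(dists: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Indices within the k-distance (ties included) and the k-distance itself."""
    order = np.argsort(dists, kind="stable")
    kdist = dists[order[k - 1]]
    members = np.flatnonzero(dists <= kdist)
    return members, float(kdist)


def local_outlier_factor(p: np.ndarray, neighbors: np.ndarray, k: int) -> float:
    """LOF of point ``p`` with respect to a reference point set.

    ``p`` itself must not be a member of ``neighbors`` (the streaming caller
    scores the incoming point against the existing buffer).  Requires at
    least ``k + 1`` reference points so every neighbour has its own full
    k-neighbourhood.
    """
    p = np.asarray(p, dtype=float)
    pts = np.asarray(neighbors, dtype=float)
    if pts.ndim != 2:
        raise ValueError("neighbors must be an (n, d) array")
    n = pts.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} neighbors, got {n}")

    # pairwise distances inside the reference set, and query-to-set distances
    diff = pts[:, None, :] - pts[None, :, :]
    dmat = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    dq = np.linalg.norm(pts - p, axis=1)

    kdist = np.empty(n)
    hoods: list[np.ndarray] = []
    for i in range(n):
        d_others = np.delete(dmat[i], i)
        idx_others = np.delete(np.arange(n), i)
        members, kd = _k_neighbourhood(d_others, k)
        hoods.append(idx_others[members])
        kdist[i] = kd

    def lrd_of(dist_to_members: np.ndarray, members: np.ndarray) -> float:
        reach = np.maximum(dist_to_members, kdist[members])
        mean_reach = reach.mean()
        if mean_reach == 0.0:
            return np.inf  # duplicated points: infinite density
        return 1.0 / mean_reach

    hood_q, _ = _k_neighbourhood(dq, k)
    lrd_q = lrd_of(dq[hood_q], hood_q)

    lrd_ref = np.empty(n)
    for i in range(n):
        lrd_ref[i] = lrd_of(dmat[i][hoods[i]], hoods[i])

    with np.errstate(invalid="ignore"):
        ratios = lrd_ref[hood_q] / lrd_q
    # inf/inf (duplicate query in a duplicated cluster) -> density ratio 1
    ratios = np.where(np.isnan(ratios), 1.0, ratios)
    return float(np.mean(ratios))
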