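"""Periodic (torus) geometry primitives shared by the simulator and the
spatial statistics.

All coordinates live in the half-open square [0, L) x [0, L); distances use
the per-axis minimal-image convention, so the maximal possible separation is
L*sqrt(2)/2.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "wrap_positions",
    "wrapped_delta",
    "wrapped_distance",
    "pairwise_wrapped_distances",
    "min_pairwise_distance",
    "hard_core_pattern",
    "nearest_neighbor_distances",
]


def wrap_positions(pos: np.ndarray, side: float) -> np.ndarray:
    """Map coordinates onto the torus fundamental domain [0, side)."""
    return np.mod(pos, side)


def wrapped_delta(p_from: np.ndarray, p_to: np.ndarray, side: float) -> np.ndarray:
    """Minimal-image displacement vector(s) from ``p_from`` to ``p_to``."""
    d = np.asarray(p_to, dtype=float) - np.asarray(p_from, dtype=float)
    return d - side * np.round(d / side)


def wrapped_distance(p1, p2, side: float):
    """Euclidean distance on the torus (per-axis minimal image).

    Accepts single points or arrays broadcastable to (..., 2); non-finite
    coordinates raise ``ValueError``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise ValueError("coordinates must be finite")
    d = wrapped_delta(p1, p2, side)
    return np.sqrt(np.sum(d * d, axis=-1))


def pairwise_wrapped_distances(points: np.ndarray, side: float) -> np.ndarray:
    """Dense m x m matrix of minimal-image distances (diagonal 0)."""
    pts = np.asarray(points, dtype=float)
    d = pts[:, None, :] - pts[None, :, :]
    d -= side * np.round(d / side)
    return np.sqrt(np.sum(d * d, axis=-1))


def min_pairwise_distance(points: np.ndarray, side: float) -> float:
    """Smallest inter-point distance; inf for fewer than two points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return float("inf")
    nn = nearest_neighbor_distances(pts, side)
    return float(nn.min())


def hard_core_pattern(
    m: int,
    side: float,
    d_min: float,
    rng: np.random.Generator,
    max_attempts_per_point: int = 1000,
) -> np.ndarray:
    """Seed ``m`` points uniformly on the torus by rejection sampling with a
    hard-core exclusion radius ``d_min``.

    Candidates conflicting with the minimal distance are discarded and the
    procedure continues until the required density is obtained.  Raises
    ``ValueError`` when the attempt budget is exhausted (infeasible density).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if side <= 2.0 * d_min:
        raise ValueError("domain side must exceed twice the hard-core distance")
    pts = np.empty((m, 2), dtype=float)
    n_placed = 0
    attempts = 0
    budget = max_attempts_per_point * m
    while n_placed < m:
        cand = rng.uniform(0.0, side, size=2)
        if n_placed == 0:
            pts[0] = cand
            n_placed = 1
            continue
        delta = pts[:n_placed] - cand
        delta -= side * np.round(delta / side)
        if np.all(np.einsum("ij,ij->i", delta, delta) >= d_min * d_min):
            pts[n_placed] = cand
            n_placed += 1
        attempts += 1
        if attempts > budget:
            raise ValueError(
                f"hard-core seeding infeasible: placed {n_placed}/{m} points "
                f"(side={side}, d_min={d_min})"
            )
    return pts


def nearest_neighbor_distances(points: np.ndarray, side: float) -> np.ndarray:
    """Per-point distance to the nearest other point, periodic boundaries."""
    pts = np.mod(np.asarray(points, dtype=float), side)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    tree = cKDTree(pts, boxsize=side)
    dists, _ = tree.query(pts, k=2)
    return dists[:, 1]
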