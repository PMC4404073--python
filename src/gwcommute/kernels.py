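"""Planar distances and geographic weighting kernels.

Every local regression in a geographically weighted model is driven by a
distance-decay weight given to each observation around a regression point.
Two kernel families are supported:

* ``bisquare`` — compact support, ``w = (1 - (d/b)^2)^2`` for ``d < b`` and 0
  beyond the bandwidth ``b``;
* ``gaussian`` — ``w = exp(-0.5 (d/b)^2)``, positive everywhere.

Bandwidths are either *fixed* (a metric distance, in meters) or *adaptive*
(the distance to a location's N-th nearest other point, so that each local
regression sees a constant number of neighbours regardless of point density).

All coordinates are planar meters in a single projection; longitude/latitude
input must be projected upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "KernelSpec",
    "pairwise_distances",
    "adaptive_bandwidths",
    "kernel_weights",
    "looks_like_degrees",
]


def _as_points(x, y=None):
    """Coerce input to an (n, 2) float array of planar coordinates."""
    if y is not None:
        pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    else:
        pts = np.asarray(x, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar meters")
    if pts.shape[0] < 1:
        raise ValueError("point set must be non-empty")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in point set")
    return pts


def looks_like_degrees(points) -> bool:
    """Heuristic: coordinates within |x| <= 180 and |y| <= 90 are probably
    unprojected geographic degrees, which the planar machinery refuses."""
    pts = _as_points(points)
    return bool(np.all(np.abs(pts[:, 0]) <= 180) and np.all(np.abs(pts[:, 1]) <= 90))


@dataclass(frozen=True)
class KernelSpec:
    """Geographic weighting scheme.

    Parameters
    ----------
    family : {"gaussian", "bisquare"}
    mode : {"fixed", "adaptive"}
    bandwidth_m : float, optional
        Metric bandwidth in meters (fixed mode only).
    neighbor_count : int, optional
        Number of neighbours N defining the adaptive bandwidth at each
        location (adaptive mode only).
    """

    family: Literal["gaussian", "bisquare"] = "bisquare"
    mode: Literal["fixed", "adaptive"] = "adaptive"
    bandwidth_m: float | None = None
    neighbor_count: int | None = None

    def __post_init__(self):
        if self.family not in ("gaussian", "bisquare"):
            raise ValueError(f"unknown kernel family: {self.family!r}")
        if self.mode == "fixed":
            if self.bandwidth_m is None or self.neighbor_count is not None:
                raise ValueError("fixed mode requires bandwidth_m and no neighbor_count")
            if self.bandwidth_m <= 0:
                raise ValueError("bandwidth_m must be > 0")
        elif self.mode == "adaptive":
            if self.neighbor_count is None or self.bandwidth_m is not None:
                raise ValueError("adaptive mode requires neighbor_count and no bandwidth_m")
            if self.neighbor_count < 2:
                raise ValueError("neighbor_count must be >= 2")
        else:
            raise ValueError(f"unknown kernel mode: {self.mode!r}")

    def with_neighbor_count(self, n: int) -> "KernelSpec":
        return KernelSpec(self.family, "adaptive", None, int(n))


def pairwise_distances(a, b) -> np.ndarray:
    """Euclidean distance table (meters) between two planar point sets.

    Returns an (n_a, n_b) array; symmetric with a zero diagonal when ``a``
    and ``b`` are the same set.
    """
    pa, pb = _as_points(a), _as_points(b)
    diff = pa[:, None, :] - pb[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def adaptive_bandwidths(points, neighbor_count: int) -> np.ndarray:
    """Distance from each location to its N-th nearest *other* point.

    The location itself is excluded from the count (rank 1 = nearest
    neighbour). Duplicate coordinates are allowed; ties are broken in stable
    index order, so the bandwidth can be 0 only if more than N points share a
    coordinate.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    N = int(neighbor_count)
    if not 1 <= N <= n - 1:
        raise ValueError(f"neighbor_count must be in [1, n-1]; got {N} for n={n}")
    tree = cKDTree(pts)
    # k = N + 1 nearest including (possibly) the point itself.
    dist, idx = tree.query(pts, k=N + 1)
    bw = np.empty(n)
    for i in range(n):
        d = dist[i]
        # Drop the self entry: prefer the slot whose index is i, else the
        # first zero-distance slot (duplicate coordinates).
        self_pos = np.nonzero(idx[i] == i)[0]
        if self_pos.size:
            d = np.delete(d, self_pos[0])
        else:
            d = d[1:]
        bw[i] = d[N - 1]
    return bw


def kernel_weights(distances, bandwidth: float, family: str = "bisquare") -> np.ndarray:
    """Evaluate a kernel weight for each distance; weights lie in [0, 1].

    Bi-square has compact support: ``d >= bandwidth`` gives exactly 0, and
    the self-distance 0 always gives weight 1.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    d = np.asarray(distances, float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    u = d / bandwidth
    if family == "bisquare":
        w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    elif family == "gaussian":
        w = np.exp(-0.5 * u**2)
    else:
        raise ValueError(f"unknown kernel family: {family!r}")
    return w
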