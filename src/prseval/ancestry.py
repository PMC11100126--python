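"""Ancestry cluster assignment in genotype-PC space.

Individuals are assigned to the closest reference population center by
Euclidean distance, where each center is the *geometric median* of labelled
reference individuals' PC coordinates — the point minimising the summed
Euclidean distances, a robust alternative to the centroid.  The median is
computed by the Weiszfeld fixed-point iteration with the Vardi-Zhang rule for
iterates that land exactly on a data point.

Individuals farther than an optional cutoff from every center are labelled
``unassigned`` (and would be discarded from a downstream analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ConvergenceError",
    "ReferenceCenters",
    "geometric_median",
    "assign_clusters",
]

UNASSIGNED = "unassigned"


class ConvergenceError(RuntimeError):
    """Weiszfeld iteration did not converge; ``.last_iterate`` holds the state."""

    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


def geometric_median(
    points: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """Point minimising the sum of Euclidean distances to ``points``.

    Weiszfeld iteration started at the centroid.  When the current iterate
    coincides with a data point, the Vardi-Zhang modification decides whether
    that point is optimal and otherwise steps past it.  Raises
    :class:`ConvergenceError` after ``max_iter`` steps.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("geometric median of an empty point set is undefined")
    if pts.shape[0] == 1:
        return pts[0].copy()

    y = pts.mean(axis=0)
    eps = 1e-12 * max(1.0, float(np.abs(pts).max()))
    for _ in range(max_iter):
        d = np.linalg.norm(pts - y, axis=1)
        at_point = d < eps
        if at_point.any():
            others = ~at_point
            if not others.any():  # all points identical
                return y
            dn = d[others]
            diffs = (pts[others] - y) / dn[:, None]
            R = diffs.sum(axis=0)
            r = float(np.linalg.norm(R))
            if r <= 1.0 + 1e-12:  # the data point itself is the minimiser
                return y
            inv = 1.0 / dn
            T = (pts[others] * inv[:, None]).sum(axis=0) / inv.sum()
            step = max(0.0, 1.0 - 1.0 / r)
            y_new = step * T + min(1.0, 1.0 / r) * y
        else:
            inv = 1.0 / d
            y_new = (pts * inv[:, None]).sum(axis=0) / inv.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    raise ConvergenceError(
        f"Weiszfeld iteration did not converge within {max_iter} iterations",
        last_iterate=y,
    )


@dataclass(frozen=True)
class ReferenceCenters:
    """Named reference population centers in k-dimensional PC space."""

    cluster_names: tuple[str, ...]
    centers: np.ndarray  # clusters x k

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        names = tuple(str(n) for n in self.cluster_names)
        if len(set(names)) != len(names):
            raise ValueError("cluster names must be distinct")
        if centers.shape[0] != len(names):
            raise ValueError("one center per cluster name is required")
        if centers.shape[1] < 1:
            raise ValueError("centers must have at least one dimension")
        object.__setattr__(self, "cluster_names", names)
        object.__setattr__(self, "centers", centers)

    @classmethod
    def from_labelled(
        cls, pcs: np.ndarray, labels: np.ndarray, tol: float = 1e-8,
        max_iter: int = 1000,
    ) -> "ReferenceCenters":
        """Geometric-median centers from labelled reference individuals."""
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        labels = np.asarray(labels)
        names = sorted(map(str, set(labels)))
        centers = np.vstack(
            [
                geometric_median(pcs[labels == name], tol=tol, max_iter=max_iter)
                for name in names
            ]
        )
        return cls(cluster_names=tuple(names), centers=centers)

    @property
    def k(self) -> int:
        return self.centers.shape[1]


def assign_clusters(
    pcs: np.ndarray,
    refs: ReferenceCenters,
    max_dist: float | None = None,
    sample_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Nearest-reference-center cluster assignment in PC space.

    Returns a frame with columns ``sample_id``, ``cluster``, ``distance``.
    Exact distance ties are broken by cluster-name order with a warning;
    individuals farther than ``max_dist`` from every center are labelled
    ``unassigned``.
    """
    coords = np.atleast_2d(np.asarray(pcs, dtype=float))
    if coords.shape[1] != refs.k:
        raise ValueError(
            f"PC dimension {coords.shape[1]} does not match reference "
            f"centers ({refs.k})"
        )
    dist = cdist(coords, refs.centers)
    best = dist.argmin(axis=1)
    best_dist = dist[np.arange(len(coords)), best]

    ties = (np.isclose(dist, best_dist[:, None])).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} individual(s) equidistant from multiple "
            "reference centers; ties broken by cluster-name order",
            stacklevel=2,
        )
    labels = np.array([refs.cluster_names[j] for j in best], dtype=object)
    if max_dist is not None:
        labels[best_dist > max_dist] = UNASSIGNED
    if sample_ids is None:
        sample_ids = np.arange(len(coords))
    return pd.DataFrame(
        {"sample_id": sample_ids, "cluster": labels, "distance": best_dist}
    )
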