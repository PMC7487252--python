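"""Flat-kernel mean-shift clustering for merging positive windows.

Overlapping sliding windows fire several times on the same stoma; their
centers form a tight cloud around it.  Mean shift — iteratively moving
each point to the mean of all points within a bandwidth — converges on
the density modes of that cloud, one per stoma.  The flat (uniform)
kernel of Comaniciu & Meer's basic formulation is used by default because
its fixed points are exactly checkable; a Gaussian kernel is available
behind a flag.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = ["FlatMeanShift", "mean_shift"]


def _shift_once(p: np.ndarray, points: np.ndarray, bandwidth: float,
                kernel: str) -> np.ndarray:
    d2 = ((points - p) ** 2).sum(axis=1)
    if kernel == "flat":
        inside = d2 <= bandwidth * bandwidth
        return points[inside].mean(axis=0)
    w = np.exp(-0.5 * d2 / bandwidth ** 2)
    return (points * w[:, None]).sum(axis=0) / w.sum()


def mean_shift(points, bandwidth: float, *, kernel: str = "flat",
               tol: float = 1e-3, max_iter: int = 300
               ) -> tuple[np.ndarray, np.ndarray]:
    """Cluster 2-D points by mean shift.

    Each point is iterated to the mean of the points within ``bandwidth``
    of its current position until it moves less than ``tol`` px (at most
    ``max_iter`` iterations).  Converged positions closer than
    ``bandwidth / 2`` are merged into one mode; every input point is
    assigned to its nearest mode.

    Returns
    -------
    modes : (k, 2) array of cluster centers.
    labels : (n,) array assigning each input point to a mode.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be strictly positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.empty((0, 2)), np.empty(0, dtype=int)

    converged = np.empty_like(pts)
    for i, p0 in enumerate(pts):
        p = p0.copy()
        for _ in range(max_iter):
            q = _shift_once(p, pts, bandwidth, kernel)
            if np.hypot(*(q - p)) < tol:
                p = q
                break
            p = q
        converged[i] = p

    # merge converged positions closer than bandwidth / 2
    modes: list[np.ndarray] = []
    labels = np.empty(len(pts), dtype=int)
    merge_r2 = (bandwidth / 2.0) ** 2
    for i, p in enumerate(converged):
        for j, m in enumerate(modes):
            if ((p - m) ** 2).sum() < merge_r2:
                labels[i] = j
                break
        else:
            modes.append(p.copy())
            labels[i] = len(modes) - 1
    mode_arr = np.array(modes)
    # nearest-mode assignment (modes may have merged under a different order)
    d2 = ((pts[:, None, :] - mode_arr[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return mode_arr, labels


class FlatMeanShift(BaseEstimator, ClusterMixin):
    """scikit-learn style wrapper around :func:`mean_shift`.

    Parameters
    ----------
    bandwidth : float, default 60
        Radius (px) of the flat kernel; half a patch, on the scale of a
        stoma radius.
    kernel : {"flat", "gaussian"}
    tol, max_iter : convergence controls of the fixed-point iteration.

    Attributes
    ----------
    cluster_centers_ : (k, 2) modes.
    labels_ : (n,) assignment of the fitted points.
    """

    def __init__(self, bandwidth: float = 60.0, kernel: str = "flat",
                 tol: float = 1e-3, max_iter: int = 300):
        self.bandwidth = bandwidth
        self.kernel = kernel
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "FlatMeanShift":
        self.cluster_centers_, self.labels_ = mean_shift(
            X, self.bandwidth, kernel=self.kernel,
            tol=self.tol, max_iter=self.max_iter)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float).reshape(-1, 2)
        if len(self.cluster_centers_) == 0:
            raise ValueError("no modes were found during fit")
        d2 = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
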