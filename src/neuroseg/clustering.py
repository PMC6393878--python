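"""Intensity clustering engines: k-means and fuzzy c-means.

Both engines operate on a flat vector of pixel intensities (the in-brain
pixels after skull stripping, coordinates retained by the caller). The FCM
engine minimizes the fuzzified within-cluster objective

    J_m = sum_i sum_j u_ij^m (x_i - c_j)^2

by alternating the weighted-mean center update and the row-stochastic
membership update; k-means is the crisp special case with nearest-center
assignment and plain cluster means. Initialization is deterministic:
centers at evenly spaced intensity percentiles (25/50/75 for c = 3), with
optional seeded random restarts for robustness studies.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional

import numpy as np

from .errors import ArgumentError, DegenerateClusteringError

__all__ = ["ClusterModel", "kmeans_assign", "kmeans_update", "kmeans_cluster",
           "fcm_memberships", "fcm_centers", "fcm_objective", "fcm_cluster",
           "assign_tissue_labels", "percentile_centers"]

log = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-9
_MONOTONE_SLACK = 1e-9


@dataclasses.dataclass
class ClusterModel:
    """Converged clustering state.

    ``memberships`` rows sum to 1; ``objective_history`` is non-increasing;
    ``centers`` lie within the pixel intensity range. ``fuzziness`` is 1.0
    for the crisp k-means engine and > 1 for FCM. ``coords`` optionally
    retains the (row, col) image coordinate of each pixel.
    """

    pixels: np.ndarray
    centers: np.ndarray
    memberships: np.ndarray
    fuzziness: float
    objective_history: List[float]
    coords: Optional[np.ndarray] = None

    @property
    def distances(self) -> np.ndarray:
        """N x c matrix of absolute intensity distances |x_i - c_j|."""
        return np.abs(self.pixels[:, None] - self.centers[None, :])

    @property
    def labels(self) -> np.ndarray:
        """Crisp label per pixel: argmax membership (lowest index on ties)."""
        return np.argmax(self.memberships, axis=1)

    def check_invariants(self) -> None:
        rows = self.memberships.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise AssertionError("membership rows do not sum to 1")
        hist = np.asarray(self.objective_history)
        if hist.size > 1 and np.any(np.diff(hist) > _MONOTONE_SLACK):
            raise AssertionError("objective history increased")
        lo, hi = self.pixels.min(), self.pixels.max()
        if np.any(self.centers < lo - 1e-12) or np.any(self.centers > hi + 1e-12):
            raise AssertionError("centers escaped the pixel intensity range")


def percentile_centers(pixels: np.ndarray, k: int,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Deterministic initial centers at evenly spaced intensity percentiles.

    Percentiles (j + 0.5)/k for j = 0..k-1 (25/50/75 for k = 3). Duplicate
    percentile values fall back to a linspace over the intensity range. If
    ``rng`` is given, centers are drawn uniformly from the range instead.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    lo, hi = float(pixels.min()), float(pixels.max())
    if rng is not None:
        return np.sort(rng.uniform(lo, hi, size=k))
    qs = (np.arange(k) + 0.5) / k * 100.0
    centers = np.percentile(pixels, qs)
    if np.unique(centers).size < k:
        centers = np.linspace(lo, hi, k)
    return np.asarray(centers, dtype=np.float64)


# --------------------------------------------------------------------------
# k-means (crisp) engine
# --------------------------------------------------------------------------

def kmeans_assign(pixels: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Label each pixel with its nearest center; ties go to the lower index."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ArgumentError("cannot assign an empty pixel set")
    d = np.abs(pixels[:, None] - np.asarray(centers)[None, :])
    return np.argmin(d, axis=1)  # argmin returns the first (lowest) index


def kmeans_update(pixels: np.ndarray, labels: np.ndarray, k: int,
                  previous: Optional[np.ndarray] = None) -> np.ndarray:
    """Center = mean of assigned pixels; an empty cluster keeps its center."""
    pixels = np.asarray(pixels, dtype=np.float64)
    centers = np.empty(k, dtype=np.float64)
    for j in range(k):
        members = pixels[labels == j]
        if members.size:
            centers[j] = members.mean()
        elif previous is not None:
            centers[j] = previous[j]
        else:
            raise ArgumentError(f"cluster {j} is empty and no previous center given")
    return centers


def kmeans_cluster(pixels: np.ndarray, k: int, tol: float = 1e-6,
                   max_iter: int = 100,
                   rng: Optional[np.random.Generator] = None) -> ClusterModel:
    """Alternate assignment and mean updates until the centers stop moving."""
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if pixels.size == 0:
        raise ArgumentError("cannot cluster an empty pixel set")
    if k < 2:
        raise ArgumentError("k must be >= 2")
    n_distinct = np.unique(pixels).size
    if k > n_distinct:
        log.warning("k=%d exceeds the %d distinct intensities; "
                    "clusters may stay empty", k, n_distinct)
    centers = percentile_centers(pixels, k, rng)
    if np.unique(centers).size < k:
        # duplicate initial centers: nudge into a linspace to keep them distinct
        centers = np.linspace(pixels.min(), pixels.max(), k)
    history: List[float] = []
    labels = kmeans_assign(pixels, centers)
    for _ in range(max_iter):
        new_centers = kmeans_update(pixels, labels, k, previous=centers)
        labels = kmeans_assign(pixels, new_centers)
        history.append(float(np.sum((pixels - new_centers[labels]) ** 2)))
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            break
    memberships = np.zeros((pixels.size, k))
    memberships[np.arange(pixels.size), labels] = 1.0
    model = ClusterModel(pixels, centers, memberships, 1.0, history)
    model.check_invariants()
    return model


# --------------------------------------------------------------------------
# fuzzy c-means engine
# --------------------------------------------------------------------------

def fcm_memberships(pixels: np.ndarray, centers: np.ndarray,
                    m: float) -> np.ndarray:
    """Row-stochastic membership update.

    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)); a pixel at zero distance from
    one or more centers gets its membership split equally among those.
    """
    if m <= 1:
        raise ArgumentError("fuzziness m must be > 1")
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    centers = np.asarray(centers, dtype=np.float64)
    d = np.abs(pixels[:, None] - centers[None, :])
    zero = d == 0.0
    any_zero = zero.any(axis=1)
    u = np.empty_like(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        power = d ** (-2.0 / (m - 1.0))
        u = power / power.sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return u


def fcm_centers(pixels: np.ndarray, memberships: np.ndarray, m: float,
                previous: Optional[np.ndarray] = None) -> np.ndarray:
    """Weighted-mean center update with weights u_ij^m."""
    if m <= 1:
        raise ArgumentError("fuzziness m must be > 1")
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    w = np.asarray(memberships, dtype=np.float64) ** m
    denom = w.sum(axis=0)
    num = w.T @ pixels
    centers = np.empty(denom.shape, dtype=np.float64)
    ok = denom > 0
    centers[ok] = num[ok] / denom[ok]
    if not ok.all():
        if previous is None:
            raise ArgumentError("all-zero membership column and no previous center")
        log.warning("FCM: %d cluster(s) received zero total membership; "
                    "keeping previous centers", int((~ok).sum()))
        centers[~ok] = previous[~ok]
    return centers


def fcm_objective(pixels: np.ndarray, centers: np.ndarray,
                  memberships: np.ndarray, m: float) -> float:
    """J_m = sum_i sum_j u_ij^m (x_i - c_j)^2."""
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    d2 = (pixels[:, None] - np.asarray(centers)[None, :]) ** 2
    return float(np.sum(np.asarray(memberships) ** m * d2))


def fcm_cluster(pixels: np.ndarray, c: int = 3, m: float = 2.0,
                tol: float = 1e-5, max_iter: int = 100,
                rng: Optional[np.random.Generator] = None,
                coords: Optional[np.ndarray] = None) -> ClusterModel:
    """Alternate center and membership updates from percentile-initialized
    centers until the largest membership change drops below ``tol``."""
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    if pixels.size == 0:
        raise ArgumentError("cannot cluster an empty pixel set")
    if c < 2:
        raise ArgumentError("c must be >= 2")
    if m <= 1:
        raise ArgumentError("fuzziness m must be > 1")
    centers = percentile_centers(pixels, c, rng)
    u = fcm_memberships(pixels, centers, m)
    history = [fcm_objective(pixels, centers, u, m)]
    for _ in range(max_iter):
        centers = fcm_centers(pixels, u, m, previous=centers)
        u_new = fcm_memberships(pixels, centers, m)
        history.append(fcm_objective(pixels, centers, u_new, m))
        delta = np.max(np.abs(u_new - u))
        u = u_new
        if delta < tol:
            break
    model = ClusterModel(pixels, centers, u, m, history, coords=coords)
    model.check_invariants()
    return model


TISSUE_ORDER_GM_WM = ("csf", "gm", "wm")


def assign_tissue_labels(model: ClusterModel, mode: str = "gm_wm") -> Dict[int, str]:
    """Map cluster indices to tissues by sorting centers (T1 ordering).

    ``gm_wm``: lowest → CSF, middle → GM, highest → WM. ``tumor``: highest →
    tumor candidate, the rest labeled ``tissue0..`` darkest first.
    """
    centers = np.asarray(model.centers, dtype=np.float64)
    if np.unique(np.round(centers, 9)).size < centers.size:
        raise DegenerateClusteringError("coincident cluster centers")
    order = np.argsort(centers, kind="stable")
    if mode == "gm_wm":
        if centers.size != 3:
            raise DegenerateClusteringError(
                f"gm_wm labeling needs exactly 3 clusters, got {centers.size}")
        return {int(order[i]): TISSUE_ORDER_GM_WM[i] for i in range(3)}
    if mode == "tumor":
        if centers.size < 2:
            raise DegenerateClusteringError("tumor labeling needs >= 2 clusters")
        out = {int(order[i]): f"tissue{i}" for i in range(centers.size - 1)}
        out[int(order[-1])] = "tumor"
        return out
    raise ArgumentError(f"unknown labeling mode {mode!r}")
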