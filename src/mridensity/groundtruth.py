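"""Ground-truth volumetric density: fuzzy c-means FGT segmentation + ratio.

The label pipeline mirrors how quantitative breast-density ground truth is
built from a precontrast scan: cluster the intensities inside the breast
region with fuzzy c-means (FCM), call the darker cluster fibroglandular
tissue (fat is bright on non-fat-suppressed T1), cut the breast region at
the sternum plane, and report 100 * |FGT| / |breast| as the density label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import Volume

__all__ = [
    "FCMConfig",
    "FCMResult",
    "DensityLabel",
    "LowSeparationWarning",
    "fcm_cluster",
    "segment_fgt",
    "apply_posterior_cutoff",
    "compute_density",
]


class LowSeparationWarning(UserWarning):
    """Cluster centroids too close to represent two tissue classes."""


@dataclass(frozen=True)
class FCMConfig:
    """Fuzzy c-means settings.

    ``m`` is the fuzziness exponent of the objective
    J = sum_i sum_k u_ik^m ||x_i - c_k||^2 (m > 1); ``tol`` is the
    convergence threshold on the maximum centroid shift between iterations.
    """

    n_clusters: int = 2
    m: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0
    # centroid gap (in the volume's intensity units) below which the two
    # clusters are considered one tissue class; used by segment_fgt
    min_separation: float = 0.15

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not self.m > 1:
            raise ValueError("fuzziness m must be > 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


@dataclass
class FCMResult:
    centroids: np.ndarray        # (K,) intensity values
    memberships: np.ndarray      # (N, K) row-stochastic weights
    objective: np.ndarray        # J per iteration, non-increasing
    n_iter: int
    converged: bool


@dataclass
class DensityLabel:
    value: float
    n_fgt_voxels: float
    n_breast_voxels: float


def _init_centroids(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++-style spread over the observed intensity values."""
    centroids = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min((x[:, None] - np.asarray(centroids)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            # all remaining mass at existing centroids; spread deterministically
            centroids.append(x[np.argmax(np.abs(x - centroids[0]))])
            continue
        centroids.append(x[rng.choice(len(x), p=d2 / total)])
    return np.asarray(centroids, dtype=np.float64)


def _memberships(x: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1)); centroid hits get weight 1."""
    d = np.abs(x[:, None] - centroids[None, :])
    u = np.zeros((len(x), len(centroids)))
    hit = d == 0
    any_hit = hit.any(axis=1)
    with np.errstate(divide="ignore"):
        inv = d[~any_hit] ** (-2.0 / (m - 1.0))
    u[~any_hit] = inv / inv.sum(axis=1, keepdims=True)
    # singularity rule: a sample coincident with a centroid belongs to it
    # (mass split evenly if coincident with several)
    u[any_hit] = hit[any_hit] / hit[any_hit].sum(axis=1, keepdims=True)
    return u


def _objective(x, centroids, u, m) -> float:
    d2 = (x[:, None] - centroids[None, :]) ** 2
    return float((u**m * d2).sum())


def fcm_cluster(intensities: np.ndarray, config: FCMConfig = FCMConfig()) -> FCMResult:
    """Fuzzy c-means on a 1D sample of voxel intensities.

    Alternates the membership update
    u_ik = 1 / sum_j (d_ik/d_ij)^(2/(m-1)) and the centroid update
    c_k = sum_i u_ik^m x_i / sum_i u_ik^m until the maximum centroid shift
    drops below ``tol`` or ``max_iter`` is reached.  Non-convergence is
    reported through ``converged=False``, never silently.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if len(np.unique(x)) < config.n_clusters:
        raise ValueError(
            f"need >= {config.n_clusters} distinct values, got {len(np.unique(x))}"
        )
    rng = np.random.default_rng(config.seed)
    centroids = _init_centroids(x, config.n_clusters, rng)
    objective = []
    converged = False
    u = _memberships(x, centroids, config.m)
    for it in range(1, config.max_iter + 1):
        um = u**config.m
        new_centroids = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        u = _memberships(x, new_centroids, config.m)
        objective.append(_objective(x, new_centroids, u, config.m))
        shift = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        if shift < config.tol:
            converged = True
            break
    return FCMResult(
        centroids=centroids,
        memberships=u,
        objective=np.asarray(objective),
        n_iter=len(objective),
        converged=converged,
    )


def segment_fgt(
    volume: Volume,
    breast_mask: np.ndarray,
    config: FCMConfig = FCMConfig(),
    counting: str = "hard",
):
    """Segment fibroglandular tissue inside the breast by FCM.

    Clusters the breast-interior intensities only; the cluster with the
    LOWER centroid is fibroglandular (fat is bright without fat
    suppression).  A voxel joins the FGT mask iff its FGT membership exceeds
    0.5 — ties go to fat, which is the conservative direction for density.

    If the two centroids are closer than ``config.min_separation`` the breast
    is treated as a single tissue class: an empty FGT mask is returned with a
    :class:`LowSeparationWarning`, rather than splitting the noise
    distribution in half.

    Returns ``(fgt_mask, result)``; with ``counting="fuzzy"`` the result's
    memberships can be summed instead of counting mask voxels.
    """
    if not breast_mask.any():
        raise ValueError("breast_mask is empty")
    if counting not in ("hard", "fuzzy"):
        raise ValueError("counting must be 'hard' or 'fuzzy'")
    inside = np.asarray(volume.values)[breast_mask]
    result = fcm_cluster(inside, config)
    order = np.argsort(result.centroids)
    fgt_cluster = order[0]
    gap = float(result.centroids[order[-1]] - result.centroids[order[0]])
    fgt_mask = np.zeros_like(breast_mask, dtype=bool)
    if gap < config.min_separation:
        warnings.warn(
            f"centroid separation {gap:.4f} < {config.min_separation}: breast "
            "treated as a single tissue class, no FGT segmented",
            LowSeparationWarning,
            stacklevel=2,
        )
        return fgt_mask, result
    fgt_mask[breast_mask] = result.memberships[:, fgt_cluster] > 0.5
    return fgt_mask, result


def apply_posterior_cutoff(mask: np.ndarray, sternum_plane_index: int) -> np.ndarray:
    """Clear every mask voxel at or posterior of the sternum plane.

    The posterior axis is axis 1 (increasing index = more posterior); the
    index may equal the grid extent, which leaves the mask unchanged.
    """
    n1 = mask.shape[1]
    if not (0 <= sternum_plane_index <= n1):
        raise ValueError(f"sternum plane index {sternum_plane_index} outside grid extent {n1}")
    out = mask.copy()
    out[:, sternum_plane_index:, :] = False
    return out


def compute_density(
    fgt_mask: np.ndarray,
    breast_mask: np.ndarray,
    fgt_memberships: np.ndarray | None = None,
) -> DensityLabel:
    """Volumetric density = 100 * |FGT| / |breast|.

    With ``fgt_memberships`` (the FGT-cluster membership of each breast
    voxel, in breast-mask order) the numerator is the summed fuzzy
    membership instead of the hard voxel count.
    """
    n_breast = int(breast_mask.sum())
    if n_breast == 0:
        raise ValueError("breast_mask is empty")
    if np.any(fgt_mask & ~breast_mask):
        raise ValueError("fgt_mask must be a subset of breast_mask")
    if fgt_memberships is not None:
        n_fgt = float(np.sum(fgt_memberships))
    else:
        n_fgt = int(fgt_mask.sum())
    return DensityLabel(
        value=100.0 * n_fgt / n_breast,
        n_fgt_voxels=n_fgt,
        n_breast_voxels=n_breast,
    )
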