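"""Combined spatial + ODF k-means parcellation and the angular-difference baseline.

Each in-mask voxel is described by two feature blocks: its spatial position
(x, y, z) in mm and its mean ODF spherical-harmonic coefficient vector scaled
by a factor S_ODF that brings ODF distances into the range of the spatial
distances.  The clustering distance is the convex combination

    d^2(v, C) = alpha * d_pos^2(v, C) + (1 - alpha) * d_ODF^2(v, C)

which equals plain squared-Euclidean k-means on the concatenated vector
[sqrt(alpha) * pos, sqrt(1 - alpha) * S_ODF * c], so Lloyd centroid updates
(per-block means) are exact minimizers and the objective is monotone.

Initialization is data-driven: many position-only k-means runs are averaged
(after matching each run's centroids to the first run's by optimal
assignment), removing the dependence on any single random initialization.

The baseline replaces the ODF distance with the angular difference between
per-voxel principal diffusion directions, scaled by a constant factor; there
the cluster "direction" is updated as the principal eigenvector of the mean
dyadic tensor of member vectors, which is the proper antipodally symmetric
average (the plain vector mean of {+v, -v} would vanish).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .io import VolumeMask

log = logging.getLogger("thalparc")


@dataclass
class ClusterConfig:
    """All tunable constants of the parcellation.

    k : number of clusters (7 thalamic nuclei groups).
    alpha : spatial weight in [0, 1]; 0.5 weighs both blocks equally.
    s_odf : scaling applied to the ODF coefficients (55 brings ODF
        distances into the spatial-distance range on 2-mm-scale data).
    n_init_runs : number of position-only k-means runs averaged for the
        data-driven initialization.
    ad_scale : factor applied to the angular difference (radians) in the
        baseline so it is commensurate with mm-scale distances.
    """

    k: int = 7
    alpha: float = 0.5
    s_odf: float = 55.0
    n_init_runs: int = 5000
    max_iter: int = 300
    tol: float = 0.0
    seed: int = 0
    ad_scale: float = 6.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.s_odf <= 0:
            raise ValueError("s_odf must be positive")


@dataclass
class FeatureMatrix:
    """Per-voxel clustering features plus the indices mapping rows to voxels."""

    positions: np.ndarray    # (V, 3) mm
    odf: np.ndarray          # (V, R) s_odf-scaled coefficients
    voxel_index: np.ndarray  # (V, 3) integer voxel coordinates

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]


@dataclass
class Labeling:
    """Integer label volume (0 background, 1..k) with per-cluster centroids."""

    labels: np.ndarray         # (X, Y, Z) int
    centroids_mm: np.ndarray   # (k, 3)
    mean_features: np.ndarray  # (k, F) per-cluster mean full feature vector
    affine: np.ndarray
    voxel_size: np.ndarray
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.k = self.centroids_mm.shape[0]

    def cluster_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def labeling_from_volume(labels: np.ndarray, affine: np.ndarray,
                         voxel_size: np.ndarray,
                         k: int | None = None) -> Labeling:
    """Wrap an integer label volume, computing per-cluster spatial centroids."""
    labels = np.asarray(labels)
    k = int(labels.max()) if k is None else k
    cents = np.full((k, 3), np.nan)
    for i in range(1, k + 1):
        idx = np.argwhere(labels == i)
        if idx.shape[0]:
            cents[i - 1] = voxel_to_mm(idx, affine).mean(axis=0)
    return Labeling(labels=labels, centroids_mm=cents,
                    mean_features=cents.copy(), affine=affine,
                    voxel_size=np.asarray(voxel_size, dtype=float))


def voxel_to_mm(index: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Voxel-center indices (V, 3) -> world mm through the affine."""
    index = np.atleast_2d(index)
    return index @ affine[:3, :3].T + affine[:3, 3]


def mm_to_voxel(pos_mm: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    pos_mm = np.atleast_2d(pos_mm)
    return pos_mm @ inv[:3, :3].T + inv[:3, 3]


def extract_features(odf_field: np.ndarray, mask: VolumeMask,
                     cfg: ClusterConfig) -> FeatureMatrix:
    """Assemble the per-voxel feature matrix from an ODF coefficient volume.

    ``odf_field`` is (X, Y, Z, R).  Positions are voxel centers in mm through
    the mask affine; ODF coefficients are multiplied by ``cfg.s_odf``.
    """
    idx = np.argwhere(mask.grid)
    coeffs = odf_field[mask.grid]
    bad = ~np.all(np.isfinite(coeffs), axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite ODF coefficients inside mask at voxels "
            f"{idx[bad][:5].tolist()}{'...' if bad.sum() > 5 else ''}")
    positions = voxel_to_mm(idx, mask.affine)
    return FeatureMatrix(positions=positions, odf=cfg.s_odf * coeffs,
                         voxel_index=idx)


# ---------------------------------------------------------------------------
# Data-driven initialization
# ---------------------------------------------------------------------------

def init_centroids(features: FeatureMatrix, cfg: ClusterConfig) -> np.ndarray:
    """Average of many position-only k-means runs, with ODF slots filled.

    Runs ``cfg.n_init_runs`` randomly initialized position-only k-means
    (each run seeded independently with k-means++, so single runs rarely
    land in degenerate local optima), aligns every run's centroids to those
    of the best run (lowest inertia, a canonical data-determined reference)
    by optimal one-to-one assignment on centroid distance, and averages per
    slot.  Each averaged centroid's ODF block is initialized from the mean
    scaled ODF vector of the voxels in its 26-neighborhood (nearest voxel
    as fallback).

    Returns (k, 3 + R) full-feature initial centroids (unweighted blocks).
    """
    pos = features.positions
    k = cfg.k
    if k > pos.shape[0]:
        raise ValueError(f"k={k} exceeds {pos.shape[0]} voxels")
    if np.unique(pos, axis=0).shape[0] < k:
        raise ValueError("fewer than k distinct positions")
    rng = np.random.default_rng(cfg.seed)
    runs = []
    inertias = []
    for _ in range(cfg.n_init_runs):
        seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                    random_state=seed).fit(pos)
        runs.append(km.cluster_centers_)
        inertias.append(km.inertia_)
    ref = runs[int(np.argmin(inertias))]
    acc = np.zeros((k, 3))
    for cents in runs:
        cost = cdist(ref, cents)
        _, col = linear_sum_assignment(cost)
        acc += cents[col]
    spatial = acc / cfg.n_init_runs

    odf_init = np.empty((k, features.odf.shape[1]))
    vox_size = _voxel_scale(features)
    for i in range(k):
        d = np.abs(features.positions - spatial[i])
        near = np.all(d <= vox_size * 1.001, axis=1)  # 26-neighborhood in mm
        if not near.any():
            near = np.zeros(features.n_voxels, dtype=bool)
            near[np.argmin(np.linalg.norm(d, axis=1))] = True
        odf_init[i] = features.odf[near].mean(axis=0)
    return np.hstack([spatial, odf_init])


def _voxel_scale(features: FeatureMatrix) -> np.ndarray:
    """Approximate per-axis voxel pitch (mm) from the position grid."""
    scale = np.ones(3)
    for ax in range(3):
        vals = np.unique(features.positions[:, ax])
        if vals.size > 1:
            scale[ax] = np.min(np.diff(vals))
    return scale


# ---------------------------------------------------------------------------
# Lloyd iteration on the combined feature space
# ---------------------------------------------------------------------------

def _relabel(assign: np.ndarray, centroids: np.ndarray, k: int
             ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic relabeling: descending size, ties by centroid lex order."""
    sizes = np.bincount(assign, minlength=k)
    order = sorted(range(k),
                   key=lambda j: (-sizes[j], tuple(centroids[j, :3])))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return remap[assign], centroids[order]


def _lloyd(weighted: np.ndarray, init: np.ndarray, cfg: ClusterConfig
           ) -> tuple[np.ndarray, np.ndarray]:
    """Plain squared-Euclidean Lloyd with empty-cluster reseeding.

    Asserts the objective is non-increasing across iterations.  Returns
    (assignments, centroids) in the weighted feature space.
    """
    cents = init.copy()
    prev_assign = None
    prev_obj = np.inf
    for _ in range(cfg.max_iter):
        d2 = cdist(weighted, cents, metric="sqeuclidean")
        assign = np.argmin(d2, axis=1)
        obj = float(d2[np.arange(len(assign)), assign].sum())
        assert obj <= prev_obj + 1e-8 * max(1.0, abs(prev_obj)), \
            "k-means objective increased"
        for j in range(cfg.k):
            members = assign == j
            if members.any():
                cents[j] = weighted[members].mean(axis=0)
            else:
                far = int(np.argmax(d2[np.arange(len(assign)), assign]))
                log.info("empty cluster %d reseeded at farthest point", j)
                cents[j] = weighted[far]
                assign[far] = j
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        if cfg.tol > 0 and prev_obj - obj <= cfg.tol * max(1.0, prev_obj):
            break
        prev_assign = assign
        prev_obj = obj
    return assign, cents


def _make_labeling(assign: np.ndarray, full: np.ndarray,
                   features: FeatureMatrix, mask: VolumeMask,
                   k: int) -> Labeling:
    # unweighted per-cluster means (robust to zero block weights)
    cents = np.vstack([full[assign == j].mean(axis=0) for j in range(k)])
    assign, cents = _relabel(assign, cents, k)
    labels = np.zeros(mask.grid.shape, dtype=np.int16)
    labels[tuple(features.voxel_index.T)] = assign + 1
    return Labeling(labels=labels, centroids_mm=cents[:, :3].copy(),
                    mean_features=cents, affine=mask.affine,
                    voxel_size=mask.voxel_size)


def kmeans_combined(features: FeatureMatrix, init: np.ndarray,
                    cfg: ClusterConfig, mask: VolumeMask) -> Labeling:
    """Lloyd k-means on [sqrt(alpha)*pos, sqrt(1-alpha)*scaled ODF].

    ``init`` holds k unweighted full-feature centroids (as produced by
    :func:`init_centroids`).  Clusters are relabeled deterministically
    (descending size, ties by centroid lexicographic order); labels run 1..k
    in the output volume.
    """
    if init.shape[0] != cfg.k:
        raise ValueError("init must provide k centroids")
    full = np.hstack([features.positions, features.odf])
    weights = np.concatenate([
        np.full(3, np.sqrt(cfg.alpha)),
        np.full(features.odf.shape[1], np.sqrt(1.0 - cfg.alpha)),
    ])
    assign, _ = _lloyd(full * weights, init * weights, cfg)
    return _make_labeling(assign, full, features, mask, cfg.k)


# ---------------------------------------------------------------------------
# Angular-difference baseline
# ---------------------------------------------------------------------------

def angular_difference(v1: np.ndarray, v2: np.ndarray) -> float:
    """Antipodally symmetric angle arccos(|v1.v2|) in [0, pi/2] radians."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angular difference of a zero vector is undefined")
    return float(np.arccos(np.clip(abs(v1 @ v2) / (n1 * n2), 0.0, 1.0)))


def _dyadic_mean_direction(vectors: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the mean outer-product tensor of unit vectors."""
    T = vectors.T @ vectors / vectors.shape[0]
    _, evecs = np.linalg.eigh(T)
    return evecs[:, -1]


def kmeans_ad(features: FeatureMatrix, principal_vectors: np.ndarray,
              init: np.ndarray, cfg: ClusterConfig,
              mask: VolumeMask) -> Labeling:
    """Baseline clustering: spatial distance + scaled angular difference.

    d^2(v, C) = alpha * d_pos^2 + (1-alpha) * (ad_scale * AD(e1_v, dir_C))^2.
    Cluster directions update as the principal eigenvector of the member
    dyadic mean; the spatial centroid updates as the mean position.  ``init``
    provides k spatial centroids (only the first 3 columns are used; initial
    directions come from the dyadic mean of each centroid's nearest voxels).
    """
    if init.shape[0] != cfg.k:
        raise ValueError("init must provide k centroids")
    pos = features.positions
    e1 = np.asarray(principal_vectors, dtype=float)
    e1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    cents_pos = init[:, :3].copy()
    # initial directions: dyadic mean of each slot's nearest voxels
    nearest = np.argmin(cdist(pos, cents_pos, "sqeuclidean"), axis=1)
    cents_dir = np.empty((cfg.k, 3))
    for j in range(cfg.k):
        members = nearest == j
        cents_dir[j] = (_dyadic_mean_direction(e1[members]) if members.any()
                        else np.array([1.0, 0.0, 0.0]))
    prev_assign = None
    for _ in range(cfg.max_iter):
        d_pos2 = cdist(pos, cents_pos, "sqeuclidean")
        cosang = np.clip(np.abs(e1 @ cents_dir.T), 0.0, 1.0)
        ad = np.arccos(cosang)
        d2 = cfg.alpha * d_pos2 + (1 - cfg.alpha) * (cfg.ad_scale * ad) ** 2
        assign = np.argmin(d2, axis=1)
        for j in range(cfg.k):
            members = assign == j
            if members.any():
                cents_pos[j] = pos[members].mean(axis=0)
                cents_dir[j] = _dyadic_mean_direction(e1[members])
            else:
                far = int(np.argmax(d2[np.arange(len(assign)), assign]))
                log.info("empty AD cluster %d reseeded at farthest point", j)
                cents_pos[j] = pos[far]
                cents_dir[j] = e1[far]
                assign[far] = j
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign
    assign, order_cents = _relabel(assign, np.hstack([cents_pos, cents_dir]),
                                   cfg.k)
    labels = np.zeros(mask.grid.shape, dtype=np.int16)
    labels[tuple(features.voxel_index.T)] = assign + 1
    return Labeling(labels=labels, centroids_mm=order_cents[:, :3].copy(),
                    mean_features=order_cents, affine=mask.affine,
                    voxel_size=mask.voxel_size)
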