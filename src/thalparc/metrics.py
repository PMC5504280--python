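"""Quantitative evaluation of parcellations.

Cluster labels produced by k-means are arbitrary, so every pairwise
comparison first matches labels by maximizing total voxel overlap (optimal
assignment on the k x k contingency table).  Matched pairs are then compared
with the Dice coefficient, the Euclidean distance between spatial centroids,
and the modified Hausdorff distance of Dubuisson & Jain between cluster
contours (the max of the two directed mean nearest-neighbor distances, which
is far less outlier-sensitive than the classical Hausdorff distance).

Group-level summaries: a majority-vote consensus map across aligned
labelings, per-cluster volumes normalized by the mask size, the distance of
each centroid to the mask contour, and a Wilcoxon signed-rank test of
left/right hemispheric symmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.stats import wilcoxon

from .cluster import Labeling, mm_to_voxel, voxel_to_mm
from .io import VolumeMask
from .refine import border_distance_map

log = logging.getLogger("thalparc")


@dataclass
class MetricsReport:
    """Per matched cluster pair: Dice, centroid distance, modified Hausdorff."""

    permutation: np.ndarray        # permutation[i] = label in L2 matching i+1
    dice: np.ndarray               # (k,)
    centroid_distance: np.ndarray  # (k,) mm
    modified_hausdorff: np.ndarray  # (k,) mm

    def as_rows(self) -> list[dict]:
        return [
            {"cluster": i + 1, "matched": int(self.permutation[i]),
             "dice": float(self.dice[i]),
             "centroid_distance_mm": float(self.centroid_distance[i]),
             "modified_hausdorff_mm": float(self.modified_hausdorff[i])}
            for i in range(len(self.dice))
        ]


def match_labels(l1: Labeling, l2: Labeling) -> np.ndarray:
    """One-to-one label assignment maximizing total voxel overlap.

    Returns ``perm`` with ``perm[i]`` = the label of ``l2`` matched to label
    ``i+1`` of ``l1``.
    """
    if l1.k != l2.k:
        raise ValueError("labelings have different numbers of clusters")
    if l1.labels.shape != l2.labels.shape:
        raise ValueError("labelings live on different grids")
    k = l1.k
    overlap = np.zeros((k, k))
    both = (l1.labels > 0) & (l2.labels > 0)
    a, b = l1.labels[both] - 1, l2.labels[both] - 1
    np.add.at(overlap, (a, b), 1)
    row, col = linear_sum_assignment(-overlap)
    perm = np.empty(k, dtype=int)
    perm[row] = col + 1
    return perm


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A^B| / (|A|+|B|) of two boolean voxel sets; 0 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.count_nonzero(a & b) / denom


def boundary_points_mm(region: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """6-connectivity boundary voxels of a region, as mm coordinates."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region has no boundary")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(region, structure, border_value=0)
    boundary = region & ~interior
    return voxel_to_mm(np.argwhere(boundary), affine)


def modified_hausdorff(a_pts: np.ndarray, b_pts: np.ndarray) -> float:
    """Dubuisson-Jain distance: max of the two directed mean NN distances."""
    a_pts = np.atleast_2d(a_pts)
    b_pts = np.atleast_2d(b_pts)
    if a_pts.shape[0] == 0 or b_pts.shape[0] == 0:
        raise ValueError("modified Hausdorff of an empty point set")
    d_ab = cKDTree(b_pts).query(a_pts)[0].mean()
    d_ba = cKDTree(a_pts).query(b_pts)[0].mean()
    return float(max(d_ab, d_ba))


def centroid_distance(l1: Labeling, l2: Labeling,
                      perm: np.ndarray) -> np.ndarray:
    """Euclidean distance (mm) between matched spatial centroids."""
    return np.linalg.norm(
        l1.centroids_mm - l2.centroids_mm[np.asarray(perm) - 1], axis=1)


def compare_labelings(l1: Labeling, l2: Labeling) -> MetricsReport:
    """Match labels, then compute Dice / centroid distance / modified Hausdorff."""
    perm = match_labels(l1, l2)
    k = l1.k
    dc = np.empty(k)
    mhd = np.empty(k)
    for i in range(k):
        m1 = l1.cluster_mask(i + 1)
        m2 = l2.cluster_mask(perm[i])
        dc[i] = dice(m1, m2)
        mhd[i] = modified_hausdorff(boundary_points_mm(m1, l1.affine),
                                    boundary_points_mm(m2, l2.affine))
    return MetricsReport(permutation=perm, dice=dc,
                         centroid_distance=centroid_distance(l1, l2, perm),
                         modified_hausdorff=mhd)


def majority_vote_map(labelings: list[Labeling],
                      permutations: list[np.ndarray] | None = None
                      ) -> np.ndarray:
    """Per-voxel modal label after permutation alignment to a reference.

    ``permutations[i]`` maps the reference's labels onto ``labelings[i]``
    (as returned by ``match_labels(reference, labelings[i])``); ``None``
    matches everything against ``labelings[0]``.  Ties break to the lowest
    label; the tie count is logged.
    """
    if not labelings:
        raise ValueError("no labelings to vote over")
    if permutations is None:
        permutations = [match_labels(labelings[0], lab) for lab in labelings]
    k = labelings[0].k
    shape = labelings[0].labels.shape
    counts = np.zeros(shape + (k + 1,), dtype=np.int32)
    for lab, perm in zip(labelings, permutations):
        inv = np.zeros(k + 1, dtype=int)
        inv[np.asarray(perm)] = np.arange(1, k + 1)  # lab's label -> reference label
        aligned = inv[lab.labels]
        for val in range(k + 1):
            counts[..., val] += aligned == val
    best = counts.max(axis=-1)
    modal = counts.argmax(axis=-1)  # argmax takes the lowest label on ties
    ties = int(((counts == best[..., None]).sum(axis=-1) > 1).sum())
    if ties:
        log.info("majority vote: %d tie voxels broken to the lowest label",
                 ties)
    return modal.astype(np.int16)


def normalized_volumes(labeling: Labeling, mask: VolumeMask) -> np.ndarray:
    """Per-cluster voxel count divided by the mask voxel count."""
    total = mask.n_voxels
    if total == 0:
        raise ValueError("empty mask")
    counts = np.array([np.count_nonzero(labeling.labels == i + 1)
                       for i in range(labeling.k)], dtype=float)
    return counts / total


def centroid_border_distance(labeling: Labeling,
                             mask: VolumeMask) -> np.ndarray:
    """Border-distance-map value (mm) at each cluster centroid.

    The distance map is sampled by trilinear interpolation at the
    (generally non-integer) centroid voxel coordinate.
    """
    dist = border_distance_map(mask)
    vox = mm_to_voxel(labeling.centroids_mm, mask.affine)
    return ndimage.map_coordinates(dist, vox.T, order=1, mode="nearest")


def symmetry_test(left_values: np.ndarray,
                  right_values: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-subject values.

    Zero differences are handled by the Pratt method; the all-identical case
    (no effect whatsoever) returns statistic 0 and p = 1.
    """
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    if left.shape != right.shape:
        raise ValueError("paired samples must have equal length")
    if left.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.allclose(left, right):
        log.info("symmetry test: all differences zero; p = 1")
        return 0.0, 1.0
    res = wilcoxon(left, right, zero_method="pratt", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
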