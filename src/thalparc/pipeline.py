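"""End-to-end parcellation pipeline.

Chains the processing stages on in-memory objects: Gaussian smoothing of the
DWI volumes, tensor/FA fitting, CSF+FA mask refinement, bootstrap-mean CSA
ODF reconstruction over the refined mask, and the combined spatial+ODF
k-means (or the angular-difference baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cluster as _cluster
from . import odf as _odf
from . import refine as _refine
from .io import DWIVolume, GradientScheme, VolumeMask, smooth_dwi

log = logging.getLogger("thalparc")


@dataclass
class PipelineConfig:
    """Aggregated settings of the full pipeline."""

    sigma_mm: float = 0.8
    lmax: int = 6
    lambda_reg: float = 0.006
    delta_clip: float = 1e-3
    refine: _refine.RefineConfig = field(default_factory=_refine.RefineConfig)
    cluster: _cluster.ClusterConfig = field(
        default_factory=_cluster.ClusterConfig)
    bootstrap: _odf.BootstrapConfig = field(
        default_factory=_odf.BootstrapConfig)
    feature: str = "odf"  # "odf" or "ad"
    do_refine: bool = True


def odf_field(dwi: DWIVolume, scheme: GradientScheme, mask: VolumeMask,
              cfg: PipelineConfig) -> np.ndarray:
    """Bootstrap-mean ODF coefficient volume (X, Y, Z, R) over the mask."""
    basis = _odf.build_sh_basis(cfg.lmax, scheme.directions)
    transform = _odf.CSATransform(cfg.lmax)
    signals = dwi.data[mask.grid][:, scheme.dwi_mask]
    s0 = dwi.s0[mask.grid]
    coeffs = _odf.bootstrap_mean_odf_field(
        signals, s0, basis, transform, cfg.bootstrap,
        lambda_reg=cfg.lambda_reg, delta_clip=cfg.delta_clip)
    out = np.zeros(dwi.shape + (basis.n_coeffs,))
    out[mask.grid] = coeffs
    return out


def run_pipeline(dwi: DWIVolume, scheme: GradientScheme, mask: VolumeMask,
                 csf_prob: np.ndarray | None = None,
                 cfg: PipelineConfig | None = None
                 ) -> tuple[_cluster.Labeling, VolumeMask]:
    """Smooth, refine the mask, reconstruct ODFs, cluster.

    Returns the labeling and the (possibly refined) working mask.  With
    ``cfg.feature == "ad"`` the ODF block is replaced by the scaled angular
    difference of per-voxel principal tensor directions.
    """
    cfg = cfg or PipelineConfig()
    dwi = smooth_dwi(dwi, cfg.sigma_mm)

    work_mask = mask
    if cfg.do_refine:
        fa = _odf.fa_map(dwi, scheme, mask)
        csf = np.zeros(mask.grid.shape) if csf_prob is None else csf_prob
        work_mask = _refine.refine_mask(mask, csf, fa, cfg.refine)

    if cfg.feature == "odf":
        field_ = odf_field(dwi, scheme, work_mask, cfg)
        features = _cluster.extract_features(field_, work_mask, cfg.cluster)
        init = _cluster.init_centroids(features, cfg.cluster)
        labeling = _cluster.kmeans_combined(features, init, cfg.cluster,
                                            work_mask)
    elif cfg.feature == "ad":
        signals = dwi.data[work_mask.grid][:, scheme.dwi_mask]
        s0 = dwi.s0[work_mask.grid]
        _, e1, _ = _odf.fit_tensor_field(signals, s0, scheme)
        idx = np.argwhere(work_mask.grid)
        features = _cluster.FeatureMatrix(
            positions=_cluster.voxel_to_mm(idx, work_mask.affine),
            odf=np.zeros((idx.shape[0], 1)), voxel_index=idx)
        init = _cluster.init_centroids(features, cfg.cluster)
        labeling = _cluster.kmeans_ad(features, e1, init, cfg.cluster,
                                      work_mask)
    else:
        raise ValueError(f"unknown feature type {cfg.feature!r}")
    return labeling, work_mask
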