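"""Readers/writers for the volumes and gradient tables the pipeline touches.

All volumes are NIfTI-1 via nibabel; gradient tables are FSL-style plain-text
``bvals``/``bvecs``. World coordinates are millimetres in the image affine
frame; voxel indexing is 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

log = logging.getLogger("thalparc")

#: b-values below this (s/mm^2) are treated as b=0, robust to scanner-reported
#: near-zero values.
B0_THRESHOLD = 50.0


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected dialect."""


class SchemeError(ValueError):
    """Raised when a gradient scheme is unusable (e.g. no b=0 volume)."""


@dataclass
class GradientScheme:
    """Diffusion sampling scheme: per-volume b-value and unit direction.

    ``bvecs[i]`` is the unit gradient direction of volume ``i`` (the zero
    vector is retained for b=0 volumes, by FSL convention).
    """

    bvals: np.ndarray  # (N,) s/mm^2
    bvecs: np.ndarray  # (N, 3) unit vectors; zero rows allowed at b=0

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise SchemeError("bvals and bvecs have different lengths")
        if self.bvecs.shape[1] != 3:
            raise SchemeError("bvecs must be Nx3")
        if not np.any(self.b0_mask):
            raise SchemeError("no b=0 volume in scheme")
        if not np.any(self.dwi_mask):
            raise SchemeError("no diffusion-weighted volumes")
        norms = np.linalg.norm(self.bvecs[self.dwi_mask], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise SchemeError("non-unit gradient direction at a b>0 volume")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.b0_mask))

    @property
    def n_dwi(self) -> int:
        return int(np.count_nonzero(self.dwi_mask))

    @property
    def directions(self) -> np.ndarray:
        """Unit directions of the diffusion-weighted volumes only."""
        return self.bvecs[self.dwi_mask]

    @property
    def b_nominal(self) -> float:
        """The (single-shell) b-value of the diffusion-weighted volumes."""
        return float(np.median(self.bvals[self.dwi_mask]))


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal S(u) plus the mean b=0 image S(0)."""

    data: np.ndarray       # (X, Y, Z, N)
    s0: np.ndarray         # (X, Y, Z)
    voxel_size: np.ndarray  # (3,) mm
    affine: np.ndarray      # (4, 4)

    def __post_init__(self) -> None:
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.data.shape[:3] != self.s0.shape:
            raise FormatError("spatial shape of data does not match s0")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class VolumeMask:
    """Binary 3-D mask on the same grid as the DWI volume."""

    grid: np.ndarray        # (X, Y, Z) bool
    voxel_size: np.ndarray  # (3,) mm
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.grid))


def read_gradient_scheme(bvals_path, bvecs_path) -> GradientScheme:
    """Read FSL-dialect bvals (one row) and bvecs (3 rows x N columns)."""
    bvals = np.loadtxt(bvals_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvecs_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL writes 3 rows x N columns
        bvecs = bvecs.T
    if bvecs.shape[1] != 3:
        raise FormatError(f"bvecs has shape {bvecs.shape}, expected 3xN")
    if bvals.shape[0] != bvecs.shape[0]:
        raise FormatError("bvals and bvecs lengths differ")
    # renormalize directions at b>0; keep zero rows at b=0
    dwi = bvals >= B0_THRESHOLD
    norms = np.linalg.norm(bvecs, axis=1)
    if np.any(norms[dwi] == 0):
        raise FormatError("zero gradient vector at a diffusion-weighted volume")
    bvecs = bvecs.copy()
    bvecs[dwi] /= norms[dwi, None]
    bvecs[~dwi & (norms > 0)] /= norms[~dwi & (norms > 0), None]
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def read_dwi(dwi_path, bvals_path, bvecs_path) -> tuple[DWIVolume, GradientScheme]:
    """Load a 4-D NIfTI plus its FSL gradient table.

    ``s0`` is the mean of all b=0 volumes; b-values below 50 s/mm^2 count
    as b=0.
    """
    scheme = read_gradient_scheme(bvals_path, bvecs_path)
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D image, got {data.ndim}-D")
    if data.shape[3] != scheme.bvals.shape[0]:
        raise FormatError(
            f"image has {data.shape[3]} volumes but scheme lists "
            f"{scheme.bvals.shape[0]}"
        )
    if scheme.n_dwi == 0:
        raise SchemeError("no diffusion-weighted volumes")
    s0 = data[..., scheme.b0_mask].mean(axis=3)
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIVolume(data=data, s0=s0, voxel_size=voxel_size,
                     affine=np.asarray(img.affine)), scheme


def write_dwi(path, dwi: DWIVolume) -> None:
    img = nib.Nifti1Image(dwi.data.astype(np.float32), dwi.affine)
    img.header.set_zooms(tuple(dwi.voxel_size) + (1.0,))
    nib.save(img, str(path))


def write_scheme(bvals_path, bvecs_path, scheme: GradientScheme) -> None:
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvecs_path, scheme.bvecs.T, fmt="%.8f")


def smooth_dwi(dwi: DWIVolume, sigma_mm: float = 0.8) -> DWIVolume:
    """Smooth each 3-D volume with an isotropic Gaussian of std ``sigma_mm``.

    The std is expressed in mm and converted to voxels per axis; b=0 volumes
    (hence ``s0``) are smoothed identically. Reflect padding at the edges
    keeps image mass near the boundary.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be non-negative")
    if sigma_mm == 0:
        return dwi
    sigma_vox = sigma_mm / dwi.voxel_size
    out = np.empty_like(dwi.data)
    for i in range(dwi.data.shape[3]):
        out[..., i] = ndimage.gaussian_filter(dwi.data[..., i], sigma_vox,
                                              mode="reflect")
    s0 = ndimage.gaussian_filter(dwi.s0, sigma_vox, mode="reflect")
    return DWIVolume(data=out, s0=s0, voxel_size=dwi.voxel_size,
                     affine=dwi.affine)


def read_mask(path) -> VolumeMask:
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj) > 0.5
    return VolumeMask(grid=grid,
                      voxel_size=np.asarray(img.header.get_zooms()[:3]),
                      affine=np.asarray(img.affine))


def write_mask(path, mask: VolumeMask) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def write_labeling(path, labels: np.ndarray, affine: np.ndarray) -> None:
    """Write an integer label volume (0 = background) losslessly."""
    img = nib.Nifti1Image(np.asarray(labels).astype(np.int16), affine)
    nib.save(img, str(path))


def read_labeling(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an integer label volume; float files with integral values cast."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise FormatError("label volume contains non-integer voxel values")
    labels = rounded.astype(np.int32)
    if not labels.any():
        log.warning("empty labeling read from %s", path)
    return labels, np.asarray(img.affine)


def load_config(path) -> dict:
    """Load a YAML config holding refinement/clustering constants."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
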