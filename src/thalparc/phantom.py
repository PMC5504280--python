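"""Synthetic multi-tensor diffusion phantoms.

The generator emulates a single-shell acquisition (default 64 directions at
b = 1000 s/mm^2 plus one b=0 volume, 2 x 2 x 2.5 mm voxels) over an
ellipsoidal "thalamus" partitioned into k spatially compact regions: a
spherical central core (mirroring the medial nuclear group, which is
surrounded by the other nuclei rather than reaching the thalamic border)
plus k-1 equal-angle azimuthal wedge sectors around it.  Every region is
spatially compact and no two regions collapse onto a common point, matching
the working assumption of the parcellation that spatial position and ODF
shape jointly separate nuclei.  Each region carries its own fiber
configuration (one or two tensor compartments); the defaults place the k-1
wedge fibers in-plane at 30-degree steps and the core fiber axially, so
neighboring regions always differ strongly in orientation.  The noise-free
signal is the multi-tensor model

    S(u) = S0 * sum_i f_i * exp(-b u^T D_i u)

with Rician noise (magnitude of a complex Gaussian perturbation of std
S0/SNR) added per volume.  Two contamination rims can be injected against
which the mask-refinement rules are exercised: a CSF-like rim (isotropic
free-water tensor, high CSF probability) on one side of the border and a
high-anisotropy shell emulating the internal capsule on the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIVolume, GradientScheme, VolumeMask
from .refine import border_distance_map

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

# diffusivities in mm^2/s
REGION_EIGENVALUES = (1.0e-3, 0.5e-3, 0.5e-3)   # moderate anisotropy, FA ~ 0.41
CAPSULE_EIGENVALUES = (1.7e-3, 0.2e-3, 0.2e-3)  # white-matter-like, FA ~ 0.86
CSF_DIFFUSIVITY = 3.0e-3                        # free water, isotropic


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the upper hemisphere (deterministic)."""
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * GOLDEN_ANGLE
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def default_scheme(n_dirs: int = 64, b: float = 1000.0,
                   n_b0: int = 1) -> GradientScheme:
    """Single-shell scheme: ``n_b0`` b=0 volumes then ``n_dirs`` directions."""
    dirs = fibonacci_hemisphere(n_dirs)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def _default_orientations(k: int) -> list[np.ndarray]:
    """Well-separated fiber orientations: k-1 in-plane fans plus one axial.

    The wedge regions get in-plane directions at equal angular steps over
    half a turn (antipodal symmetry makes half a turn sufficient); the
    central core gets the z axis, orthogonal to every wedge fiber.
    """
    if k == 1:
        return [np.array([0.0, 0.0, 1.0])]
    step = np.pi / (k - 1)
    dirs = [np.array([np.cos(i * step), np.sin(i * step), 0.0])
            for i in range(k - 1)]
    dirs.append(np.array([0.0, 0.0, 1.0]))
    return dirs


def _perpendicular(v: np.ndarray) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(v @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, helper)
    return p / np.linalg.norm(p)


@dataclass
class PhantomSpec:
    """Geometry, tissue model and acquisition of the synthetic phantom.

    Regions 1..k-1 are the azimuthal wedge sectors, region k is the central
    spherical core (its radius is set so every region holds ~1/k of the mask
    volume).  ``crossing_in_region`` adds a second, perpendicular 50/50 fiber
    compartment to one region; all regions share the moderate-anisotropy
    tensor eigenvalues typical of thalamic gray matter.
    """

    shape: tuple = (24, 24, 18)
    voxel_size: tuple = (2.0, 2.0, 2.5)
    semi_axes_mm: tuple = (23.0, 21.0, 9.0)
    k_regions: int = 7
    orientations: list | None = None       # per-region list of (n_i, 3) arrays
    fractions: list | None = None          # per-region volume fractions
    crossing_in_region: int | None = 1     # 1-based region to get a 2nd fiber
    snr: float | None = 30.0               # S0-referenced Rician SNR; None = noise-free
    s0: float = 1000.0
    scheme: GradientScheme = field(default_factory=default_scheme)
    csf_rim_mm: float = 2.0
    capsule_rim_mm: float = 2.0
    csf_prob_rim: float = 0.9
    region_eigenvalues: tuple = REGION_EIGENVALUES
    capsule_eigenvalues: tuple = CAPSULE_EIGENVALUES

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noise-free)")
        if self.orientations is None:
            base = _default_orientations(self.k_regions)
            self.orientations = [v[None, :] for v in base]
            if self.crossing_in_region is not None:
                r = self.crossing_in_region - 1
                v = base[r]
                self.orientations[r] = np.vstack([v, _perpendicular(v)])
        if self.fractions is None:
            self.fractions = [np.full(o.shape[0], 1.0 / o.shape[0])
                              for o in self.orientations]
        for o, f in zip(self.orientations, self.fractions):
            if not np.allclose(np.sum(f), 1.0):
                raise ValueError("region volume fractions must sum to 1")
            if not np.allclose(np.linalg.norm(o, axis=1), 1.0):
                raise ValueError("fiber orientations must be unit vectors")

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])


def _tensor(direction: np.ndarray, eigenvalues: tuple) -> np.ndarray:
    l1, l2, _ = eigenvalues
    d = np.asarray(direction, dtype=float)
    return (l1 - l2) * np.outer(d, d) + l2 * np.eye(3)


def multi_tensor_signal(scheme: GradientScheme, tensors: np.ndarray,
                        fractions: np.ndarray, s0: float) -> np.ndarray:
    """Closed-form multi-tensor signal over all scheme volumes (b=0 -> s0)."""
    out = np.full(scheme.bvals.shape[0], float(s0))
    g = scheme.bvecs
    b = scheme.bvals
    dwi = scheme.dwi_mask
    atten = np.zeros(np.count_nonzero(dwi))
    for D, f in zip(tensors, fractions):
        quad = np.einsum("ni,ij,nj->n", g[dwi], D, g[dwi])
        atten += f * np.exp(-b[dwi] * quad)
    out[dwi] = s0 * atten
    return out


def core_radius_mm(spec: PhantomSpec) -> float:
    """Radius of the central core region: 1/k of the ellipsoid volume."""
    volume = 4.0 / 3.0 * np.pi * float(np.prod(spec.semi_axes_mm))
    return (3.0 * volume / (4.0 * np.pi * spec.k_regions)) ** (1.0 / 3.0)


def _geometry(spec: PhantomSpec):
    """Mask, region labels, and contamination rims on the voxel grid.

    Regions: k-1 equal-angle azimuthal wedges around the mask center plus a
    central spherical core as region k (skipped for k = 1).
    """
    shape = np.asarray(spec.shape)
    vox = np.asarray(spec.voxel_size, dtype=float)
    idx = np.indices(spec.shape).reshape(3, -1).T
    pos = idx * vox
    center = (shape - 1) / 2.0 * vox
    rel = pos - center
    inside = np.sum((rel / np.asarray(spec.semi_axes_mm)) ** 2, axis=1) <= 1.0
    mask_grid = inside.reshape(spec.shape)
    mask = VolumeMask(grid=mask_grid, voxel_size=vox, affine=spec.affine)

    k = spec.k_regions
    if k == 1:
        region = np.ones(rel.shape[0], dtype=int)
    else:
        ang = np.arctan2(rel[:, 1], rel[:, 0])  # (-pi, pi]
        sector = np.floor((ang + np.pi) / (2 * np.pi / (k - 1))).astype(int)
        region = np.clip(sector, 0, k - 2) + 1
        core = np.linalg.norm(rel, axis=1) <= core_radius_mm(spec)
        region[core] = k
    truth = np.zeros(spec.shape, dtype=np.int16)
    truth[mask_grid] = region.reshape(spec.shape)[mask_grid]

    # contamination rims on the mask border: CSF on the +x side,
    # internal-capsule-like high-FA shell on the -x side
    dist = border_distance_map(mask)
    rim_csf = mask_grid & (dist <= spec.csf_rim_mm) \
        & (rel[:, 0].reshape(spec.shape) > 0)
    rim_capsule = mask_grid & (dist <= spec.capsule_rim_mm) \
        & (rel[:, 0].reshape(spec.shape) <= 0)
    if spec.csf_rim_mm <= 0:
        rim_csf[:] = False
    if spec.capsule_rim_mm <= 0:
        rim_capsule[:] = False
    return mask, truth, rim_csf, rim_capsule


def noiseless_phantom(spec: PhantomSpec):
    """Noise-free signal volume plus mask, CSF probability map and truth labels."""
    mask, truth, rim_csf, rim_capsule = _geometry(spec)
    n_vol = spec.scheme.bvals.shape[0]
    data = np.zeros(spec.shape + (n_vol,))

    profiles = {}
    for r in range(spec.k_regions):
        tensors = [_tensor(o, spec.region_eigenvalues)
                   for o in spec.orientations[r]]
        profiles[r + 1] = multi_tensor_signal(spec.scheme, tensors,
                                              spec.fractions[r], spec.s0)
    capsule_dir = np.array([0.0, 0.0, 1.0])
    capsule_profile = multi_tensor_signal(
        spec.scheme, [_tensor(capsule_dir, spec.capsule_eigenvalues)],
        np.array([1.0]), spec.s0)
    csf_profile = multi_tensor_signal(
        spec.scheme, [CSF_DIFFUSIVITY * np.eye(3)], np.array([1.0]), spec.s0)

    for r in range(1, spec.k_regions + 1):
        sel = (truth == r) & ~rim_csf & ~rim_capsule
        data[sel] = profiles[r]
    data[rim_capsule] = capsule_profile
    data[rim_csf] = csf_profile

    csf_prob = np.zeros(spec.shape)
    csf_prob[rim_csf] = spec.csf_prob_rim
    return data, mask, csf_prob, truth


def add_rician_noise(data: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the signal perturbed by complex Gaussian noise of std sigma."""
    n1 = rng.normal(0.0, sigma, size=data.shape)
    n2 = rng.normal(0.0, sigma, size=data.shape)
    return np.sqrt((data + n1) ** 2 + n2**2)


def _to_dwi(data: np.ndarray, spec: PhantomSpec) -> DWIVolume:
    s0 = data[..., spec.scheme.b0_mask].mean(axis=3)
    return DWIVolume(data=data, s0=s0, voxel_size=np.asarray(spec.voxel_size),
                     affine=spec.affine)


def generate_phantom(spec: PhantomSpec, seed: int = 0):
    """Synthesize one acquisition.

    Returns
    -------
    dwi : DWIVolume (noisy unless ``spec.snr`` is None)
    mask : VolumeMask
    csf_prob : (X, Y, Z) CSF probability map (high only in the injected rim)
    truth : (X, Y, Z) int ground-truth region labels (0 background)
    """
    clean, mask, csf_prob, truth = noiseless_phantom(spec)
    if spec.snr is None:
        return _to_dwi(clean, spec), mask, csf_prob, truth
    rng = np.random.default_rng(seed)
    noisy = add_rician_noise(clean, spec.s0 / spec.snr, rng)
    return _to_dwi(noisy, spec), mask, csf_prob, truth


def simulate_scan_rescan(spec: PhantomSpec, seed_a: int, seed_b: int):
    """Two acquisitions of the same noiseless phantom, independent noise.

    Returns (dwi_a, dwi_b, mask, csf_prob, truth).
    """
    clean, mask, csf_prob, truth = noiseless_phantom(spec)
    if spec.snr is None:
        return (_to_dwi(clean, spec), _to_dwi(clean.copy(), spec),
                mask, csf_prob, truth)
    sigma = spec.s0 / spec.snr
    dwi_a = _to_dwi(add_rician_noise(clean, sigma,
                                     np.random.default_rng(seed_a)), spec)
    dwi_b = _to_dwi(add_rician_noise(clean, sigma,
                                     np.random.default_rng(seed_b)), spec)
    return dwi_a, dwi_b, mask, csf_prob, truth
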