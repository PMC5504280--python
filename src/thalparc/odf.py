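"""Constant-solid-angle q-ball ODF reconstruction in a spherical-harmonic basis.

The diffusion signal ratio S(u)/S(0) on a single shell is passed through the
double-log transform ln(-ln S/S0) and fitted in the real, antipodally
symmetric (even-order) spherical-harmonic basis of Descoteaux et al.  The
constant-solid-angle ODF is then obtained analytically: the Laplace-Beltrami
operator and the Funk-Radon transform are both diagonal in the SH basis, with
eigenvalues -l(l+1) and 2*pi*P_l(0) respectively, so the transform reduces to
a per-order scaling of the fitted coefficients.  The constant term is fixed so
that the ODF integrates to 1 over the sphere.

Per-voxel uncertainty is propagated by residual bootstrapping in the
double-log domain: residuals of the initial fit are resampled with
replacement, the fit is repeated, and the coefficient-wise mean ODF is kept.

The module also carries the standard log-linear diffusion-tensor fit used for
the FA map (mask refinement) and for the principal-direction baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

from .io import GradientScheme

log = logging.getLogger("thalparc")

LOGLOG_SIGNAL = "loglog_signal"
ODF = "odf"


# ---------------------------------------------------------------------------
# Spherical-harmonic basis
# ---------------------------------------------------------------------------

def _cart_to_sphere(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors -> (polar theta from +z, azimuth phi)."""
    dirs = np.asarray(dirs, dtype=float)
    theta = np.arccos(np.clip(dirs[..., 2], -1.0, 1.0))
    phi = np.arctan2(dirs[..., 1], dirs[..., 0])
    return theta, phi


def sh_degrees_orders(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient (l, m) for the even-order basis, l ascending then m."""
    ls, ms = [], []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.array(ls), np.array(ms)


def sh_design_matrix(lmax: int, dirs: np.ndarray) -> np.ndarray:
    """Evaluate the modified real symmetric SH basis at unit vectors.

    Convention (Descoteaux): for m < 0, sqrt(2) * Re(Y_l^|m|); for m = 0,
    Y_l^0; for m > 0, sqrt(2) * Im(Y_l^m).  Only even orders are present, so
    every basis function is antipodally symmetric.
    """
    theta, phi = _cart_to_sphere(dirs)
    ls, ms = sh_degrees_orders(lmax)
    cols = []
    for l, m in zip(ls, ms):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2.0) * y.real)
        elif m == 0:
            cols.append(y.real)
        else:
            cols.append(np.sqrt(2.0) * y.imag)
    return np.stack(cols, axis=-1)


@dataclass
class SHBasis:
    """Even-order real SH basis sampled at a set of gradient directions."""

    lmax: int
    dirs: np.ndarray          # (N, 3) unit vectors (the b>0 shell)
    degrees: np.ndarray = field(init=False)  # per-coefficient l
    orders: np.ndarray = field(init=False)   # per-coefficient m
    design: np.ndarray = field(init=False)   # (N, R)

    def __post_init__(self) -> None:
        if self.lmax % 2 != 0 or self.lmax < 0:
            raise ValueError("lmax must be an even non-negative integer")
        self.dirs = np.atleast_2d(np.asarray(self.dirs, dtype=float))
        if self.dirs.shape[0] == 0:
            raise ValueError("basis needs at least one direction")
        self.degrees, self.orders = sh_degrees_orders(self.lmax)
        self.design = sh_design_matrix(self.lmax, self.dirs)

    @property
    def n_coeffs(self) -> int:
        return (self.lmax + 1) * (self.lmax + 2) // 2


def build_sh_basis(lmax: int, dirs: np.ndarray) -> SHBasis:
    """Construct the order-``lmax`` basis; R = (lmax+1)(lmax+2)/2 columns."""
    return SHBasis(lmax=lmax, dirs=dirs)


@dataclass
class SHCoeffVector:
    """Length-R real coefficient vector, tagged by the function it encodes."""

    coeffs: np.ndarray
    domain: str  # LOGLOG_SIGNAL or ODF

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite SH coefficients")


# ---------------------------------------------------------------------------
# The CSA transform
# ---------------------------------------------------------------------------

@dataclass
class CSATransform:
    """Per-order multipliers of the constant-solid-angle ODF estimator.

    For order l > 0 the double-log coefficients are scaled by
    ``-l(l+1) * 2*pi*P_l(0) / (16*pi^2)`` (Laplace-Beltrami eigenvalue, then
    Funk-Radon eigenvalue, then the solid-angle normalization).  The constant
    term is replaced by ``1/(2*sqrt(pi))`` so the ODF integrates to exactly 1.
    """

    lmax: int
    multipliers: np.ndarray = field(init=False)  # (R,), zero at l = 0
    c0: float = field(init=False)

    def __post_init__(self) -> None:
        degrees, _ = sh_degrees_orders(self.lmax)
        lb = -degrees * (degrees + 1.0)
        frt = 2.0 * np.pi * eval_legendre(degrees, 0.0)
        m = lb * frt / (16.0 * np.pi**2)
        m[degrees == 0] = 0.0
        self.multipliers = m
        self.c0 = 1.0 / (2.0 * np.sqrt(np.pi))


def csa_odf(c: SHCoeffVector, t: CSATransform) -> SHCoeffVector:
    """Apply the analytic CSA transform to double-log fit coefficients."""
    if c.domain == ODF:
        raise ValueError("input is already an ODF coefficient vector")
    out = c.coeffs * t.multipliers
    out[0] = t.c0
    return SHCoeffVector(coeffs=out, domain=ODF)


def csa_transform_array(coeffs: np.ndarray, t: CSATransform) -> np.ndarray:
    """Vectorized CSA transform on an (..., R) array of fit coefficients."""
    out = coeffs * t.multipliers
    out[..., 0] = t.c0
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _solver_matrix(basis: SHBasis, lambda_reg: float) -> np.ndarray:
    """(R, N) matrix H with c = H @ y, Laplace-Beltrami ridge optional."""
    B = basis.design
    n, r = B.shape
    if lambda_reg == 0.0:
        if n < r:
            raise ValueError(
                f"underdetermined fit: {n} directions < {r} coefficients "
                "and lambda_reg = 0"
            )
        return np.linalg.pinv(B)
    L = np.diag((basis.degrees * (basis.degrees + 1.0)) ** 2)
    return np.linalg.solve(B.T @ B + lambda_reg * L, B.T)


def loglog_transform(signal: np.ndarray, s0, delta_clip: float) -> np.ndarray:
    """Clipped double-log transform ln(-ln(S/S0)), elementwise."""
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("s0 must be strictly positive")
    ratio = np.asarray(signal, dtype=float) / s0
    ratio = np.clip(ratio, delta_clip, 1.0 - delta_clip)
    return np.log(-np.log(ratio))


def fit_loglog_sh(signal: np.ndarray, s0: float, basis: SHBasis,
                  lambda_reg: float = 0.006,
                  delta_clip: float = 1e-3) -> SHCoeffVector:
    """Least-squares SH fit of ln(-ln S/S0) on the shell directions.

    The signal ratio is clipped to ``[delta_clip, 1 - delta_clip]`` before
    the double log (the estimator requires 0 < S/S0 < 1).  ``lambda_reg``
    weights a Laplace-Beltrami ridge penalty; 0 gives the plain LS solution.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != basis.design.shape[0]:
        raise ValueError("one signal value per basis direction required")
    y = loglog_transform(signal, s0, delta_clip)
    H = _solver_matrix(basis, lambda_reg)
    return SHCoeffVector(coeffs=H @ y, domain=LOGLOG_SIGNAL)


@dataclass
class BootstrapConfig:
    """Residual-bootstrap settings: number of refits and RNG seed."""

    n_samples: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def bootstrap_mean_odf(signal: np.ndarray, s0: float, basis: SHBasis,
                       transform: CSATransform, cfg: BootstrapConfig,
                       lambda_reg: float = 0.006,
                       delta_clip: float = 1e-3) -> SHCoeffVector:
    """Residual-bootstrap mean ODF for one voxel.

    Fits once, resamples the double-log residuals with replacement
    ``cfg.n_samples`` times, refits, applies the CSA transform to each
    replicate and returns the coefficient-wise mean.
    """
    mean = bootstrap_mean_odf_field(np.atleast_2d(signal),
                                    np.atleast_1d(float(s0)), basis,
                                    transform, cfg, lambda_reg, delta_clip)
    return SHCoeffVector(coeffs=mean[0], domain=ODF)


def bootstrap_mean_odf_field(signals: np.ndarray, s0: np.ndarray,
                             basis: SHBasis, transform: CSATransform,
                             cfg: BootstrapConfig,
                             lambda_reg: float = 0.006,
                             delta_clip: float = 1e-3) -> np.ndarray:
    """Vectorized residual-bootstrap mean ODF over many voxels.

    Parameters
    ----------
    signals : (V, N) per-voxel shell signal
    s0 : (V,) per-voxel b=0 signal

    Returns
    -------
    (V, R) mean ODF coefficients.
    """
    signals = np.asarray(signals, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    y = loglog_transform(signals, s0[:, None], delta_clip)  # (V, N)
    H = _solver_matrix(basis, lambda_reg)                    # (R, N)
    B = basis.design                                         # (N, R)
    c = y @ H.T                                              # (V, R)
    y_hat = c @ B.T
    resid = y - y_hat
    n_vox, n_dir = y.shape
    rng = np.random.default_rng(cfg.seed)
    acc = np.zeros_like(c)
    for _ in range(cfg.n_samples):
        idx = rng.integers(0, n_dir, size=(n_vox, n_dir))
        y_b = y_hat + np.take_along_axis(resid, idx, axis=1)
        acc += csa_transform_array(y_b @ H.T, transform)
    return acc / cfg.n_samples


# ---------------------------------------------------------------------------
# Diffusion tensor and FA
# ---------------------------------------------------------------------------

@dataclass
class TensorFit:
    """Single-voxel diffusion tensor with eigensystem and FA."""

    D: np.ndarray            # (3, 3) mm^2/s
    eigenvalues: np.ndarray  # descending, clamped at 0
    e1: np.ndarray           # principal eigenvector, unit
    fa: float


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2 * sum((l - mean)^2) / sum(l^2)); 0 for a null tensor."""
    evals = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - mean) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, np.clip(fa, 0.0, 1.0), 0.0)


def _tensor_design(scheme: GradientScheme) -> np.ndarray:
    """Rows -b * [gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz] at the b>0 volumes."""
    g = scheme.directions
    b = scheme.bvals[scheme.dwi_mask]
    return -b[:, None] * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def _vec_to_tensor(d: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz] -> (..., 3, 3) symmetric."""
    out = np.empty(d.shape[:-1] + (3, 3))
    out[..., 0, 0] = d[..., 0]
    out[..., 1, 1] = d[..., 1]
    out[..., 2, 2] = d[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
    return out


def fit_tensor(signal: np.ndarray, s0: float,
               scheme: GradientScheme) -> TensorFit:
    """Log-linear LS fit of ln(S/S0) = -b g^T D g for one voxel.

    Negative eigenvalues are clamped to 0 before the FA computation.
    """
    X = _tensor_design(scheme)
    if X.shape[0] < 6 or np.linalg.matrix_rank(X) < 6:
        raise ValueError("tensor fit needs >= 6 non-collinear directions")
    ratio = np.clip(np.asarray(signal, dtype=float) / float(s0), 1e-10, None)
    y = np.log(ratio)
    d, *_ = np.linalg.lstsq(X, y, rcond=None)
    D = _vec_to_tensor(d)
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    clamped = np.clip(evals, 0.0, None)
    if np.any(evals < 0):
        log.debug("negative tensor eigenvalue clamped (min %.3e)", evals.min())
    return TensorFit(D=D, eigenvalues=clamped, e1=evecs[:, 0],
                     fa=float(fa_from_eigenvalues(clamped)))


def fit_tensor_field(signals: np.ndarray, s0: np.ndarray,
                     scheme: GradientScheme
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized tensor fit over voxels.

    Parameters
    ----------
    signals : (V, N) shell signal; s0 : (V,)

    Returns
    -------
    fa : (V,); e1 : (V, 3) principal eigenvectors; evals : (V, 3) descending.
    """
    X = _tensor_design(scheme)
    if X.shape[0] < 6 or np.linalg.matrix_rank(X) < 6:
        raise ValueError("tensor fit needs >= 6 non-collinear directions")
    pinv = np.linalg.pinv(X)
    ratio = np.clip(np.asarray(signals, dtype=float)
                    / np.asarray(s0, dtype=float)[:, None], 1e-10, None)
    d = np.log(ratio) @ pinv.T
    D = _vec_to_tensor(d)
    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = evals[:, ::-1]
    e1 = evecs[:, :, ::-1][:, :, 0]
    return fa_from_eigenvalues(evals), e1, np.clip(evals, 0.0, None)


def fa_map(dwi, scheme: GradientScheme, mask=None) -> np.ndarray:
    """Voxel-wise FA volume from a DWIVolume (0 outside the mask)."""
    grid = mask.grid if mask is not None else np.ones(dwi.shape, dtype=bool)
    signals = dwi.data[grid][:, scheme.dwi_mask]
    s0 = dwi.s0[grid]
    fa, _, _ = fit_tensor_field(signals, s0, scheme)
    out = np.zeros(dwi.shape)
    out[grid] = fa
    return out


# ---------------------------------------------------------------------------
# Quadrature utility (used for normalization checks and oracles)
# ---------------------------------------------------------------------------

def sphere_quadrature(n_theta: int = 64, n_phi: int = 128
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre x uniform-azimuth product quadrature on the sphere.

    Exact for band-limited (spherical-harmonic) integrands up to high order.
    Returns (points (M, 3), weights (M,)) with weights summing to 4*pi.
    """
    x, w = np.polynomial.legendre.leggauss(n_theta)  # x = cos(theta)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    ct, ph = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    pts = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=-1)
    wts = np.broadcast_to(w[:, None], ct.shape) * (2.0 * np.pi / n_phi)
    return pts.reshape(-1, 3), wts.ravel()
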