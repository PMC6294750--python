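"""Per-voxel diffusion tensor estimation and derived maps.

The fit is ordinary log-linear least squares of
``log S(g) = log S0 - b g^T D g`` per masked voxel — deterministic, exact on
noise-free single-tensor signal, and adequate at the SNR of muscle DTI.
Negative eigenvalues are clamped to zero and the voxel flagged rather than
refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import DWIVolume, LabelMask

__all__ = [
    "TensorField",
    "fit_tensor",
    "fractional_anisotropy",
    "principal_direction",
    "color_fa_map",
    "measure_snr",
]

# Rayleigh std of |complex Gaussian| relative to the per-channel sigma
_RAYLEIGH_STD = float(np.sqrt(2.0 - np.pi / 2.0))


@dataclass
class TensorField:
    """Eigen-system, FA and validity of a fitted tensor volume."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3) mm^2/s
    s0_map: np.ndarray  # (nx, ny, nz)
    eigenvalues: np.ndarray  # (nx, ny, nz, 3) sorted descending
    eigenvectors: np.ndarray  # (nx, ny, nz, 3, 3); [..., :, m] pairs with eigenvalue m
    fa_map: np.ndarray  # (nx, ny, nz) in [0, 1]; 0 where invalid
    valid_mask: np.ndarray  # (nx, ny, nz) bool
    clamped_mask: np.ndarray  # voxels whose negative eigenvalues were clamped
    affine: np.ndarray

    @property
    def shape(self):
        return self.fa_map.shape


def fractional_anisotropy(eigenvalues) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||; 0 for all-zero input."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < 0):
        raise ValueError("eigenvalues must be non-negative")
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(ev - mean, axis=-1)
    den = np.linalg.norm(ev, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def _design_matrix(gtab) -> np.ndarray:
    b = gtab.bvals
    g = gtab.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(dwi: DWIVolume, mask: LabelMask | None = None) -> TensorField:
    """Log-linear least-squares tensor fit over masked voxels.

    Voxels outside the mask, or with non-positive signal anywhere, are
    flagged invalid (FA reported as 0) rather than raising.
    """
    gtab = dwi.gtab
    if gtab.n_dwi < 6:
        raise ValueError("tensor fit needs at least 6 non-b0 directions")
    if gtab.n_b0 < 1:
        raise ValueError("tensor fit needs at least one b0 acquisition")

    shape = dwi.shape
    in_mask = np.ones(shape, dtype=bool) if mask is None else mask.binary()

    signal = dwi.data.reshape(-1, len(gtab))
    flat_mask = in_mask.ravel().copy()
    positive = np.all(signal > 0, axis=1)
    fit_rows = flat_mask & positive

    X = _design_matrix(gtab)
    pinv = np.linalg.pinv(X)

    coeffs = np.zeros((signal.shape[0], 7))
    if fit_rows.any():
        logs = np.log(signal[fit_rows])
        coeffs[fit_rows] = logs @ pinv.T

    D = np.zeros((signal.shape[0], 3, 3))
    D[:, 0, 0] = coeffs[:, 1]
    D[:, 1, 1] = coeffs[:, 2]
    D[:, 2, 2] = coeffs[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = coeffs[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = coeffs[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = coeffs[:, 6]

    evals = np.zeros((signal.shape[0], 3))
    evecs = np.zeros((signal.shape[0], 3, 3))
    if fit_rows.any():
        w, v = np.linalg.eigh(D[fit_rows])  # ascending
        w = w[:, ::-1]
        v = v[:, :, ::-1]
        evals[fit_rows] = w
        evecs[fit_rows] = v

    clamped = fit_rows & np.any(evals < 0, axis=1)
    evals = np.clip(evals, 0.0, None)

    fa = np.zeros(signal.shape[0])
    fa[fit_rows] = fractional_anisotropy(evals[fit_rows])

    return TensorField(
        tensors=D.reshape(*shape, 3, 3),
        s0_map=np.exp(coeffs[:, 0]).reshape(shape) * fit_rows.reshape(shape),
        eigenvalues=evals.reshape(*shape, 3),
        eigenvectors=evecs.reshape(*shape, 3, 3),
        fa_map=fa.reshape(shape),
        valid_mask=fit_rows.reshape(shape),
        clamped_mask=clamped.reshape(shape),
        affine=dwi.affine.copy(),
    )


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Antipodal representative: first nonzero component non-negative."""
    v = np.asarray(v, dtype=float)
    for c in v:
        if abs(c) > 1e-12:
            return v if c > 0 else -v
    return v


def principal_direction(tf: TensorField, voxel) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue, sign-canonicalized.

    A degenerate lambda1 = lambda2 resolves deterministically: ``eigh``
    orders repeated eigenvalues consistently and the antipodal sign rule
    fixes the representative.
    """
    i, j, k = voxel
    if not tf.valid_mask[i, j, k]:
        raise KeyError(f"voxel {tuple(voxel)} has no valid tensor fit")
    return _canonical_sign(tf.eigenvectors[i, j, k, :, 0])


def color_fa_map(tf: TensorField, convention: str = "ras") -> np.ndarray:
    """Direction-encoded color volume: RGB = FA * |principal direction|.

    ``convention="ras"`` maps R <- |x| (right-left), G <- |y|
    (antero-posterior), B <- |z| (cranio-caudal). An alternative
    ``"ap-red"`` swaps red and green (both axis assignments are in
    circulation; the mapping is configurable for that reason).
    """
    pd = tf.eigenvectors[..., :, 0]
    rgb = tf.fa_map[..., None] * np.abs(pd)
    rgb = np.where(tf.valid_mask[..., None], rgb, 0.0)
    if convention == "ras":
        return rgb
    if convention == "ap-red":
        return rgb[..., [1, 0, 2]]
    raise ValueError(f"unknown color convention {convention!r}")


def measure_snr(
    dwi: DWIVolume,
    tissue_roi: LabelMask,
    background_roi: LabelMask,
    correction: str = "rayleigh",
) -> float:
    """b0 SNR: mean over a tissue ROI / noise std from a background ROI.

    Multiple b0 volumes are averaged first. In a magnitude image the
    signal-free background is Rayleigh distributed, so its raw std
    understates the per-channel noise sigma by sqrt(2 - pi/2) ~ 0.655;
    the default corrects for this so the estimate is the per-channel SNR.
    ``correction="none"`` returns the literal ratio of tissue mean to raw
    background std.
    """
    tissue = tissue_roi.binary()
    background = background_roi.binary()
    if not tissue.any() or not background.any():
        raise ValueError("both ROIs must be non-empty")
    b0 = dwi.b0_image()
    mean_tissue = float(b0[tissue].mean())
    std_bg = float(b0[background].std())
    if correction == "rayleigh":
        std_bg /= _RAYLEIGH_STD
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    if std_bg == 0:
        warnings.warn("background ROI has zero std; SNR undefined, reporting inf")
        return np.inf if mean_tissue > 0 else 0.0
    return mean_tissue / std_bg
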