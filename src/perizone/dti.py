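"""Ordinary log-linear diffusion tensor estimation (FA and MD).

The tensor is fitted to the b = 0 and b = 1000 s/mm^2 volumes only, by
ordinary least squares on the log signal:

    ln S(g, b) = ln S0 - b * g^T D g

which is linear in the six unique tensor elements plus ln S0.  Higher
shells, when present, are ignored for DTI.  Diffusivities are in um^2/ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import IdentifiabilityError
from .scheme import AcquisitionScheme

__all__ = ["TensorMap", "fit_tensor", "fa_md", "design_matrix",
           "fa_from_eigenvalues", "single_voxel_tensor"]

log = logging.getLogger(__name__)

_DTI_MAX_B = 1000.0  # s/mm^2; shells above this are excluded from tensor fitting


def design_matrix(bvals_ms: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear DTI design matrix.

    Columns: [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]; b in ms/um^2 so the
    recovered tensor is in um^2/ms.
    """
    b = np.asarray(bvals_ms, float)
    g = np.asarray(bvecs, float)
    X = np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])
    return X


@dataclass
class TensorMap:
    """Per-voxel tensor eigensystem on a 3D grid.

    ``eigenvalues`` are sorted descending (lam1 >= lam2 >= lam3) and are NaN
    where ``valid`` is False.
    """

    eigenvalues: np.ndarray       # (x, y, z, 3), um^2/ms
    valid: np.ndarray             # (x, y, z) bool
    tensors: np.ndarray | None = field(default=None, repr=False)  # (x, y, z, 3, 3)
    n_negative_clipped: int = 0


def _select_dti_volumes(scheme: AcquisitionScheme) -> np.ndarray:
    bvals = scheme.bvals()
    keep = bvals <= _DTI_MAX_B
    nonzero = sorted(set(bvals[keep][bvals[keep] > 0]))
    if len(nonzero) != 1:
        raise IdentifiabilityError(
            f"DTI fit needs exactly one nonzero shell at or below {_DTI_MAX_B:g} s/mm^2, "
            f"found {nonzero}")
    return keep


def fit_tensor(data: np.ndarray, scheme: AcquisitionScheme,
               mask: np.ndarray | None = None, keep_tensors: bool = False) -> TensorMap:
    """Ordinary log-linear tensor fit over a 4D volume.

    Parameters
    ----------
    data : ndarray (x, y, z, n_volumes)
        Diffusion-weighted signal.
    scheme : AcquisitionScheme
        Must contain b=0 and exactly one nonzero shell <= 1000 s/mm^2;
        b=2000 volumes are ignored.
    mask : bool ndarray, optional
        Voxels to fit; defaults to all.

    Voxels with any non-positive selected signal are flagged invalid rather
    than aborting the fit.
    """
    if scheme.directions_per_shell < 6:
        raise IdentifiabilityError("fewer than 6 gradient directions")
    keep = _select_dti_volumes(scheme)
    X = design_matrix(scheme.bvals()[keep] / 1000.0, scheme.bvecs()[keep])
    pinv = np.linalg.pinv(X)

    shape3 = data.shape[:3]
    if mask is None:
        mask = np.ones(shape3, bool)
    vox = data[mask][:, keep]  # (n_vox, n_kept)

    ok = np.all(vox > 0, axis=1)
    coef = np.full((vox.shape[0], 7), np.nan)
    if ok.any():
        coef[ok] = (pinv @ np.log(vox[ok]).T).T

    D = np.zeros((vox.shape[0], 3, 3))
    D[:, 0, 0] = coef[:, 1]
    D[:, 1, 1] = coef[:, 2]
    D[:, 2, 2] = coef[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = coef[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = coef[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = coef[:, 6]

    evals = np.full((vox.shape[0], 3), np.nan)
    if ok.any():
        w = np.linalg.eigvalsh(D[ok])          # ascending
        evals[ok] = w[:, ::-1]                  # descending

    eig_map = np.full(shape3 + (3,), np.nan)
    eig_map[mask] = evals
    valid_map = np.zeros(shape3, bool)
    valid_map[mask] = ok

    tens_map = None
    if keep_tensors:
        tens_map = np.full(shape3 + (3, 3), np.nan)
        tens_map[mask] = np.where(ok[:, None, None], D, np.nan)
    return TensorMap(eigenvalues=eig_map, valid=valid_map, tensors=tens_map)


def fa_md(tensor_map: TensorMap) -> tuple[np.ndarray, np.ndarray]:
    """FA and MD maps from a fitted tensor.

    MD = (lam1+lam2+lam3)/3 from the raw eigenvalues.  For FA, negative
    eigenvalues are clipped to zero first (conventional; the clip count is
    recorded on the TensorMap and logged).  An all-zero tensor has FA = 0.
    Invalid voxels are NaN in both maps.
    """
    lam = tensor_map.eigenvalues
    with np.errstate(invalid="ignore"):
        md = lam.sum(axis=-1) / 3.0

    clipped = np.clip(lam, 0.0, None)
    n_clip = int(np.sum((lam < 0) & tensor_map.valid[..., None]))
    tensor_map.n_negative_clipped = n_clip
    if n_clip:
        log.info("FA computation clipped %d negative eigenvalues to zero", n_clip)

    mbar = clipped.mean(axis=-1)
    num = np.sum((clipped - mbar[..., None]) ** 2, axis=-1)
    den = np.sum(clipped ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    fa = np.where(tensor_map.valid, fa, np.nan)
    md = np.where(tensor_map.valid, md, np.nan)
    return fa, md


def fa_from_eigenvalues(lam: np.ndarray) -> float:
    """FA of one eigenvalue triple (negatives clipped to zero)."""
    lam = np.clip(np.asarray(lam, float), 0.0, None)
    den = np.sum(lam ** 2)
    if den == 0:
        return 0.0
    mbar = lam.mean()
    return float(np.sqrt(1.5 * np.sum((lam - mbar) ** 2) / den))


def single_voxel_tensor(signal: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Eigenvalues (descending) of the log-linear tensor fit of one voxel."""
    tm = fit_tensor(signal.reshape(1, 1, 1, -1), scheme)
    return tm.eigenvalues[0, 0, 0]
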