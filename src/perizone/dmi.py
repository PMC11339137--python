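"""Three-compartment diffusion-microstructure estimation from two-shell data.

Model
-----
Each voxel is a mixture of three water pools:

* an intra-axonal "stick" compartment (volume fraction ``V_intra``) in which
  water diffuses only along the local axon orientation with axial
  diffusivity ``D_ax_intra``;
* an extra-axonal "zeppelin" compartment (``V_extra = 1 - V_intra - V_csf``)
  with axial diffusivity ``D_ax_extra`` and radial diffusivity
  ``D_rad_extra`` (tied to the axial value by a tortuosity closure unless
  given explicitly);
* a free-fluid "ball" compartment (``V_csf``) with isotropic diffusivity
  fixed at 3 um^2/ms.

Fitting uses rotation-invariant features of the signal rather than the raw
directional measurements, so the estimates do not depend on the fiber
orientation.  Per shell, two features are extracted from the *squared*
magnitude signal: its spherical mean and its l = 2 spherical-harmonic
power.  Second moments are used because magnitude (Rician) noise is then
exactly removable at any SNR — E[M^2] = S^2 + 2 sigma^2 — whereas
first-moment (mean-signal) corrections retain bias at the low per-volume
SNR of the b = 2000 s/mm^2 shell.  Two shells give four features for the
four free parameters; spherical means alone (two numbers) would leave the
model underdetermined.

The squared signal of an axially symmetric mixture is again a mixture of
the same exponential family (pairwise compartment products), so the
forward model stays closed-form.  For a kernel K(t) = exp(-x t^2) with
t = cos(angle to fiber):

    I0(x) = int_0^1 K dt       = sqrt(pi/(4x)) * erf(sqrt(x))
    I2(x) = int_0^1 t^2 K dt   = (I0(x) - exp(-x)) / (2x)
    J2(x) = int_0^1 P2(t) K dt = (3*I2(x) - I0(x)) / 2

A compartment pair (i, j) contributes V_i V_j exp(-b(Dr_i + Dr_j)) times
I0(b(Dx_i + Dx_j)) to the spherical mean of S^2 (Dx = axial minus radial
diffusivity), and the analogous J2 term to its l = 2 coefficient
(Funk-Hecke); the l = 2 power of an axially symmetric function with SH
coefficient lambda_2 is |lambda_2| * sqrt(5/(4 pi)).

Estimation is Bayesian with a uniform prior over a bounded parameter grid
restricted to the biophysical branch D_ax_intra >= D_ax_extra (without
which the stick/zeppelin mixture admits well-known swapped-compartment
mimics): a Gaussian likelihood of the observed features is evaluated at
every grid point.  With ``refine`` (default) a projected Gauss-Newton
polish from the best cell restores continuous-parameter accuracy lost to
grid discretization (exact on noise-free input); without it the grid
posterior mean is returned.  Both stages are deterministic given
identical inputs and grid.

The arithmetic spherical mean (powder average) of the plain signal and
its closed-form forward model are also provided (`spherical_mean`,
`powder_forward`); they are the classical rotation-invariant summary and
are used for consistency checks of the synthesized signal.

All b-values are in ms/um^2 internally (b = 1000 s/mm^2 is 1 ms/um^2);
diffusivities in um^2/ms.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .errors import IdentifiabilityError
from .scheme import AcquisitionScheme

__all__ = [
    "D_FREE_WATER", "ShellMeans", "ShellFeatures", "DMIMaps", "ParameterGrid",
    "powder_forward", "sh_power_forward", "rms_powder_forward",
    "rms_sh_power_forward", "rms_sh4_power_forward", "model_features",
    "tortuosity_drad",
    "spherical_mean", "shell_features", "build_grid", "fit_features",
    "fit_volume", "fit_zones", "fit_voxel",
]

log = logging.getLogger(__name__)

D_FREE_WATER = 3.0  # um^2/ms, fixed free-fluid diffusivity

_SERIES_X = 1e-4    # switch to series expansions below this argument


def _i0(x):
    """int_0^1 exp(-x t^2) dt, elementwise, stable at x -> 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SERIES_X
    xs = np.where(small, 1.0, x)
    out = 0.5 * np.sqrt(np.pi / xs) * special.erf(np.sqrt(xs))
    series = 1.0 - x / 3.0 + x * x / 10.0
    return np.where(small, series, out)


def _i2(x):
    """int_0^1 t^2 exp(-x t^2) dt."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SERIES_X
    xs = np.where(small, 1.0, x)
    out = (_i0(xs) - np.exp(-xs)) / (2.0 * xs)
    series = 1.0 / 3.0 - x / 5.0 + x * x / 14.0
    return np.where(small, series, out)


def _j2(x):
    """int_0^1 P2(t) exp(-x t^2) dt  (negative for x > 0)."""
    return (3.0 * _i2(x) - _i0(x)) / 2.0


def _i4(x):
    """int_0^1 t^4 exp(-x t^2) dt."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-3
    xs = np.where(small, 1.0, x)
    out = (_i0(xs) - np.exp(-xs) + xs * _i2(xs) - xs * np.exp(-xs)) / (2.0 * xs * xs)
    series = 0.2 - x / 7.0 + x * x / 18.0
    return np.where(small, series, out)


def _j4(x):
    """int_0^1 P4(t) exp(-x t^2) dt."""
    return (35.0 * _i4(x) - 30.0 * _i2(x) + 3.0 * _i0(x)) / 8.0


def tortuosity_drad(v_intra, v_csf, d_ax_extra):
    """Extra-axonal radial diffusivity via the tortuosity closure.

    D_rad = D_ax * (1 - V_intra / (V_intra + V_extra)); falls back to D_ax
    when the tissue fraction vanishes (pure free fluid).
    """
    v_intra = np.asarray(v_intra, float)
    v_csf = np.asarray(v_csf, float)
    d_ax_extra = np.asarray(d_ax_extra, float)
    tissue = 1.0 - v_csf
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tissue > 1e-12, v_intra / np.where(tissue > 1e-12, tissue, 1.0), 0.0)
    return d_ax_extra * (1.0 - frac)


def _compartments(v_intra, v_csf, d_ax_intra, d_ax_extra, d_rad_extra):
    """(fraction, radial D, axial-minus-radial D) triple per compartment."""
    v_intra = np.asarray(v_intra, float)
    v_csf = np.asarray(v_csf, float)
    d_ax_intra = np.asarray(d_ax_intra, float)
    d_ax_extra = np.asarray(d_ax_extra, float)
    if d_rad_extra is None:
        d_rad_extra = tortuosity_drad(v_intra, v_csf, d_ax_extra)
    d_rad_extra = np.asarray(d_rad_extra, float)
    v_extra = 1.0 - v_intra - v_csf
    zero = np.zeros(np.broadcast(v_intra, v_csf).shape)
    return ((v_csf, D_FREE_WATER + zero, zero),
            (v_intra, zero, d_ax_intra + zero),
            (v_extra, d_rad_extra, d_ax_extra - d_rad_extra))


def _check_b(b):
    b = np.asarray(b, float)
    if np.any(b < 0):
        raise ValueError("b-value must be non-negative")
    return b


def powder_forward(v_intra, v_csf, d_ax_intra, d_ax_extra, b, d_rad_extra=None):
    """Spherical-mean (powder-average) normalized signal S_bar(b)/S0.

    Parameters broadcast; ``b`` in ms/um^2.  ``d_rad_extra=None`` applies
    the tortuosity closure.
    """
    b = _check_b(b)
    comps = _compartments(v_intra, v_csf, d_ax_intra, d_ax_extra, d_rad_extra)
    return sum(v * np.exp(-b * dr) * _i0(b * dx) for v, dr, dx in comps)


def sh_power_forward(v_intra, v_csf, d_ax_intra, d_ax_extra, b, d_rad_extra=None):
    """l = 2 spherical-harmonic power of S/S0: sqrt(sum_m c_2m^2)."""
    b = _check_b(b)
    comps = _compartments(v_intra, v_csf, d_ax_intra, d_ax_extra, d_rad_extra)
    total = sum(v * np.exp(-b * dr) * _j2(b * dx) for v, dr, dx in comps)
    return 2.0 * np.sqrt(5.0 * np.pi) * np.abs(total)


def rms_powder_forward(v_intra, v_csf, d_ax_intra, d_ax_extra, b, d_rad_extra=None):
    """Root of the spherical mean of (S/S0)^2 (noise-robust powder feature)."""
    b = _check_b(b)
    comps = _compartments(v_intra, v_csf, d_ax_intra, d_ax_extra, d_rad_extra)
    total = 0.0
    for vi_, dri, dxi in comps:
        for vj_, drj, dxj in comps:
            total = total + vi_ * vj_ * np.exp(-b * (dri + drj)) * _i0(b * (dxi + dxj))
    return np.sqrt(np.clip(total, 0.0, None))


def rms_sh_power_forward(v_intra, v_csf, d_ax_intra, d_ax_extra, b, d_rad_extra=None):
    """l = 2 spherical-harmonic power of (S/S0)^2: sqrt(sum_m c_2m^2)."""
    b = _check_b(b)
    comps = _compartments(v_intra, v_csf, d_ax_intra, d_ax_extra, d_rad_extra)
    total = 0.0
    for vi_, dri, dxi in comps:
        for vj_, drj, dxj in comps:
            total = total + vi_ * vj_ * np.exp(-b * (dri + drj)) * _j2(b * (dxi + dxj))
    return 2.0 * np.sqrt(5.0 * np.pi) * np.abs(total)


def rms_sh4_power_forward(v_intra, v_csf, d_ax_intra, d_ax_extra, b, d_rad_extra=None):
    """l = 4 spherical-harmonic power of (S/S0)^2: sqrt(sum_m c_4m^2)."""
    b = _check_b(b)
    comps = _compartments(v_intra, v_csf, d_ax_intra, d_ax_extra, d_rad_extra)
    total = 0.0
    for vi_, dri, dxi in comps:
        for vj_, drj, dxj in comps:
            total = total + vi_ * vj_ * np.exp(-b * (dri + drj)) * _j4(b * (dxi + dxj))
    return 6.0 * np.sqrt(np.pi) * np.abs(total)


def model_features(v_intra, v_csf, d_ax_intra, d_ax_extra, b_shells, d_rad_extra=None):
    """The fit's feature map per shell: rms, l=2 power, l=4 power of (S/S0)^2."""
    args = (v_intra, v_csf, d_ax_intra, d_ax_extra)
    feats = [rms_powder_forward(*args, b, d_rad_extra) for b in b_shells]
    feats += [rms_sh_power_forward(*args, b, d_rad_extra) for b in b_shells]
    feats += [rms_sh4_power_forward(*args, b, d_rad_extra) for b in b_shells]
    return np.stack([np.asarray(f, float) for f in feats])


# ---------------------------------------------------------------------------
# Real spherical harmonics (orthonormal) for the measured l=2 power
# ---------------------------------------------------------------------------

def _real_sh_basis(dirs: np.ndarray, lmax: int = 4) -> tuple[np.ndarray, list[int]]:
    """Real orthonormal SH design matrix for even l <= lmax.

    Returns (n_dirs, n_coef) matrix and the degree l of each column.
    """
    x, y, z = dirs.T
    theta = np.arccos(np.clip(z, -1, 1))
    phi = np.arctan2(y, x)
    cols, degs = [], []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ylm = special.sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * (-1) ** m * ylm.imag)
            elif m == 0:
                cols.append(ylm.real)
            else:
                cols.append(np.sqrt(2.0) * (-1) ** m * ylm.real)
            degs.append(l)
    return np.column_stack(cols), degs


@functools.lru_cache(maxsize=8)
def _sh_fit_operator(dirs_key: tuple, lmax: int = 4):
    dirs = np.array(dirs_key).reshape(-1, 3)
    Y, degs = _real_sh_basis(dirs, lmax)
    pinv = np.linalg.pinv(Y)
    l2_rows = [i for i, l in enumerate(degs) if l == 2]
    l4_rows = [i for i, l in enumerate(degs) if l == 4]
    # traces of the l-blocks of (Y^T Y)^-1: noise variance multipliers of
    # the corresponding SH powers
    cov = np.linalg.inv(Y.T @ Y)
    tr2 = float(np.trace(cov[np.ix_(l2_rows, l2_rows)]))
    tr4 = float(np.trace(cov[np.ix_(l4_rows, l4_rows)]))
    return pinv, l2_rows, l4_rows, tr2, tr4


# ---------------------------------------------------------------------------
# Feature extraction from measured volumes
# ---------------------------------------------------------------------------

@dataclass
class ShellMeans:
    """Arithmetic per-shell spherical means of S/S0 on the flattened mask."""

    b_shells: np.ndarray          # ms/um^2
    means: np.ndarray             # (n_shells, n_voxels)
    valid: np.ndarray
    mask: np.ndarray = field(repr=False)
    shape: tuple = ()


def spherical_mean(data: np.ndarray, scheme: AcquisitionScheme,
                   mask: np.ndarray | None = None) -> ShellMeans:
    """Arithmetic mean of S/S0 over the directions of each shell.

    S0 is the mean of the b=0 volumes; voxels with S0 <= 0 are invalid.
    """
    if len(scheme.nonzero_shells) < 2:
        raise IdentifiabilityError("microstructure fit requires at least two nonzero shells")
    shape3 = data.shape[:3]
    if mask is None:
        mask = np.ones(shape3, bool)
    vox = data[mask].astype(float)
    s0 = vox[:, scheme.b0_slice].mean(axis=1)
    valid = s0 > 0
    s0_safe = np.where(valid, s0, 1.0)
    means = np.stack([(vox[:, sl] / s0_safe[:, None]).mean(axis=1)
                      for sl in scheme.shell_slices().values()])
    means[:, ~valid] = np.nan
    return ShellMeans(b_shells=scheme.shells_ms_um2, means=means, valid=valid,
                      mask=mask, shape=shape3)


@dataclass
class ShellFeatures:
    """Noise-robust rotation-invariant per-voxel features.

    ``rms`` is sqrt of the debiased spherical mean of (M/S0)^2 per shell;
    ``p2``/``p4`` the square roots of the debiased l=2 and l=4 SH powers
    of (M/S0)^2.
    Shapes (n_shells, n_voxels); b-values in ms/um^2.  ``sigma_vol`` is
    the estimated per-volume noise SD as a fraction of S0 (single
    representative value for the masked region).
    """

    b_shells: np.ndarray
    rms: np.ndarray
    p2: np.ndarray
    p4: np.ndarray
    n_dirs: int
    sigma_vol: float
    valid: np.ndarray
    mask: np.ndarray = field(repr=False)
    shape: tuple = ()
    tr2: float = 1.083  # traces of the l-blocks of (Y^T Y)^-1; 58-direction defaults
    tr4: float = 1.983


def _squared_normalized(data: np.ndarray, scheme: AcquisitionScheme,
                        mask: np.ndarray, sigma: float | None,
                        rician_correct: bool):
    """Noise-floor-debiased squared signal (M^2 - floor) / S0_sq per voxel.

    Returns (sq_by_shell list of (nv, ndir), s0_sq_safe, valid, sigma).
    The floor is 2 sigma^2 under Rician noise (E[M^2] = S^2 + 2 sigma^2,
    exact at any SNR), sigma^2 under plain Gaussian noise; the squared
    b=0 reference is debiased the same way.  ``sigma`` defaults to the
    spread of the b=0 volumes.
    """
    vox = data[mask].astype(float)                      # (nv, nvol)
    b0 = vox[:, scheme.b0_slice]
    if sigma is None:
        if scheme.n_b0 >= 3:
            valid0 = b0.mean(axis=1) > 0
            per_vox = b0.std(axis=1, ddof=1)
            sigma = float(np.median(per_vox[valid0])) if valid0.any() else 0.0
        else:
            sigma = 0.0
    floor = (2.0 if rician_correct else 1.0) * sigma ** 2
    s0_sq = np.clip((b0 ** 2).mean(axis=1) - floor, 0.0, None)
    valid = s0_sq > 0
    s0_sq_safe = np.where(valid, s0_sq, 1.0)
    sq_by_shell = [(vox[:, sl] ** 2 - floor) / s0_sq_safe[:, None]
                   for sl in scheme.shell_slices().values()]
    return sq_by_shell, s0_sq_safe, valid, sigma


def shell_features(data: np.ndarray, scheme: AcquisitionScheme,
                   mask: np.ndarray | None = None, sigma: float | None = None,
                   rician_correct: bool = True) -> ShellFeatures:
    """Second-moment rotation-invariant features of the measured signal.

    The squared magnitude signal is debiased by its exact noise floor
    (2 sigma^2 under Rician noise, sigma^2 under plain Gaussian noise,
    selected by ``rician_correct``); the squared b=0 reference S0^2 is
    debiased the same way.  When ``sigma`` (absolute noise SD) is not
    given it is estimated from the spread of the b=0 volumes.  Voxels
    with S0 <= 0 are flagged invalid.
    """
    if len(scheme.nonzero_shells) < 2:
        raise IdentifiabilityError("microstructure fit requires at least two nonzero shells")
    shape3 = data.shape[:3]
    if mask is None:
        mask = np.ones(shape3, bool)
    sq_by_shell, s0_sq_safe, valid, sigma = _squared_normalized(
        data, scheme, mask, sigma, rician_correct)

    pinv, l2_rows, l4_rows, tr2, tr4 = _sh_fit_operator(tuple(scheme.directions.ravel()))

    n_sh = len(scheme.nonzero_shells)
    nv = s0_sq_safe.shape[0]
    rms = np.zeros((n_sh, nv))
    p2 = np.zeros((n_sh, nv))
    p4 = np.zeros((n_sh, nv))
    for k, sq in enumerate(sq_by_shell):                       # (nv, ndir)
        rms[k] = np.sqrt(np.clip(sq.mean(axis=1), 0.0, None))
        coef = sq @ pinv.T
        pow2 = np.sum(coef[:, l2_rows] ** 2, axis=1)
        pow4 = np.sum(coef[:, l4_rows] ** 2, axis=1)
        if sigma > 0:
            # var of M^2 under Rician noise: 4 S^2 sigma^2 + 4 sigma^4
            s_sq = np.clip(sq.mean(axis=1), 0.0, None) * s0_sq_safe
            var_sq = (4.0 * s_sq * sigma ** 2 + 4.0 * sigma ** 4) / s0_sq_safe ** 2
            pow2 = np.clip(pow2 - tr2 * var_sq, 0.0, None)
            pow4 = np.clip(pow4 - tr4 * var_sq, 0.0, None)
        p2[k] = np.sqrt(pow2)
        p4[k] = np.sqrt(pow4)

    sigma_vol = (float(sigma / np.median(np.sqrt(s0_sq_safe[valid])))
                 if valid.any() and sigma > 0 else 0.0)
    return ShellFeatures(b_shells=scheme.shells_ms_um2, rms=rms, p2=p2, p4=p4,
                         n_dirs=scheme.directions_per_shell, sigma_vol=sigma_vol,
                         valid=valid, mask=mask, shape=shape3, tr2=tr2, tr4=tr4)


# ---------------------------------------------------------------------------
# Grid posterior fit
# ---------------------------------------------------------------------------

GRID_PRESETS = {
    # fraction step, diffusivity step
    "fine": (0.02, 0.05),
    "coarse": (0.04, 0.10),
}


@dataclass
class ParameterGrid:
    """Precomputed forward features on a bounded parameter lattice."""

    params: np.ndarray        # (n_grid, 4): v_intra, v_csf, d_ax_intra, d_ax_extra
    features: np.ndarray      # (n_grid, 3 * n_shells), float32
    b_shells: tuple
    frac_step: float
    diff_step: float


@functools.lru_cache(maxsize=4)
def _build_grid_cached(preset: str, b_key: tuple, d_max: float) -> ParameterGrid:
    hf, hd = GRID_PRESETS[preset]
    levels = np.round(np.arange(0.0, 1.0 + hf / 2, hf), 10)
    vi, vc = np.meshgrid(levels, levels, indexing="ij")
    keep = (vi + vc) <= 1.0 + 1e-12
    vi, vc = vi[keep], vc[keep]
    dd = np.round(np.arange(hd, d_max + hd / 2, hd), 10)
    dai, dae = np.meshgrid(dd, dd, indexing="ij")
    dai, dae = dai.ravel(), dae.ravel()
    # biophysical branch selection: axial intra-axonal diffusivity is not
    # smaller than the (hindered) extra-axonal one; without this the
    # stick/zeppelin mixture admits well-known mimic solutions with the
    # two compartments swapped.
    branch = dai >= dae
    dai, dae = dai[branch], dae[branch]

    nf, nd = vi.size, dai.size
    VI = np.repeat(vi, nd)
    VC = np.repeat(vc, nd)
    DAI = np.tile(dai, nf)
    DAE = np.tile(dae, nf)
    feats = model_features(VI, VC, DAI, DAE, b_key).T.astype(np.float32)
    params = np.column_stack([VI, VC, DAI, DAE]).astype(np.float32)
    log.info("built %s DMI grid: %d points", preset, params.shape[0])
    return ParameterGrid(params=params, features=feats, b_shells=b_key,
                         frac_step=hf, diff_step=hd)


def build_grid(preset: str = "coarse", b_shells=(1.0, 2.0),
               d_max: float = D_FREE_WATER) -> ParameterGrid:
    """Parameter lattice for the posterior fit (memoized per scheme/preset)."""
    if preset not in GRID_PRESETS:
        raise ValueError(f"unknown grid preset {preset!r}")
    return _build_grid_cached(preset, tuple(float(b) for b in b_shells), float(d_max))


@dataclass
class DMIMaps:
    """Fitted microstructure maps on the original 3D grid (NaN outside mask)."""

    v_intra: np.ndarray
    v_csf: np.ndarray
    d_ax_intra: np.ndarray
    d_ax_extra: np.ndarray
    residual: np.ndarray     # min chi^2 over the grid (fit quality)
    valid: np.ndarray

    @property
    def v_extra(self) -> np.ndarray:
        return 1.0 - self.v_intra - self.v_csf

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"v_intra": self.v_intra, "v_csf": self.v_csf,
                "d_ax_intra": self.d_ax_intra, "d_ax_extra": self.d_ax_extra}


_SIGMA_FLOOR = 2e-3   # fraction of S0; keeps the noise-free posterior finite
_RMS_VALID_RANGE = (0.0, 1.2)
_D_LOWER = 0.05       # um^2/ms, lower box bound for diffusivities in refinement


def _feature_sd(features: ShellFeatures) -> np.ndarray:
    """Per-feature Gaussian likelihood SDs [rms..., p2..., p4 powers...]."""
    n_sh = features.rms.shape[0]
    sig = max(features.sigma_vol, _SIGMA_FLOOR)
    sd_rms = sig / np.sqrt(features.n_dirs)
    sd_p2 = sig * np.sqrt(features.tr2 / 5.0)
    sd_p4 = sig * np.sqrt(features.tr4 / 9.0)
    return np.concatenate([np.full(n_sh, sd_rms), np.full(n_sh, sd_p2),
                           np.full(n_sh, sd_p4)])


def _resid_of(q: np.ndarray, Y: np.ndarray, b_shells, weights: np.ndarray,
              forward=None, cols=None) -> np.ndarray:
    """Weighted feature residual for reparametrized points q = (vi, u, dai, dae).

    ``forward(vi, vc, dai, dae, cols)`` may override the closed-form
    feature map (e.g. a discrete-sampling operator); ``cols`` identifies
    which voxel columns ``q`` refers to.
    """
    vi = q[:, 0]
    vc = q[:, 1] * (1.0 - vi)
    if forward is None:
        f = model_features(vi, vc, q[:, 2], q[:, 3], b_shells)   # (F, nv)
    else:
        f = forward(vi, vc, q[:, 2], q[:, 3], cols)
    return (f - Y) * weights[:, None]


def _refine_gauss_newton(start: np.ndarray, Y: np.ndarray, b_shells,
                         weights: np.ndarray, n_iter: int = 150,
                         forward=None, cols=None) -> np.ndarray:
    """Projected Levenberg-Marquardt polish of per-voxel estimates.

    ``start`` is (nv, 4) in (v_intra, v_csf, d_ax_intra, d_ax_extra); the
    simplex constraint is handled by reparametrizing v_csf = u * (1 -
    v_intra) with u in [0, 1], box bounds and the biophysical branch by
    projection.  Damping is per voxel and adaptive (divide on success,
    multiply on failure), which lets the iteration follow the long curved
    valleys of this stiff feature map; steps are accepted only when they
    reduce the weighted residual, so the result never fits worse than the
    start.
    """
    b_shells = tuple(float(b) for b in b_shells)

    def unpack(q):
        vi, u, dai, dae = q.T
        return vi, u * (1.0 - vi), dai, dae

    lo = np.array([0.0, 0.0, _D_LOWER, _D_LOWER])
    hi = np.array([0.999, 1.0, D_FREE_WATER, D_FREE_WATER])

    def project(q):
        q = np.clip(q, lo, hi)
        # stay on the biophysical branch d_ax_intra >= d_ax_extra
        q[:, 3] = np.minimum(q[:, 3], q[:, 2])
        return q

    q = start.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        q[:, 1] = np.clip(start[:, 1] / np.clip(1.0 - start[:, 0], 1e-9, None), 0.0, 1.0)
    q = project(q)

    nv = q.shape[0]
    if cols is None:
        cols = np.arange(nv)
    r = _resid_of(q, Y, b_shells, weights, forward, cols)
    cost = (r ** 2).sum(axis=0)
    h = 1e-6
    lam = np.full(nv, 1e-3)
    active = np.arange(nv)
    step_tol = 1e-7
    for _ in range(n_iter):
        if active.size == 0:
            break
        qa = q[active]
        ra = r[:, active]
        Ya = Y[:, active]
        ca = cols[active]
        J = np.empty((active.size, ra.shape[0], 4))
        for j in range(4):
            qp = qa.copy()
            qp[:, j] = np.clip(qp[:, j] + h, lo[j], hi[j])
            step = qp[:, j] - qa[:, j]
            step[step == 0] = h
            J[:, :, j] = ((_resid_of(qp, Ya, b_shells, weights, forward, ca) - ra) / step).T
        g = np.einsum("vfp,fv->vp", J, ra)
        H = np.einsum("vfp,vfq->vpq", J, J)
        diag = np.einsum("vpp->vp", H).copy()
        diag[diag < 1e-12] = 1e-12

        pending = np.arange(active.size)
        moved = np.zeros(active.size, bool)
        small_step = np.zeros(active.size, bool)
        for _try in range(6):
            if pending.size == 0:
                break
            sel = active[pending]
            Hd = H[pending] + (lam[sel][:, None] * diag[pending])[:, :, None] * np.eye(4)
            try:
                delta = -np.linalg.solve(Hd, g[pending][..., None])[..., 0]
            except np.linalg.LinAlgError:
                lam[sel] *= 10.0
                continue
            qn = project(q[sel] + delta)
            rn = _resid_of(qn, Y[:, sel], b_shells, weights, forward, cols[sel])
            costn = (rn ** 2).sum(axis=0)
            better = costn < cost[sel] - 1e-14
            acc = sel[better]
            q[acc] = qn[better]
            r[:, acc] = rn[:, better]
            cost[acc] = costn[better]
            lam[acc] = np.maximum(lam[acc] / 3.0, 1e-10)
            moved[pending[better]] = True
            small_step[pending[better]] = np.abs(delta[better]).max(axis=1) < step_tol
            lam[sel[~better]] *= 10.0
            pending = pending[~better]
        keep = moved & ~small_step
        active = active[keep]
    vi, vc, dai, dae = unpack(q)
    return np.column_stack([vi, vc, dai, dae]), cost


def fit_features(features: ShellFeatures, grid: ParameterGrid | None = None,
                 chunk: int = 256, refine: bool = True, forward=None,
                 n_starts: int = 4, n_iter: int = 150) -> DMIMaps:
    """Microstructure estimate for every masked voxel.

    Stage 1 evaluates a Gaussian likelihood of the observed features on the
    bounded parameter grid (uniform prior): rms features carry variance
    sigma_vol^2 / N_dirs, l=2 powers sigma_vol^2 * tr2 / 5 (a small
    variance floor keeps the posterior proper on noise-free input).  The
    best-fitting cell is recorded.  Stage 2 (``refine``, default) runs a
    projected Gauss-Newton polish from the best cell, which restores
    continuous-parameter accuracy lost to grid discretization; with
    ``refine=False`` the grid posterior mean is returned unmodified.
    """
    if grid is None:
        grid = build_grid("coarse", tuple(features.b_shells))
    n_sh = features.rms.shape[0]
    if 3 * n_sh != grid.features.shape[1]:
        raise ValueError("grid and features disagree on shell count")

    sd = _feature_sd(features)
    # cell ranking uses a discretization-aware variance so that candidate
    # basins are ordered by true feature proximity rather than by how
    # luckily the lattice happens to sample them
    disc = np.concatenate([
        np.full(n_sh, 0.2 * grid.frac_step + 0.03 * grid.diff_step),
        np.full(n_sh, 0.1 * grid.frac_step + 0.02 * grid.diff_step),
        np.full(n_sh, 0.05 * grid.frac_step + 0.01 * grid.diff_step)])
    sd_rank = np.sqrt(sd ** 2 + disc ** 2)
    invvar = (1.0 / sd_rank ** 2).astype(np.float32)

    G = grid.features                     # (Ng, F)
    P = grid.params                       # (Ng, 4)
    A = (G * G * invvar).sum(axis=1)      # (Ng,)
    B = (G * invvar).astype(np.float32)   # (Ng, F)

    Y = np.vstack([features.rms, features.p2, features.p4]).astype(np.float32)   # (F, nv)
    nv = Y.shape[1]
    ok = features.valid & np.all((Y[:n_sh] >= _RMS_VALID_RANGE[0])
                                 & (Y[:n_sh] <= _RMS_VALID_RANGE[1]), axis=0)

    # diverse multi-start refinement against local minima
    n_top = 48
    div_scale = np.array([0.1, 0.1, 0.4, 0.4], dtype=np.float32)

    est = np.full((nv, 4), np.nan, dtype=np.float64)
    starts = np.full((nv, n_starts, 4), np.nan, dtype=np.float64)
    resid = np.full(nv, np.nan)
    idx = np.flatnonzero(ok)
    Bt = B.T.copy()
    for start in range(0, idx.size, chunk):
        sel = idx[start:start + chunk]
        Yc = Y[:, sel]                                     # (F, c)
        R = A[None, :] - 2.0 * (Yc.T @ Bt)                 # (c, Ng) + const per voxel
        Rmin = R.min(axis=1)
        resid[sel] = Rmin + (Yc * Yc * invvar[:, None]).sum(axis=0)
        if refine:
            top = np.argpartition(R, n_top, axis=1)[:, :n_top]
            for row, v in enumerate(sel):
                order = top[row][np.argsort(R[row, top[row]], kind="stable")]
                cand = P[order]                            # (n_top, 4) best-first
                chosen = [cand[0]]
                for c_ in cand[1:]:
                    if len(chosen) == n_starts:
                        break
                    if all(np.abs((c_ - ch) / div_scale).max() >= 1.0 for ch in chosen):
                        chosen.append(c_)
                while len(chosen) < n_starts:
                    chosen.append(chosen[0])
                starts[v] = np.asarray(chosen)
        else:
            W = np.exp(np.clip(-0.5 * (R - Rmin[:, None]), -60.0, 0.0))
            est[sel] = (W @ P) / W.sum(axis=1)[:, None]

    if refine and idx.size:
        Yd = np.vstack([features.rms, features.p2, features.p4])[:, idx]
        best_cost = np.full(idx.size, np.inf)
        best_est = np.full((idx.size, 4), np.nan)
        for k in range(n_starts):
            refined, cost = _refine_gauss_newton(starts[idx, k, :], Yd,
                                                 features.b_shells, 1.0 / sd,
                                                 n_iter=n_iter,
                                                 forward=forward, cols=idx.copy())
            better = cost < best_cost
            best_est[better] = refined[better]
            best_cost[better] = cost[better]
        est[idx] = best_est
        resid[idx] = best_cost

    shape3 = features.shape
    mask = features.mask

    def scatter(v):
        out = np.full(shape3, np.nan)
        out[mask] = v
        return out

    valid = np.zeros(shape3, bool)
    valid[mask] = ok
    return DMIMaps(v_intra=scatter(est[:, 0]), v_csf=scatter(est[:, 1]),
                   d_ax_intra=scatter(est[:, 2]), d_ax_extra=scatter(est[:, 3]),
                   residual=scatter(resid), valid=valid)


def fit_volume(data: np.ndarray, scheme: AcquisitionScheme,
               mask: np.ndarray | None = None, grid_preset: str = "coarse",
               sigma: float | None = None, rician_correct: bool = True,
               refine: bool = True, n_starts: int = 2, n_iter: int = 50) -> DMIMaps:
    """Convenience: features then grid fit on a 4D volume.

    Voxelwise maps default to lighter refinement settings than the
    zone-level fit: per-voxel noise dominates the residual there, so the
    extra polish would cost time without adding accuracy.
    """
    feats = shell_features(data, scheme, mask=mask, sigma=sigma,
                           rician_correct=rician_correct)
    grid = build_grid(grid_preset, tuple(feats.b_shells))
    return fit_features(feats, grid, refine=refine, n_starts=n_starts, n_iter=n_iter)


def _principal_orientation(dirs: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Fiber axis from a direction-sampled decaying profile.

    Fits log(vals) = c0 + g^T C g and returns the eigenvector of -C with
    the largest eigenvalue (fastest decay = along the fiber).
    """
    g = dirs
    X = np.column_stack([np.ones(len(g)), g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
                         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2],
                         2 * g[:, 1] * g[:, 2]])
    y = np.log(np.clip(vals, 1e-12, None))
    c = np.linalg.lstsq(X, y, rcond=None)[0]
    M = -np.array([[c[1], c[4], c[5]], [c[4], c[2], c[6]], [c[5], c[6], c[3]]])
    w, V = np.linalg.eigh(M)
    return V[:, np.argmax(w)]


def _discrete_zone_forward(dirs, pinv, l2_rows, l4_rows, orientations, b_shells):
    """Feature map computed through the same discrete sampling operator as
    the measurement (58-direction SH least squares), for given per-zone
    fiber orientations.  Removes the closed-form-vs-sampling
    representation mismatch that otherwise limits zone-level accuracy.
    """
    cos2_all = (dirs @ np.asarray(orientations, float).T) ** 2   # (ndir, nz)
    b_shells = tuple(float(b) for b in b_shells)

    def forward(vi, vc, dai, dae, cols):
        c2 = cos2_all[:, cols]                                    # (ndir, k)
        drad = tortuosity_drad(vi, vc, dae)
        ve = 1.0 - vi - vc
        rms_b, p2_b, p4_b = [], [], []
        for b in b_shells:
            S = (vc * np.exp(-D_FREE_WATER * b)
                 + vi * np.exp(-b * dai * c2)
                 + ve * np.exp(-b * (drad + (dae - drad) * c2)))
            sq = S ** 2
            rms_b.append(np.sqrt(sq.mean(axis=0)))
            coef = pinv @ sq
            p2_b.append(np.sqrt((coef[l2_rows] ** 2).sum(axis=0)))
            p4_b.append(np.sqrt((coef[l4_rows] ** 2).sum(axis=0)))
        return np.stack(rms_b + p2_b + p4_b)

    return forward


def fit_zones(data: np.ndarray, scheme: AcquisitionScheme,
              zone_masks: dict[str, np.ndarray], grid_preset: str = "coarse",
              sigma: float | None = None, rician_correct: bool = True,
              refine: bool = True) -> dict[str, dict[str, float]]:
    """Zone-level (ROI) microstructure estimates from zone-averaged signals.

    The debiased squared signal is averaged over each zone's voxels
    before feature extraction, which raises the effective feature SNR by
    sqrt(N_voxels) and moves the estimator into its well-conditioned
    regime; per-voxel posterior estimates at clinical SNR carry
    parameter-coupled biases that can mask small zone-to-zone contrasts.
    The zone's fiber orientation (assumed coherent within the zone) is
    estimated from the averaged directional profile, and the refinement
    evaluates the forward model through the same discrete sampling
    operator as the measurement, eliminating quadrature mismatch.

    Returns ``{zone: {parameter: value, "n_voxels": n}}``.
    """
    union = np.zeros(data.shape[:3], bool)
    for m in zone_masks.values():
        union |= np.asarray(m, bool)
    sq_by_shell, s0_sq_safe, valid, sigma_abs = _squared_normalized(
        data, scheme, union, sigma, rician_correct)
    grid = build_grid(grid_preset, tuple(scheme.shells_ms_um2))
    pinv, l2_rows, l4_rows, tr2, tr4 = _sh_fit_operator(tuple(scheme.directions.ravel()))

    zone_of = {z: np.asarray(m, bool)[union] for z, m in zone_masks.items()}
    n_sh = len(sq_by_shell)

    zones, feat_cols, orients, counts = [], [], [], []
    for zone, sel in zone_of.items():
        ok = sel & valid
        n_ok = int(ok.sum())
        zones.append(zone)
        counts.append(n_ok)
        if n_ok == 0:
            continue
        rms_b, p2_b, p4_b = [], [], []
        sq_means = []
        for sq in sq_by_shell:
            sq_mean = sq[ok].mean(axis=0)                # (ndir,)
            sq_means.append(sq_mean)
            rms_b.append(np.sqrt(max(sq_mean.mean(), 0.0)))
            coef = pinv @ sq_mean
            pow2 = float((coef[l2_rows] ** 2).sum())
            pow4 = float((coef[l4_rows] ** 2).sum())
            if sigma_abs > 0:
                s_sq = max(sq_mean.mean(), 0.0) * float(np.median(s0_sq_safe[ok]))
                var_sq = ((4.0 * s_sq * sigma_abs ** 2 + 4.0 * sigma_abs ** 4)
                          / float(np.median(s0_sq_safe[ok])) ** 2) / n_ok
                pow2 = max(pow2 - tr2 * var_sq, 0.0)
                pow4 = max(pow4 - tr4 * var_sq, 0.0)
            p2_b.append(np.sqrt(pow2))
            p4_b.append(np.sqrt(pow4))
        feat_cols.append(np.array(rms_b + p2_b + p4_b))
        orients.append(_principal_orientation(scheme.directions, sq_means[0]))

    out: dict[str, dict[str, float]] = {}
    fitted = [i for i, c in enumerate(counts) if c > 0]
    if fitted:
        feats_arr = np.stack(feat_cols, axis=1)          # (3*n_sh, nz)
        nz = feats_arr.shape[1]
        sigma_vol = 0.0
        if sigma_abs > 0 and valid.any():
            # zones hold near-equal voxel counts; a common (conservative)
            # effective noise level keeps the fit batched
            s0_med = float(np.median(np.sqrt(s0_sq_safe[valid])))
            sigma_vol = sigma_abs / s0_med / np.sqrt(min(counts[i] for i in fitted))
        zone_feats = ShellFeatures(
            b_shells=scheme.shells_ms_um2,
            rms=feats_arr[:n_sh], p2=feats_arr[n_sh:2 * n_sh], p4=feats_arr[2 * n_sh:],
            n_dirs=scheme.directions_per_shell,
            sigma_vol=sigma_vol,
            valid=np.ones(nz, bool), mask=np.ones((nz, 1, 1), bool),
            shape=(nz, 1, 1), tr2=tr2, tr4=tr4)
        fwd = _discrete_zone_forward(scheme.directions, pinv, l2_rows, l4_rows,
                                     np.stack(orients), scheme.shells_ms_um2)
        maps = fit_features(zone_feats, grid, refine=refine, forward=fwd)
        for col, i in enumerate(fitted):
            out[zones[i]] = {"v_intra": float(maps.v_intra[col, 0, 0]),
                             "v_csf": float(maps.v_csf[col, 0, 0]),
                             "d_ax_intra": float(maps.d_ax_intra[col, 0, 0]),
                             "d_ax_extra": float(maps.d_ax_extra[col, 0, 0]),
                             "n_voxels": counts[i]}
    for i, zone in enumerate(zones):
        if counts[i] == 0:
            out[zone] = {"v_intra": np.nan, "v_csf": np.nan,
                         "d_ax_intra": np.nan, "d_ax_extra": np.nan,
                         "n_voxels": 0}
    return out


def fit_voxel(rms: np.ndarray, p2: np.ndarray, p4: np.ndarray, b_shells,
              n_dirs: int = 58, sigma_vol: float = 0.0, grid_preset: str = "fine",
              refine: bool = True) -> dict[str, float]:
    """Fit a single voxel from its rotation-invariant features.

    Returns the posterior parameter dict; out-of-range features mark the
    voxel invalid (NaN) instead of raising.
    """
    rms = np.asarray(rms, float).reshape(-1, 1)
    p2 = np.asarray(p2, float).reshape(-1, 1)
    p4 = np.asarray(p4, float).reshape(-1, 1)
    feats = ShellFeatures(b_shells=np.asarray(b_shells, float), rms=rms, p2=p2,
                          p4=p4, n_dirs=n_dirs, sigma_vol=sigma_vol,
                          valid=np.array([True]), mask=np.ones((1, 1, 1), bool),
                          shape=(1, 1, 1))
    grid = build_grid(grid_preset, tuple(feats.b_shells))
    maps = fit_features(feats, grid, refine=refine)
    return {"v_intra": float(maps.v_intra[0, 0, 0]),
            "v_csf": float(maps.v_csf[0, 0, 0]),
            "d_ax_intra": float(maps.d_ax_intra[0, 0, 0]),
            "d_ax_extra": float(maps.d_ax_extra[0, 0, 0]),
            "residual": float(maps.residual[0, 0, 0]),
            "valid": bool(maps.valid[0, 0, 0])}
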