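"""Synthetic lesion phantoms: label geometry, ground truth and DWI signal.

A phantom is a spherical enhancing tumor core surrounded by an edema
shell, embedded in normal white matter, with an optional gray-matter
shell outside the edema to exercise exclusion logic.  Edema voxels carry
zone-dependent microstructure: either hard per-tertile constants (the
default for calibrated cohorts, so that zone summaries equal the
calibrated zone values exactly) or a smooth radial interpolation from the
inner-zone value at the core boundary to the outer-zone value at the
edema boundary.

The diffusion-weighted signal of a voxel with fiber orientation n under
gradient g at b (ms/um^2) is the three-compartment mixture

    S/S0 = V_csf * exp(-3 b)
         + V_intra * exp(-b * D_ax_intra * (g.n)^2)
         + V_extra * exp(-b * [D_rad + (D_ax_extra - D_rad) * (g.n)^2])

with Rician noise of sigma = S0 / SNR applied to the magnitude (Gaussian
and noise-free modes are available for analytic checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import dmi, dti, zonation
from .errors import DegenerateGeometryError, InvalidNoiseError
from .profiles import HEALTHY_TISSUE, ZoneProfile, SubjectSpec
from .scheme import AcquisitionScheme

__all__ = ["PhantomSpec", "LabelVolume", "MicrostructureGroundTruth", "DWIVolume",
           "make_labels", "assign_microstructure", "synthesize_signal",
           "effective_fa", "calibrate_drad_for_fa", "make_subject", "Subject"]

_PARAM_NAMES = ("v_intra", "v_csf", "d_ax_intra", "d_ax_extra")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and synthesis settings for one phantom."""

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    r_core_mm: float = 6.0
    r_edema_mm: float = 13.5
    gm_thickness_mm: float = 0.0
    brain_radius_mm: float | None = None   # None: whole grid is brain
    snr: float = 30.0
    noise_model: str = "rician"            # rician | gaussian | none
    s0: float = 500.0
    seed: int = 0
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    smooth: bool = False

    def __post_init__(self):
        if not (0 < self.r_core_mm < self.r_edema_mm):
            raise DegenerateGeometryError(
                f"need 0 < core radius ({self.r_core_mm}) < edema radius ({self.r_edema_mm})")


@dataclass
class LabelVolume:
    """Integer tissue labels: 0 bg, 1 core, 2 edema, 3 GM, 4 WM."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class MicrostructureGroundTruth:
    """Per-voxel ground-truth parameters (arrays share the label grid).

    ``signal_scale`` is 1 inside the head and 0 in background, where no
    signal is produced.  ``orientation`` is the (global) fiber direction.
    """

    v_intra: np.ndarray
    v_csf: np.ndarray
    d_ax_intra: np.ndarray
    d_ax_extra: np.ndarray
    d_rad_extra: np.ndarray
    orientation: np.ndarray
    signal_scale: np.ndarray
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    affine: np.ndarray | None = None

    @property
    def v_extra(self) -> np.ndarray:
        return 1.0 - self.v_intra - self.v_csf

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in _PARAM_NAMES}


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its acquisition scheme."""

    data: np.ndarray
    scheme: AcquisitionScheme
    spacing: tuple[float, float, float]
    affine: np.ndarray
    s0: float

    def __post_init__(self):
        if self.data.shape[-1] != self.scheme.n_volumes:
            raise ValueError("volume count does not match scheme")


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _voxel_radii(shape, spacing) -> np.ndarray:
    """Distance (mm) of every voxel center from the grid center."""
    axes = [(np.arange(n) + 0.5) * s - n * s / 2.0 for n, s in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)


def make_labels(spec: PhantomSpec) -> LabelVolume:
    """Spherical core + edema shell (+ optional GM shell) label volume.

    Raises
    ------
    DegenerateGeometryError
        If the edema shell contains no voxel at this resolution.
    """
    r = _voxel_radii(spec.shape, spec.spacing)
    labels = np.full(spec.shape, zonation.LABEL_WM, dtype=np.int8)
    if spec.brain_radius_mm is not None:
        labels[r > spec.brain_radius_mm] = zonation.LABEL_BACKGROUND
    if spec.gm_thickness_mm > 0:
        gm = (r > spec.r_edema_mm) & (r <= spec.r_edema_mm + spec.gm_thickness_mm)
        labels[gm] = zonation.LABEL_GM
    core = r <= spec.r_core_mm
    edema = (r <= spec.r_edema_mm) & ~core
    if not core.any():
        raise DegenerateGeometryError("core contains no voxels at this resolution")
    if not edema.any():
        raise DegenerateGeometryError("edema shell contains no voxels at this resolution")
    labels[edema] = zonation.LABEL_EDEMA
    labels[core] = zonation.LABEL_CORE
    if spec.r_edema_mm > min(n * s / 2 for n, s in zip(spec.shape, spec.spacing)):
        raise DegenerateGeometryError("edema extends beyond the grid")
    return LabelVolume(labels=labels, spacing=spec.spacing, affine=_affine(spec.spacing))


def _zone_weights_smooth(dist: np.ndarray, edema: np.ndarray) -> np.ndarray:
    d = dist[edema]
    lo, hi = float(np.nanmin(d)), float(np.nanmax(d))
    if hi <= lo:
        return np.zeros(d.shape)
    return (d - lo) / (hi - lo)


def assign_microstructure(labels: LabelVolume, profile: ZoneProfile,
                          smooth: bool = False,
                          orientation=(0.0, 0.0, 1.0)) -> MicrostructureGroundTruth:
    """Paint ground-truth parameter maps onto a label volume.

    Edema voxels get zone-dependent values: with ``smooth`` a piecewise-
    linear radial profile anchored at the IZ value on the core boundary,
    the MZ value midway and the OZ value on the outer boundary; otherwise
    hard constants on the equal-volume distance tertiles (computed with
    the same rule the zonation module uses, so analysis zones and
    ground-truth zones coincide when no voxels are excluded).
    """
    profile.validate()
    lab = labels.labels
    core = lab == zonation.LABEL_CORE
    edema = lab == zonation.LABEL_EDEMA
    if not edema.any():
        raise DegenerateGeometryError("label volume has no edema")

    maps = {}
    for name in _PARAM_NAMES:
        arr = np.zeros(lab.shape)
        for tissue, code in (("wm", zonation.LABEL_WM), ("gm", zonation.LABEL_GM),
                             ("core", zonation.LABEL_CORE)):
            arr[lab == code] = HEALTHY_TISSUE[tissue][name]
        maps[name] = arr

    dist = zonation.distance_from_core(core, edema, labels.spacing)
    zone_vals = {name: np.asarray(getattr(profile, name), float) for name in _PARAM_NAMES}
    drad_zone = (np.asarray(profile.d_rad_extra, float)
                 if profile.d_rad_extra is not None else None)

    if smooth:
        w = _zone_weights_smooth(dist, edema)
        for name in _PARAM_NAMES:
            iz, mz, oz = zone_vals[name]
            maps[name][edema] = np.interp(w, [0.0, 0.5, 1.0], [iz, mz, oz])
        drad_edema = (np.interp(w, [0.0, 0.5, 1.0], drad_zone)
                      if drad_zone is not None else None)
    else:
        parc = zonation.partition_equal_volume(dist, edema)
        zone_idx = parc.zone_map[edema] - 1        # 0,1,2
        for name in _PARAM_NAMES:
            maps[name][edema] = zone_vals[name][zone_idx]
        drad_edema = drad_zone[zone_idx] if drad_zone is not None else None

    drad = dmi.tortuosity_drad(maps["v_intra"], maps["v_csf"], maps["d_ax_extra"])
    if drad_edema is not None:
        drad[edema] = drad_edema

    scale = (lab != zonation.LABEL_BACKGROUND).astype(float)
    n = np.asarray(orientation, float)
    n = n / np.linalg.norm(n)
    return MicrostructureGroundTruth(
        v_intra=maps["v_intra"], v_csf=maps["v_csf"],
        d_ax_intra=maps["d_ax_intra"], d_ax_extra=maps["d_ax_extra"],
        d_rad_extra=drad, orientation=n, signal_scale=scale,
        spacing=labels.spacing, affine=labels.affine)


def _noise_free_signal(truth: MicrostructureGroundTruth,
                       scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free S/S0, shape (*grid, n_volumes)."""
    b = scheme.bvals()[None, :] / 1000.0                     # ms/um^2
    cos2 = (scheme.bvecs() @ truth.orientation)[None, :] ** 2
    flat = lambda a: a.reshape(-1, 1)
    vi, vc = flat(truth.v_intra), flat(truth.v_csf)
    ve = 1.0 - vi - vc
    dai, dae, dr = flat(truth.d_ax_intra), flat(truth.d_ax_extra), flat(truth.d_rad_extra)
    s = (vc * np.exp(-dmi.D_FREE_WATER * b)
         + vi * np.exp(-b * dai * cos2)
         + ve * np.exp(-b * (dr + (dae - dr) * cos2)))
    s *= flat(truth.signal_scale)
    return s.reshape(truth.v_intra.shape + (scheme.n_volumes,))


def synthesize_signal(truth: MicrostructureGroundTruth, scheme: AcquisitionScheme,
                      snr: float = 30.0, seed: int = 0,
                      noise_model: str = "rician", s0: float = 500.0) -> DWIVolume:
    """Noisy two-shell DWI volume from ground-truth maps.

    ``snr`` is the b=0 signal-to-noise ratio; sigma = s0/snr.  Identical
    seeds give bit-identical output.

    Raises
    ------
    InvalidNoiseError
        If snr <= 0 or the noise model is unknown.
    """
    if not np.isfinite(snr) or snr <= 0:
        raise InvalidNoiseError(f"snr must be positive and finite, got {snr}")
    if noise_model not in ("rician", "gaussian", "none"):
        raise InvalidNoiseError(f"unknown noise model {noise_model!r}")
    s = s0 * _noise_free_signal(truth, scheme)
    if noise_model != "none":
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        if noise_model == "rician":
            s = np.sqrt((s + rng.normal(0, sigma, s.shape)) ** 2
                        + rng.normal(0, sigma, s.shape) ** 2)
        else:
            s = s + rng.normal(0, sigma, s.shape)
    return DWIVolume(data=s, scheme=scheme, spacing=truth.spacing,
                     affine=truth.affine if truth.affine is not None else _affine(truth.spacing),
                     s0=s0)


# ---------------------------------------------------------------------------
# FA calibration
# ---------------------------------------------------------------------------

def effective_fa(v_intra: float, v_csf: float, d_ax_intra: float,
                 d_ax_extra: float, d_rad_extra: float,
                 scheme: AcquisitionScheme) -> float:
    """FA that the log-linear DTI fit recovers from the noise-free mixture.

    The mixture signal is not mono-exponential, so this effective FA -- not
    an analytic tensor FA -- is the quantity the pipeline's DTI stage
    measures; calibration targets it directly.
    """
    b = scheme.bvals() / 1000.0
    cos2 = (scheme.bvecs() @ np.array([0.0, 0.0, 1.0])) ** 2
    ve = 1.0 - v_intra - v_csf
    s = (v_csf * np.exp(-dmi.D_FREE_WATER * b)
         + v_intra * np.exp(-b * d_ax_intra * cos2)
         + ve * np.exp(-b * (d_rad_extra + (d_ax_extra - d_rad_extra) * cos2)))
    lam = dti.single_voxel_tensor(s, scheme)
    return dti.fa_from_eigenvalues(lam)


def calibrate_drad_for_fa(v_intra: float, v_csf: float, d_ax_intra: float,
                          d_ax_extra: float, fa_target: float,
                          scheme: AcquisitionScheme,
                          bounds: tuple[float, float] = (0.05, None)) -> float:
    """Radial extra-axonal diffusivity that reaches a target effective FA.

    FA decreases monotonically in D_rad (the zeppelin flattens), so a
    bracketed root search applies; targets outside the reachable range are
    clamped to the nearest bound.
    """
    lo = bounds[0]
    hi = bounds[1] if bounds[1] is not None else d_ax_extra - 0.01
    hi = min(hi, d_ax_extra - 1e-3)
    f = lambda dr: effective_fa(v_intra, v_csf, d_ax_intra, d_ax_extra, dr, scheme) - fa_target
    f_lo, f_hi = f(lo), f(hi)
    if f_lo <= 0:          # even the most anisotropic zeppelin is below target
        return lo
    if f_hi >= 0:          # fully tortuosity-flattened still above target
        return hi
    return brentq(f, lo, hi, xtol=1e-6)


# ---------------------------------------------------------------------------
# Subject assembly
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    """All per-subject artifacts the pipeline consumes."""

    spec: SubjectSpec
    labels: LabelVolume
    truth: MicrostructureGroundTruth
    dwi: DWIVolume
    fa_truth: tuple[float, float, float] | None = None


def make_subject(spec: SubjectSpec, scheme: AcquisitionScheme,
                 shape=(32, 32, 32), spacing=(1.5, 1.5, 1.5),
                 snr: float = 30.0, noise_model: str = "rician",
                 smooth: bool = False, gm_thickness_mm: float = 0.0,
                 calibrate_fa: bool = True) -> Subject:
    """Build one synthetic subject from its specification.

    With ``calibrate_fa`` and a profile carrying FA targets, the per-zone
    radial extra-axonal diffusivity is calibrated so the noise-free DTI FA
    of each zone equals the target; otherwise the tortuosity closure sets
    it (the configuration the microstructure fit assumes, appropriate when
    assessing microstructure-parameter recovery).
    """
    pspec = PhantomSpec(shape=shape, spacing=spacing, r_core_mm=spec.r_core_mm,
                        r_edema_mm=spec.r_edema_mm, snr=snr, noise_model=noise_model,
                        seed=spec.seed, smooth=smooth, gm_thickness_mm=gm_thickness_mm)
    labels = make_labels(pspec)
    profile = spec.profile
    if calibrate_fa and profile.fa_target is not None and profile.d_rad_extra is None:
        drad = tuple(
            calibrate_drad_for_fa(profile.v_intra[i], profile.v_csf[i],
                                  profile.d_ax_intra[i], profile.d_ax_extra[i],
                                  profile.fa_target[i], scheme)
            for i in range(3))
        profile = ZoneProfile(v_intra=profile.v_intra, v_csf=profile.v_csf,
                              d_ax_intra=profile.d_ax_intra,
                              d_ax_extra=profile.d_ax_extra,
                              d_rad_extra=drad, fa_target=profile.fa_target)
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(size=3)
    orientation = tuple(u / np.linalg.norm(u))
    truth = assign_microstructure(labels, profile, smooth=smooth,
                                  orientation=orientation)
    dwi = synthesize_signal(truth, scheme, snr=snr, seed=spec.seed,
                            noise_model=noise_model, s0=pspec.s0)
    return Subject(spec=spec, labels=labels, truth=truth, dwi=dwi,
                   fa_truth=profile.fa_target)
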