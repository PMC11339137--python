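"""Zone-wise microstructure profiles and synthetic cohort sampling.

The generator has to stand in for patient data, so its defaults encode the
published group-level zone statistics of peritumoral edema around
glioblastoma ("gbm") and brain metastases ("met"): fractional anisotropy,
the intra-axonal volume fraction, the free-water fraction and the axial
intra-/extra-axonal diffusivities in the inner zone, plus the outer-minus-
inner (OZ-IZ) gradient of each metric.  Where a quantity is published as
median [IQR], the normal SD is taken as IQR / 1.349; quantities never
published for one group (e.g. metastasis V_intra levels) use values chosen
once to be physiologically plausible and consistent with the published
gradients.

Per-subject zone values are sampled from these normal distributions.  The
default sampling mode is ``"quantile"``: one draw per normal quantile
midpoint (i - 0.5)/n, randomly permuted across subjects.  This represents
the same distribution but makes the finite cohort's sample statistics
match the calibrated population values, which is the point of a calibrated
synthetic cohort; ``"random"`` gives plain i.i.d. draws.

The middle-zone value of every metric is the IZ/OZ midpoint (the published
zone analysis shows monotone gradual change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidProfileError

__all__ = ["ZoneProfile", "SubjectSpec", "GROUP_CALIBRATION", "HEALTHY_TISSUE",
           "default_profile", "sample_cohort"]

ZONES = ("IZ", "MZ", "OZ")


@dataclass(frozen=True)
class ZoneProfile:
    """Ground-truth parameter values per zone (IZ, MZ, OZ tuples).

    ``fa_target`` is the desired DTI fractional anisotropy per zone; when
    set, the extra-axonal radial diffusivity is calibrated per zone to
    reach it (see phantom.calibrate_drad_for_fa), otherwise the tortuosity
    closure applies (``d_rad_extra=None``).
    """

    v_intra: tuple[float, float, float]
    v_csf: tuple[float, float, float]
    d_ax_intra: tuple[float, float, float]
    d_ax_extra: tuple[float, float, float]
    d_rad_extra: tuple[float, float, float] | None = None
    fa_target: tuple[float, float, float] | None = None

    def validate(self) -> None:
        for i, z in enumerate(ZONES):
            vi, vc = self.v_intra[i], self.v_csf[i]
            if not (0 <= vi <= 1 and 0 <= vc <= 1 and vi + vc <= 1):
                raise InvalidProfileError(
                    f"zone {z}: V_intra={vi}, V_csf={vc} violate the simplex")
            for nm in ("d_ax_intra", "d_ax_extra"):
                d = getattr(self, nm)[i]
                if not (0 < d <= 3):
                    raise InvalidProfileError(f"zone {z}: {nm}={d} outside (0, 3]")
            if self.d_rad_extra is not None:
                dr = self.d_rad_extra[i]
                if not (0 < dr <= self.d_ax_extra[i]):
                    raise InvalidProfileError(
                        f"zone {z}: d_rad_extra={dr} outside (0, d_ax_extra]")

    def zone_values(self, metric: str, zone: str) -> float:
        return getattr(self, metric)[ZONES.index(zone)]


# (mean, SD) of the inner-zone level and of the OZ-IZ per-subject gradient.
# SDs of median[IQR] quantities are IQR / 1.349.
GROUP_CALIBRATION: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "gbm": {
        "fa":         {"iz": (0.18, 0.04),   "doz": (0.003, 0.04)},
        "v_intra":    {"iz": (0.08, 0.0297), "doz": (0.010, 0.010)},
        "v_csf":      {"iz": (0.48, 0.12),   "doz": (-0.010, 0.020)},
        "d_ax_intra": {"iz": (2.29, 0.0222), "doz": (-0.008, 0.0114)},
        "d_ax_extra": {"iz": (1.22, 0.0297), "doz": (-0.010, 0.0237)},
    },
    "met": {
        "fa":         {"iz": (0.18, 0.04),   "doz": (0.030, 0.05)},
        "v_intra":    {"iz": (0.085, 0.0297), "doz": (0.005, 0.010)},
        "v_csf":      {"iz": (0.50, 0.12),   "doz": (-0.010, 0.020)},
        "d_ax_intra": {"iz": (2.28, 0.0222), "doz": (0.002, 0.0096)},
        "d_ax_extra": {"iz": (1.24, 0.0297), "doz": (0.010, 0.0200)},
    },
}

# clamp ranges keep sampled cohorts physical
_CLAMPS = {
    "fa": (0.08, 0.40),
    "v_intra": (0.02, 0.30),
    "v_csf": (0.05, 0.85),
    "d_ax_intra": (1.50, 3.00),
    "d_ax_extra": (0.80, 2.95),
}

# fixed values for non-edema tissue: v_intra, v_csf, d_ax_intra, d_ax_extra
HEALTHY_TISSUE = {
    "wm":   {"v_intra": 0.40, "v_csf": 0.05, "d_ax_intra": 2.30, "d_ax_extra": 2.00},
    "gm":   {"v_intra": 0.15, "v_csf": 0.10, "d_ax_intra": 1.80, "d_ax_extra": 1.20},
    "core": {"v_intra": 0.02, "v_csf": 0.35, "d_ax_intra": 2.00, "d_ax_extra": 1.50},
}


@dataclass(frozen=True)
class SubjectSpec:
    """One synthetic subject: identity, geometry and zone profile."""

    subject_id: str
    group: str
    profile: ZoneProfile
    r_core_mm: float = 6.0
    r_edema_mm: float = 13.5
    seed: int = 0


def _profile_from_levels(levels: dict[str, tuple[float, float]]) -> ZoneProfile:
    """Build a ZoneProfile from per-metric (IZ, OZ) pairs; MZ is the midpoint."""
    def tup(m):
        iz, oz = levels[m]
        return (iz, 0.5 * (iz + oz), oz)
    prof = ZoneProfile(v_intra=tup("v_intra"), v_csf=tup("v_csf"),
                       d_ax_intra=tup("d_ax_intra"), d_ax_extra=tup("d_ax_extra"),
                       fa_target=tup("fa"))
    prof.validate()
    return prof


def default_profile(group: str) -> ZoneProfile:
    """Central (population-mean) zone profile for ``"gbm"`` or ``"met"``."""
    cal = GROUP_CALIBRATION[group]
    levels = {m: (cal[m]["iz"][0], cal[m]["iz"][0] + cal[m]["doz"][0]) for m in cal}
    return _profile_from_levels(levels)


def _draws(mean: float, sd: float, n: int, rng: np.random.Generator,
           sampling: str) -> np.ndarray:
    if sampling == "quantile":
        q = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        return rng.permutation(mean + sd * q)
    if sampling == "random":
        return rng.normal(mean, sd, n)
    raise ValueError(f"unknown sampling mode {sampling!r}")


def sample_cohort(group: str, n: int, seed: int, sampling: str = "quantile",
                  r_core_mm: float = 6.0,
                  r_edema_range_mm: tuple[float, float] = (12.0, 15.0)) -> list[SubjectSpec]:
    """Draw ``n`` subject specifications for one group.

    Inner-zone levels and OZ-IZ gradients are drawn independently per
    metric from the group calibration; edema outer radii are spread
    uniformly over ``r_edema_range_mm`` (scaled-down lesions keep cohorts
    tractable while leaving zone statistics untouched).
    """
    if group not in GROUP_CALIBRATION:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    cal = GROUP_CALIBRATION[group]
    iz = {m: _draws(*cal[m]["iz"], n, rng, sampling) for m in cal}
    doz = {m: _draws(*cal[m]["doz"], n, rng, sampling) for m in cal}

    lo, hi = r_edema_range_mm
    if sampling == "quantile":
        r_edema = rng.permutation(lo + (hi - lo) * (np.arange(1, n + 1) - 0.5) / n)
    else:
        r_edema = rng.uniform(lo, hi, n)

    subjects = []
    for i in range(n):
        levels = {}
        for m in cal:
            a, b = _CLAMPS[m]
            iz_v = float(np.clip(iz[m][i], a, b))
            oz_v = float(np.clip(iz_v + doz[m][i], a, b))
            levels[m] = (iz_v, oz_v)
        # keep the simplex with headroom
        for z in range(2):
            vi = levels["v_intra"][z]
            vc = levels["v_csf"][z]
            if vi + vc > 0.95:
                levels["v_csf"] = tuple(
                    (0.95 - vi) if k == z else v for k, v in enumerate(levels["v_csf"]))
        prof = _profile_from_levels(levels)
        subjects.append(SubjectSpec(
            subject_id=f"{group}{i+1:03d}", group=group, profile=prof,
            r_core_mm=r_core_mm, r_edema_mm=float(r_edema[i]),
            seed=int(rng.integers(0, 2**31 - 1))))
    return subjects
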