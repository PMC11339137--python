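import numpy as np
import pytest

from perizone import dmi
from perizone.scheme import AcquisitionScheme, make_scheme


@pytest.fixture(scope="session")
def scheme():
    """The default two-shell protocol: 15 b=0 + 58 directions at b=1000/2000."""
    return make_scheme()


@pytest.fixture(scope="session")
def axis_scheme():
    """Small scheme whose direction set contains exact axis-aligned vectors."""
    s = 1.0 / np.sqrt(2.0)
    dirs = np.array([
        [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [s, s, 0], [s, 0, s], [0, s, s],
        [-s, s, 0], [s, 0, -s],
    ], dtype=float)
    return AcquisitionScheme(b_values=(0.0, 1000.0, 2000.0), n_b0=2, directions=dirs)


def mixture_signal(scheme, v_intra, v_csf, d_ax_intra, d_ax_extra,
                   d_rad_extra=None, orientation=(0.0, 0.0, 1.0)):
    """Noise-free per-volume S/S0 of the three-compartment mixture."""
    if d_rad_extra is None:
        d_rad_extra = float(dmi.tortuosity_drad(v_intra, v_csf, d_ax_extra))
    n = np.asarray(orientation, float)
    n = n / np.linalg.norm(n)
    b = scheme.bvals() / 1000.0
    cos2 = (scheme.bvecs() @ n) ** 2
    ve = 1.0 - v_intra - v_csf
    return (v_csf * np.exp(-dmi.D_FREE_WATER * b)
            + v_intra * np.exp(-b * d_ax_intra * cos2)
            + ve * np.exp(-b * (d_rad_extra + (d_ax_extra - d_rad_extra) * cos2)))


def measured_features(scheme, signal):
    """(rms, p2, p4) per shell of a per-volume signal, as the fit measures them."""
    pinv, l2, l4, _, _ = dmi._sh_fit_operator(tuple(scheme.directions.ravel()))
    rms, p2, p4 = [], [], []
    for sl in scheme.shell_slices().values():
        sq = np.asarray(signal[sl]) ** 2
        rms.append(np.sqrt(sq.mean()))
        c = pinv @ sq
        p2.append(np.sqrt(np.sum(c[l2] ** 2)))
        p4.append(np.sqrt(np.sum(c[l4] ** 2)))
    return np.array(rms), np.array(p2), np.array(p4)
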