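import numpy as np
import pytest

from perizone import dmi
from perizone.errors import (DegenerateGeometryError, InvalidNoiseError,
                             InvalidProfileError)
from perizone.phantom import (PhantomSpec, assign_microstructure,
                              calibrate_drad_for_fa, effective_fa, make_labels,
                              make_subject, synthesize_signal)
from perizone.profiles import ZoneProfile, default_profile, sample_cohort
from perizone.zonation import LABEL_CORE, LABEL_EDEMA

from conftest import mixture_signal


@pytest.fixture(scope="module")
def labels():
    return make_labels(PhantomSpec(shape=(40, 40, 40), r_core_mm=6.0, r_edema_mm=15.0))


def test_core_and_edema_disjoint_nonzero(labels):
    core = labels.mask(LABEL_CORE)
    edema = labels.mask(LABEL_EDEMA)
    assert core.any() and edema.any()
    assert not (core & edema).any()


def test_core_count_matches_voxel_center_enumeration(labels):
    # exhaustive check: voxel centers within 6 mm of the grid center
    n, s = 40, 1.5
    ax = (np.arange(n) + 0.5) * s - n * s / 2
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    expected = int((gx ** 2 + gy ** 2 + gz ** 2 <= 6.0 ** 2).sum())
    assert int(labels.mask(LABEL_CORE).sum()) == expected


def test_empty_edema_shell_raises():
    with pytest.raises(DegenerateGeometryError):
        make_labels(PhantomSpec(shape=(40, 40, 40), r_core_mm=6.0, r_edema_mm=6.1))


def test_edema_beyond_grid_raises():
    with pytest.raises(DegenerateGeometryError):
        make_labels(PhantomSpec(shape=(10, 10, 10), r_core_mm=4.0, r_edema_mm=20.0))


class TestAssignMicrostructure:
    def test_smooth_boundary_voxel_gets_inner_zone_value(self, labels):
        prof = default_profile("met")
        truth = assign_microstructure(labels, prof, smooth=True)
        from perizone import zonation
        dist = zonation.distance_from_core(labels.mask(LABEL_CORE),
                                           labels.mask(LABEL_EDEMA), labels.spacing)
        edema = labels.mask(LABEL_EDEMA)
        closest = np.nanargmin(np.where(edema, dist, np.nan).ravel())
        assert truth.v_csf.ravel()[closest] == pytest.approx(prof.v_csf[0])

    def test_smooth_profile_monotone_outward(self, labels):
        # inner V_intra below outer -> nondecreasing along any outward ray
        prof = default_profile("gbm")
        assert prof.v_intra[0] < prof.v_intra[2]
        truth = assign_microstructure(labels, prof, smooth=True)
        from perizone import zonation
        dist = zonation.distance_from_core(labels.mask(LABEL_CORE),
                                           labels.mask(LABEL_EDEMA), labels.spacing)
        edema = labels.mask(LABEL_EDEMA)
        order = np.argsort(dist[edema])
        vals = truth.v_intra[edema][order]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_hard_zones_have_three_levels(self, labels):
        truth = assign_microstructure(labels, default_profile("gbm"), smooth=False)
        vals = np.unique(truth.v_intra[labels.mask(LABEL_EDEMA)])
        assert len(vals) == 3

    def test_invalid_profile_rejected(self, labels):
        bad = ZoneProfile(v_intra=(0.5, 0.5, 0.5), v_csf=(0.6, 0.6, 0.6),
                          d_ax_intra=(2.3,) * 3, d_ax_extra=(1.2,) * 3)
        with pytest.raises(InvalidProfileError):
            assign_microstructure(labels, bad)

    def test_fractions_sum_to_one(self, labels):
        truth = assign_microstructure(labels, default_profile("met"), smooth=True)
        total = truth.v_intra + truth.v_csf + truth.v_extra
        np.testing.assert_allclose(total, 1.0, atol=1e-9)


class TestSynthesizeSignal:
    def _csf_truth(self, labels):
        prof = ZoneProfile(v_intra=(0.0,) * 3, v_csf=(1.0,) * 3,
                           d_ax_intra=(2.3,) * 3, d_ax_extra=(1.2,) * 3)
        return assign_microstructure(labels, prof)

    def test_pure_csf_attenuation(self, labels, scheme):
        truth = self._csf_truth(labels)
        dwi = synthesize_signal(truth, scheme, noise_model="none", s0=1.0)
        edema = labels.mask(LABEL_EDEMA)
        b1000 = dwi.data[edema][:, scheme.shell_slices()[1000.0]]
        np.testing.assert_allclose(b1000, np.exp(-3.0), rtol=1e-12)

    def test_b0_normalization(self, labels, scheme):
        truth = assign_microstructure(labels, default_profile("gbm"))
        dwi = synthesize_signal(truth, scheme, noise_model="none", s0=1.0)
        edema = labels.mask(LABEL_EDEMA)
        np.testing.assert_allclose(dwi.data[edema][:, scheme.b0_slice], 1.0)

    def test_stick_parallel_and_perpendicular(self, axis_scheme):
        # V_intra = 1, D_ax = 2.29: no attenuation across the fiber,
        # exp(-b D) along it
        s = mixture_signal(axis_scheme, 1.0, 0.0, 2.29, 1.2, orientation=(0, 0, 1))
        shell = axis_scheme.shell_slices()[1000.0]
        dirs = axis_scheme.directions
        perp = np.flatnonzero(np.abs(dirs @ [0, 0, 1]) < 1e-12)[0]
        par = np.flatnonzero(np.abs(dirs @ [0, 0, 1]) > 1 - 1e-12)[0]
        assert s[shell][perp] == pytest.approx(1.0, abs=1e-12)
        assert s[shell][par] == pytest.approx(np.exp(-2.29), abs=1e-12)

    def test_noise_free_signal_bounds(self, labels, scheme):
        truth = assign_microstructure(labels, default_profile("met"))
        dwi = synthesize_signal(truth, scheme, noise_model="none", s0=1.0)
        inside = labels.labels > 0
        vals = dwi.data[inside]
        assert vals.min() > 0.0 and vals.max() <= 1.0 + 1e-12

    def test_seed_determinism(self, labels, scheme):
        truth = assign_microstructure(labels, default_profile("gbm"))
        a = synthesize_signal(truth, scheme, snr=30, seed=11)
        b = synthesize_signal(truth, scheme, snr=30, seed=11)
        c = synthesize_signal(truth, scheme, snr=30, seed=12)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_invalid_noise_raises(self, labels, scheme):
        truth = assign_microstructure(labels, default_profile("gbm"))
        with pytest.raises(InvalidNoiseError):
            synthesize_signal(truth, scheme, snr=0.0)
        with pytest.raises(InvalidNoiseError):
            synthesize_signal(truth, scheme, noise_model="poisson")


def test_spherical_mean_matches_powder_average(scheme):
    # direction-sampling error of the 58-point layout is far below 1%
    vi, vc, dai, dae = 0.09, 0.47, 2.28, 1.25
    s = mixture_signal(scheme, vi, vc, dai, dae, orientation=(0.3, -0.5, 0.81))
    for b_smm, sl in scheme.shell_slices().items():
        sampled = s[sl].mean()
        closed = float(dmi.powder_forward(vi, vc, dai, dae, b_smm / 1000.0))
        assert sampled == pytest.approx(closed, rel=0.01)


def test_fa_calibration_round_trip(scheme):
    vi, vc, dai, dae = 0.085, 0.5, 2.28, 1.24
    for target in (0.18, 0.22, 0.28):
        drad = calibrate_drad_for_fa(vi, vc, dai, dae, target, scheme)
        assert 0 < drad < dae
        assert effective_fa(vi, vc, dai, dae, drad, scheme) == pytest.approx(target, abs=1e-4)


def test_fa_calibration_clamps_unreachable_targets(scheme):
    vi, vc, dai, dae = 0.085, 0.5, 2.28, 1.24
    # below the least anisotropic reachable mixture: clamp at the upper bound
    drad = calibrate_drad_for_fa(vi, vc, dai, dae, 0.05, scheme)
    assert drad == pytest.approx(dae - 0.01, abs=1e-9)
    # above the most anisotropic reachable mixture: clamp at the lower bound
    drad = calibrate_drad_for_fa(vi, vc, dai, dae, 0.9, scheme)
    assert drad == pytest.approx(0.05)


def test_make_subject_bundles_consistent_pieces(scheme):
    spec = sample_cohort("met", 2, seed=3)[0]
    subj = make_subject(spec, scheme, shape=(24, 24, 24),
                        snr=30, noise_model="rician")
    assert subj.dwi.data.shape == (24, 24, 24, scheme.n_volumes)
    assert subj.labels.mask(LABEL_EDEMA).any()
    assert np.isfinite(subj.truth.d_rad_extra[subj.labels.mask(LABEL_EDEMA)]).all()


def test_cohort_sampling_is_calibrated_and_deterministic():
    a = sample_cohort("gbm", 30, seed=5)
    b = sample_cohort("gbm", 30, seed=5)
    assert [s.profile for s in a] == [s.profile for s in b]
    iz_vi = np.array([s.profile.v_intra[0] for s in a])
    # quantile sampling pins the sample statistics to the calibration
    assert np.median(iz_vi) == pytest.approx(0.08, abs=0.005)
    assert iz_vi.std() == pytest.approx(0.0297, rel=0.2)
    for s in a:
        s.profile.validate()
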