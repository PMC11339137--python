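import numpy as np
import pytest

from perizone import dmi
from perizone.errors import IdentifiabilityError
from perizone.scheme import fibonacci_directions, make_scheme

from conftest import measured_features, mixture_signal


def dense_sphere_mean(fn, n_pts=20000):
    """Brute-force spherical quadrature of a function of cos(theta)."""
    dirs = fibonacci_directions(n_pts)
    return fn(dirs[:, 2]).mean()   # orientation along z


class TestPowderForward:
    def test_b_zero_is_one(self):
        assert dmi.powder_forward(0.1, 0.3, 2.3, 1.2, 0.0) == pytest.approx(1.0)

    def test_pure_csf(self):
        assert dmi.powder_forward(0.0, 1.0, 2.3, 1.2, 1.0) == pytest.approx(
            np.exp(-3.0), rel=1e-12)

    def test_pure_stick_closed_form(self):
        # sqrt(pi/(4 b D)) erf(sqrt(b D)) for b = 1, D = 2
        from scipy.special import erf
        expect = np.sqrt(np.pi / 8.0) * erf(np.sqrt(2.0))
        assert dmi.powder_forward(1.0, 0.0, 2.0, 1.0, 1.0) == pytest.approx(expect)
        assert expect == pytest.approx(0.598, abs=5e-4)

    @pytest.mark.parametrize("b", [1.0, 2.0])
    def test_mixture_matches_dense_quadrature(self, b):
        vi, vc, dai, dae = 0.09, 0.47, 2.28, 1.25
        drad = float(dmi.tortuosity_drad(vi, vc, dae))
        ve = 1 - vi - vc

        def f(t):
            c2 = t ** 2
            return (vc * np.exp(-3 * b) + vi * np.exp(-b * dai * c2)
                    + ve * np.exp(-b * (drad + (dae - drad) * c2)))
        assert dmi.powder_forward(vi, vc, dai, dae, b) == pytest.approx(
            dense_sphere_mean(f), abs=1e-4)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            dmi.powder_forward(0.1, 0.3, 2.3, 1.2, -1.0)


class TestSecondMomentForward:
    @pytest.mark.parametrize("b", [1.0, 2.0])
    def test_rms_matches_dense_quadrature(self, b):
        vi, vc, dai, dae = 0.08, 0.48, 2.29, 1.22
        drad = float(dmi.tortuosity_drad(vi, vc, dae))
        ve = 1 - vi - vc

        def f(t):
            c2 = t ** 2
            s = (vc * np.exp(-3 * b) + vi * np.exp(-b * dai * c2)
                 + ve * np.exp(-b * (drad + (dae - drad) * c2)))
            return s ** 2
        assert dmi.rms_powder_forward(vi, vc, dai, dae, b) == pytest.approx(
            np.sqrt(dense_sphere_mean(f)), abs=1e-5)

    def test_powers_match_sampled_sh_fit(self, scheme):
        vi, vc, dai, dae = 0.085, 0.5, 2.28, 1.24
        s = mixture_signal(scheme, vi, vc, dai, dae, orientation=(0.2, 0.7, 0.68))
        rms, p2, p4 = measured_features(scheme, s)
        for k, b in enumerate(scheme.shells_ms_um2):
            assert rms[k] == pytest.approx(
                float(dmi.rms_powder_forward(vi, vc, dai, dae, b)), abs=2e-4)
            assert p2[k] == pytest.approx(
                float(dmi.rms_sh_power_forward(vi, vc, dai, dae, b)), abs=1e-3)
            assert p4[k] == pytest.approx(
                float(dmi.rms_sh4_power_forward(vi, vc, dai, dae, b)), abs=1e-3)


class TestSphericalMean:
    def test_isotropic_voxel(self, scheme):
        d = 1.1
        sig = np.exp(-scheme.bvals() / 1000.0 * d).reshape(1, 1, 1, -1)
        sm = dmi.spherical_mean(sig, scheme)
        np.testing.assert_allclose(sm.means[:, 0],
                                   np.exp(-np.array([1.0, 2.0]) * d), rtol=1e-12)

    def test_matches_powder_forward_on_phantom_voxel(self, scheme):
        vi, vc, dai, dae = 0.09, 0.47, 2.28, 1.25
        sig = mixture_signal(scheme, vi, vc, dai, dae,
                             orientation=(0.5, 0.5, 0.707)).reshape(1, 1, 1, -1)
        sm = dmi.spherical_mean(sig, scheme)
        for k, b in enumerate(scheme.shells_ms_um2):
            assert sm.means[k, 0] == pytest.approx(
                float(dmi.powder_forward(vi, vc, dai, dae, b)), rel=0.01)

    def test_zero_s0_voxel_invalid(self, scheme):
        sig = np.zeros((1, 1, 1, scheme.n_volumes))
        sm = dmi.spherical_mean(sig, scheme)
        assert not sm.valid[0]

    def test_single_shell_rejected(self):
        scheme1 = make_scheme(2, 6, (0, 1000))
        with pytest.raises(IdentifiabilityError):
            dmi.spherical_mean(np.ones((1, 1, 1, 8)), scheme1)


class TestFitVoxel:
    def _fit(self, scheme, vi, vc, dai, dae, preset="fine"):
        # exact rotation-invariant features of the mixture (generator -> fit
        # self-consistency; finite-direction sampling effects are covered by
        # the zone-level and rotation tests)
        f = np.asarray(dmi.model_features(vi, vc, dai, dae, scheme.shells_ms_um2))
        return dmi.fit_voxel(f[:2], f[2:4], f[4:], scheme.shells_ms_um2,
                             grid_preset=preset)

    def test_pure_csf_identified(self, scheme):
        res = self._fit(scheme, 0.0, 1.0, 2.3, 1.2)
        assert res["v_csf"] >= 0.99

    def test_operating_point_recovery(self, scheme):
        # inner-zone GBM-like parameters
        res = self._fit(scheme, 0.08, 0.48, 2.29, 1.22)
        assert abs(res["v_intra"] - 0.08) <= 0.02
        assert abs(res["v_csf"] - 0.48) <= 0.02
        assert abs(res["d_ax_intra"] - 2.29) <= 0.05
        assert abs(res["d_ax_extra"] - 1.22) <= 0.05

    def test_vcsf_monotonicity(self, scheme):
        ests = [self._fit(scheme, 0.08, vc, 2.28, 1.24, preset="coarse")["v_csf"]
                for vc in (0.30, 0.40, 0.50, 0.60, 0.70)]
        assert np.all(np.diff(ests) > -0.02)

    def test_rotation_leaves_estimates_unchanged(self, scheme):
        outs = []
        for n in [(0, 0, 1), (0.8, -0.36, 0.48), (0.577, 0.577, 0.577)]:
            s = mixture_signal(scheme, 0.09, 0.47, 2.28, 1.25, orientation=n)
            rms, p2, p4 = measured_features(scheme, s)
            r = dmi.fit_voxel(rms, p2, p4, scheme.shells_ms_um2, grid_preset="coarse")
            outs.append([r["v_intra"], r["v_csf"], r["d_ax_intra"], r["d_ax_extra"]])
        outs = np.array(outs)
        spread = outs.max(axis=0) - outs.min(axis=0)
        assert np.all(spread <= [0.02, 0.02, 0.12, 0.06])

    def test_out_of_range_features_invalid(self, scheme):
        res = dmi.fit_voxel([1.5, 1.4], [0.01, 0.01], [0.005, 0.005],
                            scheme.shells_ms_um2, grid_preset="coarse")
        assert not res["valid"]


def test_sampled_features_accuracy(scheme):
    """With 58-direction sampled features, the stiff axial intra-axonal
    diffusivity is recovered to about +-0.1; the other parameters stay
    within grid resolution."""
    truth = (0.08, 0.48, 2.29, 1.22)
    s = mixture_signal(scheme, *truth, orientation=(0.3, -0.4, 0.866))
    rms, p2, p4 = measured_features(scheme, s)
    r = dmi.fit_voxel(rms, p2, p4, scheme.shells_ms_um2, grid_preset="fine")
    assert abs(r["v_intra"] - truth[0]) <= 0.02
    assert abs(r["v_csf"] - truth[1]) <= 0.03
    assert abs(r["d_ax_intra"] - truth[2]) <= 0.12
    assert abs(r["d_ax_extra"] - truth[3]) <= 0.06


def test_noise_free_identifiability_grid(scheme):
    """Posterior recovery within two grid steps over the published ranges."""
    hf, hd = dmi.GRID_PRESETS["fine"]
    worst = np.zeros(4)
    for vi in np.linspace(0.07, 0.12, 3):
        for vc in np.linspace(0.46, 0.49, 3):
            for dai in np.linspace(2.27, 2.30, 3):
                for dae in np.linspace(1.19, 1.27, 3):
                    f = np.asarray(dmi.model_features(
                        vi, vc, dai, dae, scheme.shells_ms_um2))
                    r = dmi.fit_voxel(f[:2], f[2:4], f[4:], scheme.shells_ms_um2,
                                      grid_preset="fine")
                    err = np.abs(np.array([r["v_intra"], r["v_csf"],
                                           r["d_ax_intra"], r["d_ax_extra"]])
                                 - [vi, vc, dai, dae])
                    worst = np.maximum(worst, err)
    assert np.all(worst <= [2 * hf, 2 * hf, 2 * hd, 2 * hd]), worst


def test_noisy_median_tracks_noise_free_estimate(scheme):
    """SNR-30 Rician repetitions: median estimate within a grid step of the
    noise-free estimate (allowing for the sampling error of the median)."""
    truth = (0.08, 0.48, 2.29, 1.22)
    s = mixture_signal(scheme, *truth)
    rms, p2, p4 = measured_features(scheme, s)
    nf = dmi.fit_voxel(rms, p2, p4, scheme.shells_ms_um2, grid_preset="coarse")

    s0, snr, reps = 500.0, 30.0, 200
    rng = np.random.default_rng(42)
    S = np.broadcast_to(s0 * s, (reps, s.size)).copy()
    sg = s0 / snr
    noisy = np.sqrt((S + rng.normal(0, sg, S.shape)) ** 2
                    + rng.normal(0, sg, S.shape) ** 2)
    maps = dmi.fit_volume(noisy.reshape(reps, 1, 1, -1), scheme,
                          grid_preset="coarse")
    hf, hd = dmi.GRID_PRESETS["coarse"]
    for name, step in (("v_intra", hf), ("v_csf", hf),
                       ("d_ax_intra", hd), ("d_ax_extra", hd)):
        vals = getattr(maps, name).ravel()
        med = np.nanmedian(vals)
        iqr = np.nanpercentile(vals, 75) - np.nanpercentile(vals, 25)
        se_med = 1.253 * (iqr / 1.349) / np.sqrt(reps)
        assert abs(med - nf[name]) <= step + 3 * se_med, name


def test_fit_zones_recovers_zone_parameters(scheme):
    """Zone-level fits on a hard-zone phantom, noise-free and at SNR 30."""
    from perizone.phantom import PhantomSpec, assign_microstructure, \
        make_labels, synthesize_signal
    from perizone.profiles import ZoneProfile
    from perizone import zonation
    prof = ZoneProfile(v_intra=(0.08, 0.085, 0.09), v_csf=(0.48, 0.475, 0.47),
                       d_ax_intra=(2.29, 2.285, 2.28), d_ax_extra=(1.22, 1.225, 1.23))
    spec = PhantomSpec(shape=(28, 28, 28), r_core_mm=5.0, r_edema_mm=12.0, seed=9)
    labels = make_labels(spec)
    truth = assign_microstructure(labels, prof, orientation=(0.4, 0.2, 0.89))
    parc = zonation.parcellate(labels.mask(1), labels.mask(2), labels.spacing,
                               margin_vox=0)
    masks = {z: parc.zone_mask(z) for z in ("IZ", "MZ", "OZ")}
    for noise, tol_f, tol_d in (("none", 0.005, 0.02), ("rician", 0.02, 0.06)):
        dwi = synthesize_signal(truth, scheme, snr=30, seed=5, noise_model=noise)
        zfit = dmi.fit_zones(dwi.data, scheme, masks,
                             rician_correct=(noise == "rician"))
        for i, z in enumerate(("IZ", "MZ", "OZ")):
            assert zfit[z]["v_intra"] == pytest.approx(prof.v_intra[i], abs=tol_f)
            assert zfit[z]["v_csf"] == pytest.approx(prof.v_csf[i], abs=tol_f)
            assert zfit[z]["d_ax_extra"] == pytest.approx(prof.d_ax_extra[i], abs=tol_d)
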