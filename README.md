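# perizone

Zone-resolved diffusion-MRI analysis of peritumoral edema.

Glioblastoma (GBM) infiltrates the T2-hyperintense tissue that surrounds its
contrast-enhancing core, while brain metastases are mostly surrounded by
purely vasogenic edema. `perizone` implements the analysis used to probe
this difference *in vivo*: the edema mask is split into three equal-volume
shells by Euclidean distance from the enhancing-tumor outline — inner (IZ),
middle (MZ) and outer (OZ) zone — and diffusion metrics are compared across
zones and between patient groups. Because clinical DWI of this kind is not
openly available, the package also ships a synthetic-data generator that
produces two-shell DWI phantoms with known zone-wise microstructure,
calibrated to published group statistics, so the whole pipeline is testable
end to end with ground truth.

## What it computes

* **DTI** — ordinary log-linear tensor fit on the b = 0 and 1000 s/mm²
  volumes, yielding fractional anisotropy FA = √(3/2)·√(Σ(λᵢ−MD)²)/√(Σλᵢ²)
  and mean diffusivity MD = (λ₁+λ₂+λ₃)/3.
* **DMI** (diffusion microstructure imaging) — a three-compartment
  stick–zeppelin–ball model: intra-axonal water diffuses only along the
  axon (fraction V_intra, axial diffusivity D_ax_intra), extra-axonal water
  diffuses both along and across it (D_ax_extra, radial value from a
  tortuosity closure), and free fluid (V_CSF) diffuses isotropically with
  D = 3 µm²/ms fixed. Fitting is Bayesian over a bounded parameter grid
  using rotation-invariant features of the squared signal (spherical mean
  and ℓ = 2, 4 spherical-harmonic powers per shell), followed by a
  projected Levenberg–Marquardt polish; V_extra = 1 − V_intra − V_CSF.
* **Zonation** — sampled exact Euclidean distance transform from the core
  outline, margin and gray-matter exclusions, equal-volume tertile split
  with a deterministic tie rule.
* **Statistics** — Shapiro–Wilk-gated paired t / Wilcoxon within groups,
  Welch t / Mann–Whitney U between groups on the OZ−IZ gradients, ANCOVA
  (gradient ~ group + edema volume) and demographics (age, sex χ², volume).

## Worked example

```python
from perizone import dti, dmi, phantom, profiles, zonation
from perizone import zone_metrics as zm
from perizone.scheme import make_scheme

acq = make_scheme()                              # 15 b=0 + 2 x 58 dirs, b=1000/2000
spec = profiles.sample_cohort("met", 1, seed=7)[0]
subj = phantom.make_subject(spec, acq, snr=30, calibrate_fa=False)

edema = subj.labels.mask(zonation.LABEL_EDEMA)
parc = zonation.parcellate(subj.labels.mask(zonation.LABEL_CORE), edema,
                           subj.labels.spacing, margin_vox=0)
fa, md = dti.fa_md(dti.fit_tensor(subj.dwi.data, acq, mask=edema))
zfit = dmi.fit_zones(subj.dwi.data, acq,
                     {z: parc.zone_mask(z) for z in ("IZ", "MZ", "OZ")})
```

prints, per zone (one metastasis-like subject, SNR 30 Rician noise):

```
edema volume: 9.56 ml, zones {'IZ': 944, 'MZ': 944, 'OZ': 944}
IZ: FA=0.205  V_intra=0.084  V_csf=0.505  D_ax_intra=2.33  D_ax_extra=1.22
MZ: FA=0.210  V_intra=0.087  V_csf=0.500  D_ax_intra=2.27  D_ax_extra=1.23
OZ: FA=0.218  V_intra=0.090  V_csf=0.496  D_ax_intra=2.24  D_ax_extra=1.24
```

The three zones hold exactly a third of the edema voxels each; the fitted
zone values track this subject's ground truth (IZ V_intra 0.085, V_CSF 0.50,
D_ax_extra 1.24) to within a few thousandths, and the outward D_ax_extra
gradient (+0.02 µm²/ms here) is the kind of contrast the group statistics
then test.

A full two-group study (30 GBM-like, 28 metastasis-like subjects) runs with

```
perizone run --config cfg.yaml --out results_dir
```

writing per-subject NIfTI maps, a tidy `summary.csv`, `stats.csv` and a
markdown report; `perizone simulate`, `fit-dti`, `fit-dmi`, `zonate`,
`summarize` and `analyze` expose the individual stages.

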