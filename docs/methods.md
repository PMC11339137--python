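# Methods

## Scope and data model

The package analyzes the peritumoral T2-hyperintense zone around
contrast-enhancing brain tumors on two-shell diffusion MRI. Inputs for the
analysis stages are a 4D DWI volume with FSL-style bval/bvec tables, a
binary enhancing-core mask and a binary edema mask (co-registration is
assumed). Because suitable patient data are not openly available, the
`phantom`/`profiles` modules generate synthetic subjects with known
ground truth; everything downstream treats synthetic and real inputs
identically.

## Acquisition scheme

The default protocol mirrors a clinical tumor DWI sequence: 15 b = 0
volumes and 58 diffusion directions repeated on shells at b = 1000 and
2000 s/mm² (131 volumes). Directions use a spherical-Fibonacci lattice;
since diffusion signals are antipodally symmetric, full-sphere uniformity
is the relevant design property for even-order spherical-harmonic fits and
powder averages. Internally b is expressed in ms/µm² (b = 1000 s/mm² ≡ 1)
and diffusivities in µm²/ms. The direction count per shell is
configurable; the source protocol's description is ambiguous between 65
total encoding directions and 58 per shell, and the generator defaults to
58 per shell without asserting either reading.

## Phantom generator

Geometry is a spherical enhancing core (default radius 6 mm) inside an
edema shell (outer radius drawn per subject from 12–15 mm) embedded in
white matter on a 32³ grid of 1.5 mm isotropic voxels; an optional
gray-matter shell outside the edema exercises exclusion logic. These
lesions are somewhat smaller than large clinical edemas (≈9–13 ml vs.
≈26–28 ml medians in patients); the choice keeps cohort simulations cheap
while leaving zone statistics unchanged, and all sizes are configurable.

Edema voxels carry zone-dependent microstructure. In the default
hard-zone mode the equal-volume distance tertiles (computed with the same
rule as the analysis-side parcellation) receive constant per-zone values,
so that recovered zone summaries can be compared against calibrated zone
values exactly; a smooth mode interpolates piecewise-linearly from the IZ
value at the core boundary through the MZ value to the OZ value at the
outer boundary.

Per-subject zone values are drawn from normal distributions whose means
and SDs encode the published group statistics (GBM n = 30, metastasis
n = 28): inner-zone level plus OZ−IZ gradient per metric, with
SD = IQR/1.349 where only median [IQR] is published, and one-time
physiologically plausible choices where a group's level is not published
(metastasis V_intra ≈ 0.085, V_CSF ≈ 0.50, D_ax_intra ≈ 2.28). The
default sampling is quantile-stratified: one draw per normal quantile
midpoint, randomly permuted across subjects. This realizes the same
distribution while pinning the finite cohort's sample statistics to the
calibrated population values — the purpose of a calibrated synthetic
cohort; plain i.i.d. sampling is available (`sampling="random"`).

The DWI signal per voxel is the stick–zeppelin–ball mixture

S/S0 = V_CSF·e^(−3b) + V_intra·e^(−b·D_ax_intra·cos²θ) +
V_extra·e^(−b·[D_rad + (D_ax_extra−D_rad)·cos²θ])

with a single fiber orientation per subject (drawn at random; all
estimators downstream are rotation-invariant or rotation-equivariant).
D_rad defaults to the tortuosity closure
D_rad = D_ax_extra·(1 − V_intra/(V_intra+V_extra)). Noise is Rician with
σ = S0/SNR, default SNR 30 at b = 0; Gaussian and noise-free modes exist
for analytic checks. Identical seeds give bit-identical volumes.

**FA calibration.** DTI anisotropy is not an independent input of the
mixture, so cohorts whose FA gradients must match published values
calibrate the per-zone D_rad by root-finding on the *effective* FA — the
FA the log-linear DTI fit returns on the noise-free mixture. This
deliberately departs from the tortuosity closure that the microstructure
fit assumes; it is therefore a per-cohort switch (`calibrate_fa`): on for
FA-gradient studies, off (pure closure) when microstructure-parameter
recovery is being assessed. Targets outside the reachable FA range are
clamped to the nearest bound.

What the generator does **not** emulate: real anatomy (gyri, white-matter
tracts, multiple lesions), partial-volume mixing at acquisition resolution
(1.5×1.5×3 mm acquisition with upsampling is out of scope; data are
generated clean at isotropic resolution), orientation dispersion and
fiber crossings, eddy/susceptibility artifacts, and spatially correlated
noise. Passing tests therefore demonstrate correctness of the estimators
and statistics under the stated model, not robustness to those realities.

## DTI stage

Ordinary least squares on ln S over the b = 0 and b = 1000 volumes (the
b = 2000 shell is excluded even when present), seven unknowns (ln S0 and
the six tensor elements). Voxels with non-positive signal are flagged
invalid rather than failing the fit. For FA, negative eigenvalues are
clipped to zero (count recorded and logged); MD uses the raw eigenvalues.
On mono-exponential signals the fit is exact to machine precision.

## Microstructure (DMI) stage

Estimation uses rotation-invariant features of the *squared* magnitude
signal per shell: its spherical mean and its ℓ = 2 and ℓ = 4
spherical-harmonic powers (measured by least-squares SH fit up to ℓ = 4 on
the 58 directions). Three design decisions matter:

1. **Second moments instead of mean-signal Rician corrections.** Under
   magnitude noise E[M²] = S² + 2σ² exactly, at any SNR, so squared
   features are debiased by subtracting the noise floor (σ estimated from
   the b = 0 spread; σ² for plain Gaussian noise). First-moment
   corrections such as √(M²−2σ²) per volume retain concavity bias at the
   b = 2000 per-volume SNR (≈2–3) that a sharp likelihood would otherwise
   chase. The squared mixture is again a sum of exp(−x·cos²θ) kernels
   (pairwise compartment products), so spherical means and SH powers stay
   closed-form via I0(x) = √(π/4x)·erf(√x) and its Legendre projections.
2. **Six features for four parameters.** Spherical means alone (two
   numbers) are underdetermined; means + ℓ = 2 powers admit exact
   "mimic" solutions along a stiff valley of the feature map. The ℓ = 4
   powers overdetermine that valley. The admissible set is additionally
   restricted to the biophysical branch D_ax_intra ≥ D_ax_extra, which
   removes the classical swapped-compartment duplicate of stick–zeppelin
   mixtures.
3. **Grid posterior plus local polish.** A Gaussian likelihood of the
   features is evaluated on a bounded lattice (uniform prior; default
   steps 0.02 on the fraction simplex and 0.05 on (0,3] µm²/ms, a coarse
   0.04/0.10 preset for volume work). Because the feature map is stiff in
   D_ax_intra at realistic V_intra, the discrete posterior smears along a
   valley; the estimator therefore polishes the best cells (a few diverse
   starts, ranked under a discretization-aware variance) with a projected
   Levenberg–Marquardt iteration with per-voxel adaptive damping. On
   noise-free input this recovers continuous parameters essentially
   exactly; `refine=False` returns the plain grid posterior mean.

**Zone-level estimates.** The pipeline's zone summaries for the DMI
metrics come from ROI-level fits (`fit_zones`): the debiased squared
signal is averaged over each zone's voxels before feature extraction,
raising the effective feature SNR by √N (≈30-fold for ≈900-voxel zones).
The zone's fiber orientation is estimated from the averaged directional
profile, and the refinement evaluates the forward model through the same
discrete 58-direction sampling operator as the measurement, removing the
≈3·10⁻⁴ closed-form-vs-sampling representation mismatch that the stiff
inversion would otherwise amplify to ≈0.03–0.05 µm²/ms errors in
D_ax_extra. Per-voxel maps remain available (and are written by the CLI),
but at clinical SNR their posterior estimates carry parameter-coupled
biases of the order of the zone contrasts themselves, which is why zone
summaries are not computed by aggregating them. This mirrors established
ROI-based practice in microstructure imaging.

Known limitations: per-voxel D_ax_intra is only weakly identified at low
V_intra (orientation-dependent accuracy ≈±0.1 noise-free, broad scatter
under noise); per-voxel V_CSF and D_ax_extra are noticeably biased at
SNR 30 even though zone-level values are accurate; accuracy degrades for
parameter combinations far outside the calibrated regime (e.g.
D_ax_intra ≈ D_ax_extra, where the model family is genuinely degenerate).

## Zonation

Margin exclusion removes edema voxels within a configurable number of
face-connected dilation steps of the core (module default 1) and voxels
face-adjacent to gray matter, with per-reason tallies. Distances are a
sampled exact Euclidean distance transform of the core complement
(anisotropy-aware); "Euclidean expansion within the mask" is implemented
as this restricted EDT, which coincides with a geodesic expansion for
shell-like edema. Included voxels are sorted by (distance, flat index)
with a stable sort and cut into equal thirds, remainder voxels innermost
first — deterministic under any traversal order. The cohort pipeline runs
with margin 0 by default: synthetic phantoms have no partial-volume
contamination, which is what the margin guards against in patients; the
exclusion logic is exercised separately with GM-bearing phantoms.

## Zone summaries and statistics

Per-subject zone scalars use the voxel mean by default (median available)
for the DTI maps and the ROI fits for DMI metrics; gradients are reported
as MZ−IZ and OZ−IZ, normalized to the inner zone. Edema volume is counted
both after exclusions (used as the ANCOVA covariate) and before.

The statistical battery applies a Shapiro–Wilk gate at α = 0.05 (on
paired differences within groups, per-group samples between groups;
constant input counts as non-normal): paired t vs. Wilcoxon signed-rank
(Pratt zero handling), Welch t (Student optional) vs. Mann–Whitney U, an
OLS ANCOVA gradient ~ group + edema volume reporting the group effect
(constant covariates are dropped with a note), and demographics with a
2×2 χ² without continuity correction — the convention that reproduces the
published p = 0.74 for the 18/12 vs. 18/10 sex table; Yates' correction is
available. No multiple-testing correction is applied (single-test α =
0.05 throughout); a Holm helper exists but is off by default.

## Reproducibility and problem sizes

Every stage seed is derived as SHA-256(global seed / stage / subject) mod
2³¹, so full runs are deterministic given the configuration (byte-identical
summary tables). Default cohort sizes are 30 + 28 subjects on 32³ grids;
a full two-group run takes well under a minute for the summary pathway and
a few minutes when per-voxel microstructure maps are also written. The
acceptance script (`scripts/acceptance.py`) regenerates both cohorts and
the analytic checks from scratch in about one minute.
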