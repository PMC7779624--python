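# Methods

`glymphiron` implements, end to end, the computation that links deep-nucleus
iron deposition to glymphatic function in a cross-sectional cohort: a
quantitative susceptibility mapping (QSM) chain for iron quantification, the
DTI-ALPS index as a glymphatic proxy, the cohort statistics relating them,
and a calibrated synthetic-data generator that makes every stage testable
without any image download. This note records the models, the parameters
that matter, and the design choices made where the method family leaves the
details open.

## Susceptibility chain

**Physical model.** A susceptibility distribution chi(r) (ppm) shifts the
resonance field by the spectral convolution

    delta_B(k) = D(k) chi(k),   D(k) = 1/3 - (k . b0)^2 / |k|^2,

the Lorentz-corrected unit dipole response. Gradient-echo phase accumulates
as `phi = 2 pi gamma B0 TE * 1e-6 * delta_B_ppm` with TE in seconds and
gamma = 42.576 MHz/T. The chain divides phase by `2 pi TE` (raw frequency
map, Hz), normalises by `gamma B0` (ppm), removes the background field, and
inverts the dipole convolution.

Phase is assumed already unwrapped. Rather than silently unwrapping, the
frequency step *errors* when neighbouring in-mask voxels jump by more than
pi — in the synthetic regime wraps never occur by construction, and on real
data this check is the guard against feeding wrapped phase downstream.

**Background removal (SHARP / V-SHARP).** Fields from sources outside the
brain are harmonic inside it and therefore satisfy the spherical mean value
(SMV) property: convolving with any normalised sphere kernel `rho_r`
reproduces the field, so `(delta - rho_r) * f` annihilates the background
while passing internal-source structure. We use a descending radius schedule
(default 5, 4, 3, 2, 1 mm): each voxel takes the largest radius whose sphere
fits inside the mask, so the usable region extends to within the *smallest*
radius of the edge (the V-SHARP construction). The combined high-pass field
is deconvolved by `1 - S(k)` of the largest kernel, truncated at the
threshold by *clamping*: where `|1 - S| < 0.05` the inverse uses the
threshold instead (`sign(1-S)/max(|1-S|, 0.05)`), keeping attenuated
low-frequency local-field content rather than discarding it — measurably
more accurate than zeroing on the nucleus round trip (both the schedule and
the threshold are configurable). The
mask is eroded by `ceil(min(radii)/voxel)` voxels by default — one voxel at
the default grid — because no kernel is defined closer to the edge. Eroding
by the *largest* radius instead is supported via the `erosion` parameter but
discards an edge shell that measurably degrades downstream nucleus recovery
(putamen round-trip recovery drops from ~0.96 to ~0.93 on the noiseless
phantom, and the smallest nuclei below 0.9).

**Dipole inversion (LSQR).** The kernel is undefined at k = 0; we set
D(0) = 0, leaving the volume mean of chi unobservable, and re-reference all
maps to the brain-mask mean afterwards. The inversion solves
`min_chi || D * chi - f ||` over the full grid with `f` equal to the local
field inside the eroded mask and zero outside — the standard "zero-filled"
LSQR formulation. The zero-filling matters: if the fit is made blind to the
exterior (residual masked to the brain), the minimiser can push
susceptibility into configurations whose fields vanish inside the
observation region, and on the noiseless nucleus phantom such a fit
*converges* to only ~70% nucleus-mean recovery. Treating the (rapidly
decaying) exterior local field as zero suppresses that null space; the same
phantom then recovers 93–97% per nucleus. LSQR runs unpreconditioned,
matrix-free (two real FFT pairs per iteration), with defaults
`max_iter = 50`, `atol = 1e-6`; iteration count and residuals are logged,
and hitting the cap is a warning, not an error — the remaining misfit lives
in the slowly converging near-magic-angle modes that plain least-squares
QSM deliberately leaves regularised.

**ROI quantification.** Nucleus means pool every voxel carrying a label,
across slices and hemispheres (the bilateral pairs share one label). Values
are reported in 1e-3 ppm, positive = paramagnetic (iron-rich), referenced
to the brain-mask mean. Whether published deep-nucleus values are referenced
to CSF, to white matter or to the whole brain is rarely stated; the
mask-mean convention is declared here and the simulator encodes its ground
truth on the same scale (see below).

## DTI-ALPS

At the level of the lateral-ventricle body, medullary veins and their
perivascular spaces run left-right (x), projection fibres superior-inferior
(z), association fibres anterior-posterior (y). Diffusivity along x inside
projection- and association-fibre ROIs is then perpendicular to both fibre
populations, and its excess over the true cross-fibre diffusivities is
attributed to perivascular (glymphatic) water movement:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc).

Tensors are fitted by unweighted log-linear least squares
(`ln S = ln S0 - b g^T D g`, S0 estimated jointly; a signal-squared-weighted
variant is available as an option). Voxels with non-positive signal are
flagged invalid and excluded from ROI means; negative eigenvalues are
flagged, never clipped (FA alone is clipped to [0, 1] for the colour map).
The two ROIs are 5-mm-diameter in-plane disks (a voxel belongs if its centre
is within 2.5 mm); their centres are explicit inputs — placement was a
radiological judgement in the original procedure, and no attempt is made to
automate it. The index uses per-ROI means; with the two-term numerator and
denominator each averaging one value per ROI, pooled-voxel and per-ROI-mean
readings coincide for the quantities reported here. Only the left hemisphere
is modelled, matching the original construction.

## Cohort statistics

Spearman's rho is the Pearson correlation of mid-ranks, implemented from
first principles and validated against scipy in the tests. Two-sided
p-values use the t approximation `t = r sqrt((n-2)/(1-r^2))` for n > 8 and
the exhaustive n! permutation distribution below that (the boundary is set
by runtime: 8! = 40,320 evaluations is instant, 9! is not). The seven
nucleus-vs-ALPS tests form a Bonferroni family: threshold `alpha/7`, i.e.
0.007 at alpha = 0.05.

Adjusted models z-score the outcome (nucleus susceptibility) and every
predictor, then solve the normal equations; coefficients are standardised
betas and p-values use t with `n - k - 1` degrees of freedom, matching an
intercept-carrying fit. Model A adjusts ALPS for age; model B additionally
for WMH volume and the two atrophy ordinals (entered as numeric 0/1/2).
Missing data are handled complete-case per analysis, with exclusions logged.

## Synthetic data

The generator defines the study conditions; all defaults are fixed once.

**Susceptibility phantom** (64^3 at 1 mm, configurable): an ellipsoidal
brain mask (semi-axes 28/26/24 mm) containing seven *bilateral* nucleus
ellipsoids of a few hundred voxels each (~4% of the mask), plus spherical
susceptibility sources *outside* the mask (1.5 and -1.0 ppm) that stand in
for the air/bone interfaces whose harmonic in-mask fields SHARP must remove.
Source strengths are capped so the synthetic phase stays wrap-free
(neighbour jumps well below pi), consistent with the no-unwrapping design.
Phase noise is Gaussian with SD = 1% of the noiseless phase range.
Because reconstructed chi is referenced to the brain-mask mean, the painter
adds a closed-form offset `m = sum_i f_i t_i / (1 - F)` (f_i = nucleus
volume fractions, t_i = assigned values) to every nucleus so that
*mask-mean-referencing the painted truth reproduces the assigned values
exactly* — the phantom's ground truth lives on the same scale the pipeline
reports. Acquisition defaults: TE 11.5 ms at 3 T (the SWI protocol).

**Diffusion phantom** (48^3 at 2 mm): three compartments — isotropic
background (0.7e-3 mm^2/s), a projection-fibre block (principal axis z,
1.4e-3; cross-fibre y 0.5e-3) and an association-fibre block (principal
axis y 1.4e-3; z 0.5e-3). A latent glymphatic factor g in [0, 1] sets the
perivascular diffusivity of both blocks to `g * 1.0e-3`, making the analytic
index exactly `ALPS = 2 g` — a strictly monotone link used for round-trip
assertions. Signals are mono-exponential (`S0 exp(-b g^T D g)`, one b = 0
plus 30 quasi-uniform directions at b = 2000 s/mm^2, the DTI protocol) with
Rician noise at SNR 30 (magnitude-MRI physics; Gaussian available). At SNR
30 the log-linear fit's median per-component error is ~4–6% per voxel and
its bias is below 2%, measured by the test-suite simulation.

**Cohort** (n = 213 default, 107 women): age is truncated-normal on
[43, 80] whose *post-truncation* moments are calibrated to exactly
60.1 / 7.3 years (the parent parameters are solved numerically; naive
truncation of N(60.1, 7.3) would shrink the SD to ~7.1). A single latent
glymphatic variable `z_g = alpha z_age + sqrt(1-alpha^2) eps` induces the
entire correlation structure; ALPS = 1.4 + 0.2 z_g (clipped to [0.6, 2.0] so
every subject maps to a valid diffusion phantom via g = ALPS/2 — a ±4 SD
clip). Each nucleus latent is `beta z_age + gamma z_g + delta eps_i`, with
(beta, gamma) solved from the published rank correlations of that nucleus
with age and with ALPS after converting Spearman targets to latent Pearson
loadings by the Gaussian-copula identity `rho_p = 2 sin(pi rho_s / 6)`;
infeasible target patterns are rejected before sampling. Nucleus margins use
the published means/SDs (1e-3 ppm). WMH volume is a left-truncated normal
calibrated to 9.7 ± 6.8 before truncation (moment-approximate afterwards;
units assumed mL) with an assumed weak age
loading of 0.3; atrophy scores tertile-cut the latent
`(z_age + eps)/sqrt(2)`, giving median 1 on the 0/1/2 scale. In image mode
the generator emits per-subject phantom specs whose ground truths equal the
tabulated row (nucleus values become painted susceptibilities; ALPS becomes
g = ALPS/2), so image-measured and tabulated quantities are directly
comparable.

**What the phantoms do not emulate:** real anatomy and partial volume,
susceptibility anisotropy and microstructural dephasing, eddy-current and
motion artefacts, phase wraps, crossing fibres, spatially varying coil
sensitivity. Tests passing on these phantoms validate the *algorithms*
(geometry handling, spectral operators, estimators, statistics), not
robustness to those real-data effects.

## Problem sizes and runtime

The acceptance computation measures 213 subjects per chain: DWI at the
48^3 / 2 mm default and QSM at the 64^3 / 1 mm default (~0.8 s per subject,
dominated by ~200 real FFTs of the LSQR iterations). The ten-seed
correlation replication runs its susceptibility chains at 32^3 / 2 mm with
tensor fitting restricted to the ALPS disks — rank correlations are
insensitive to the grid scale-down, and this keeps the ten-fold repetition
at desk scale. All random draws flow from explicit integer seeds through
`numpy.random.default_rng`; identical spec + seed reproduces outputs
bit-for-bit.

## Numerical notes and edge cases

- All spectral operators use real FFTs on the grid implied by the voxel
  size, array centre as spatial origin, periodic boundaries; B0 defaults to
  the third array axis.
- The SMV reliability criterion (`mask * rho_r >= 1 - 1e-6`) marks voxels
  whose whole sphere lies in the mask; a voxel supported by no radius is
  dropped from the eroded mask rather than filled with an unreliable value.
- Disk ROIs smaller than one voxel degenerate to the centre voxel; disks
  that exit the volume are an error, not a silent crop.
- A constant vector makes Spearman undefined (error); rank-deficient designs
  name the collinear columns.
- Eroding the mask to emptiness, overlapping nuclei, background sources
  intersecting the mask, and non-SPD prescribed tensors are all rejected
  with specific messages before any computation runs.

## Known limitations

- Plain (unregularised) LSQR inversion under-recovers nucleus means by
  ~3–7% even noiselessly — the price of leaving near-cone modes
  unregularised; edge-of-mask nuclei suffer most. Regularised inversions
  (MEDI-family) are out of scope.
- The one-factor cohort model reproduces the published *pairwise* structure
  (each nucleus vs age and ALPS) but implies, rather than matches,
  nucleus-nucleus correlations, which the source does not report.
- Covariate interrelations (WMH vs age, atrophy vs ALPS) are assumptions
  labelled as such; the adjusted-model betas computed on simulated cohorts
  therefore test the estimator, not the published adjusted effect sizes.
- Ordinal atrophy enters models as numeric 0/1/2 (a categorical coding
  exists but is off by default, matching the single-beta-per-covariate
  reporting convention).
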