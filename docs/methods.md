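# Methods

`hemiacm` implements hemisphere-restricted anatomical connectivity mapping
(ACM) end to end on synthetic diffusion-MRI phantoms: a voxel-wise count of
how many probabilistic streamlines, seeded throughout the white matter (WM)
of one hemisphere, pass through each voxel, together with the region-of-
interest (ROI), lateralization, and permutation statistics used to compare
patient groups. This note records the model, its assumptions, the defaults
and why they were chosen, and what the synthetic experiments do and do not
demonstrate.

## The phantom and its forward model

A phantom is a labeled voxel grid (default 40×40×40 voxels at 2 mm
isotropic, matching a typical clinical diffusion acquisition) split by a
single mid-sagittal voxel plane at x-index `nx // 2`; voxels left of the
plane form the left hemisphere, right of it the right hemisphere, and no
fiber population is ever placed on the plane itself. Each hemisphere
carries two tubular bundles:

* a **vertical bundle** spanning the full grid height — the corticospinal-
  tract (CST) analogue, radius 5 mm;
* an **oblique crossing bundle** through the vertical bundle's midpoint at
  40° from vertical (radius 4 mm) — the analogue of association tracts that
  cross the CST.

The crossing angle is deliberately below the tracker's 45° per-step
curvature limit. Streamline re-routing between bundles — the mechanism by
which crossing-fibre damage raises CST streamline counts — is geometrically
impossible at a strictly perpendicular crossing under any sub-90° turn
limit, in this implementation as in standard tractography packages.
Perpendicular crossings can still be constructed through `BundleSpec` and
are used in construction tests.

Each voxel holds up to three fiber populations (unit direction +
amplitude). A bundle contributes its `volume_fraction` (default 0.5) as
amplitude; the remaining fraction is an isotropic compartment. Two kinds of
damage reduce amplitudes:

* **focal lesions** (`visible=True`): spherical, damage every population in
  the voxel, and enter the lesion mask (hence are excluded from
  normal-appearing white matter, NAWM);
* **diffuse degeneration** (`visible=False`, usually targeted at one
  bundle): reduces that bundle's amplitude without appearing in the lesion
  mask, modeling axonal degeneration that is invisible on structural
  imaging.

The diffusion-weighted signal is a multi-tensor mixture,

S(b, g) = scale_shell · S0 · [ Σ_k f_k · exp(−b gᵀ D_k g) + f_iso · exp(−b d_iso) ],

with axially symmetric population tensors (axial diffusivity 1.7·10⁻³,
radial 0.3·10⁻³ mm²/s — healthy WM values), an isotropic background
(0.9·10⁻³ mm²/s; 3.0·10⁻³ for CSF when a CSF mask is supplied), and
optional Rician noise (magnitude of the complex Gaussian-corrupted signal;
`noise_sd = 0` reproduces the closed form exactly, which the oracle tests
rely on). The default gradient scheme has three shells — 6 directions at
b = 300, 62 at b = 1000, 62 at b = 2000 s/mm², one b0 per shell — with
per-shell scale factors emulating the TE/TR-driven intensity offsets that
shell calibration must remove.

## Shell calibration

The overall mean b0 is the voxel-wise mean of the b = 1000 and b = 2000
shells' b0 images (the low-b shell does not contribute; which b0 sets enter
the average is configurable via `calibration_bvalues`). Each shell's
calibration image is its own b0 divided by the overall mean b0, and every
volume of the shell is divided by it, so all shells share the overall mean
b0 afterwards. Voxels where this is undefined (zero mean b0 or zero shell
b0) are flagged in a QC mask and passed through unchanged rather than
zeroed — flagging preserves information. Calibration is idempotent to
machine precision.

## Tensor fitting

A single diffusion tensor per voxel is fitted by weighted least squares on
log-signals: an ordinary first pass provides predicted signals, and the
second pass weights each observation by the squared predicted signal (the
standard variance correction for log-transformed data). Non-positive
signals are excluded per voxel rather than clamped; voxels with fewer than
seven usable volumes, or a non-positive mean eigenvalue, are marked
`fit_ok = False` and carry zero maps. FA uses the normalized
eigenvalue-dispersion formula (clipped to [0, 1] against rounding); MD is
the mean eigenvalue. A rank-deficient gradient design raises an error
naming the number of distinct directions.

On pure single-tensor voxels (volume fraction 1) the fit recovers the
generating tensor, FA, and MD to better than 10⁻⁸ relative. With a partial
isotropic compartment the signal is bi-exponential and the log-linear
tensor fit is only an effective-medium approximation — its FA/MD then
depend on the b-values used, exactly as in real multi-shell DTI; tests
assert exact recovery only in the single-tensor case.

`extract_peaks` reduces the fit to a one-population orientation field
(principal eigenvector, amplitude = FA, floor 0.1) for tracking fitted
data. Cohort experiments track the phantom's ground-truth multi-peak field
instead: the tracker's contract only needs a populated orientation field,
and the ground truth exercises the crossing behavior that a single-tensor
reduction cannot represent.

## Tracking

From every WM voxel of the chosen hemisphere, `seeds_per_voxel` seeds are
drawn uniformly within the voxel (default 300 — the count shown previously
to give stable ACM estimates; scaled-down runs in tests use 6–30).
Propagation is bidirectional with step size half the voxel size. At each
step:

1. populations of the current voxel are restricted to those whose
   (sign-aligned) direction lies within the 45° curvature cone of the
   incoming direction;
2. one population is drawn with probability proportional to
   `amplitude · |cos(angle to incoming)|` — the discrete-peak analogue of
   sampling a fiber-orientation distribution. In deterministic mode
   (κ = ∞) the highest-weight population is taken, ties to the lowest
   index, which gives the exactly reproducible limit the enumeration
   oracles check;
3. the step direction is drawn from a von Mises–Fisher distribution with
   concentration κ = 30 (≈10° angular spread) around the chosen peak, and
   re-checked against the curvature cone.

A streamline ends when the local maximum population amplitude falls below
0.1, no direction passes the curvature check, it leaves the tracking mask,
or it exceeds 250 mm total (the length budget is shared across both
halves). Any streamline containing a point on the midline plane or in the
contralateral hemisphere is discarded **in full** (exclusion-ROI
semantics), and streamlines shorter than 4 mm are dropped. Launch
accounting is exact: launched = seeds × WM voxels; retained + discarded
(midline, short) = launched.

The ACM counts, per voxel, the number of *distinct* retained streamlines
whose path intersects it — one increment per streamline regardless of how
many steps it spends there; membership is decided point-in-voxel after
supersampling segments at half the step size. Counting per visit instead
of per streamline would double-count slow turns.

Amplitude-proportional selection is what makes the crossing-damage
mechanism work: when the crossing bundle's amplitude drops, both seeds
launched in the intersection and streamlines passing through it
re-route into the intact vertical bundle in proportion to the amplitude
ratio. With deterministic argmax selection the ratio would be irrelevant
and no re-routing could occur.

### Where the crossing-damage effect is measured

Lesioning the crossing bundle (severity 0.9) raises mean ACM over the
vertical bundle by ≈17% (≈23% over its voxels outside the intersection).
At the intersection voxels themselves the net change is approximately
neutral: converted streamlines traverse the intersection about as often as
before, only in a different orientation. The mechanism tests therefore
measure mean ACM over the vertical bundle's mask — the same ROI semantics
as the CST-NAWM means in the group analysis, and the direct reading of
"streamlines expand into and along" the tract. Direct damage to the
vertical bundle (severity 0.9 at mid-height) drops its amplitude below the
tracking threshold and blocks propagation, reducing mean bundle ACM by
≈30%.

## ROI analysis and lateralization

* **NAWM** = WM ∧ ¬lesion ∧ ¬(FA < 0.3): the FA rule removes
  partial-volume voxels; the comparison is a strict `<`, so FA exactly 0.3
  is kept.
* **CST mask** = atlas probability strictly > 0.10, split left/right by
  hemisphere label. The synthetic atlas is the Gaussian-blurred (6 mm
  FWHM) indicator of the lesion-free vertical bundles, peak-normalized — a
  stand-in for a population tract atlas.
* CST-NAWM and non-CST-NAWM partition each hemisphere's NAWM exactly.
* **LI** = 100·(left − right)/(left + right), computed ratio-first and
  clipped so rounding can never push it outside [−100, 100]; positive
  values mean left dominance. Undefined when left + right = 0.
* The slice profile computes, per axial slice, the LI of the per-slice ROI
  means (matching the LI-of-means construction of the whole-ROI index);
  slices with an empty side are flagged undefined and excluded.
* Gaussian smoothing (default 4 mm FWHM) uses reflective boundaries, so
  constant maps are unchanged and interior delta mass is preserved.

All subjects share one phantom grid, so inter-subject registration
collapses to identity by construction; spatial normalization of real data
is upstream of this package.

## Group statistics

* **Fatigue classification**: motor score ≥ 27 → fatigued (FMS), below →
  non-fatigued (NFMS); scores outside the instrument range 10–50 are
  rejected.
* **Repeated-measures ANCOVA**: with exactly two within-subject levels
  (left/right) the model decomposes exactly into two univariate ANCOVAs —
  between-subject effects on the per-subject mean, side and side×group on
  the difference, covariates (age, sex, whole-brain streamline count)
  centred so the difference-model intercept is the side effect at
  covariate means. Effects are nested-model F tests; collinear designs
  raise an error listing the aliased columns; pairwise post-hoc F tests
  run only when the omnibus effect is significant at 0.05.
* **Partial correlation**: both variables are residualized on the
  covariates (with intercept) and the residuals correlated; p from the t
  transform with df = n − k − 2. (Which adjustment the original SPSS
  analyses applied is not documented; residualization is the symmetric,
  reproducible choice.)
* **TFCE**: TFCE(v) = Σ_h e(h,v)^E · h^H · dh over thresholds h = dh, 2dh,
  … ≤ stat(v), with the de facto standard H = 2, E = 0.5, 26-connectivity,
  and dh defaulting to 1/100 of the map's positive maximum. Non-positive
  voxels map to zero (a one-sided positive-contrast statistic).
* **Permutation test**: voxel-wise pooled-variance two-sample t, TFCE
  enhancement, and a max-TFCE null over random relabelings (exhaustive
  when fewer distinct labelings exist than requested permutations; 5000
  requested by default). FWE p values use the (b+1)/(m+1) estimator —
  unbiased under exchangeability and never zero. Because t is
  scale-invariant, p maps are invariant to global positive rescaling of
  the input maps.
* **Slice tests**: per-slice two-sample t on the LI profiles, uncorrected
  p < 0.05, degenerate or undefined slices skipped with a warning.

## The synthetic cohort

`make_cohort` draws three groups (healthy controls HC, fatigued patients
FMS, non-fatigued patients NFMS; default 10 per group) that differ only in
the lateralization of crossing-bundle degeneration:

| parameter | default | rationale |
|---|---|---|
| crossing degeneration mean (L, R) | FMS (0.75, 0.10); NFMS (0.10, 0.75); HC (0, 0) | severity 0.75 leaves the crossing amplitude (0.125) above the 0.1 tracking threshold: damage re-routes streamlines rather than terminating them, isolating the crossing-fibre mechanism |
| between-subject severity SD | 0.10 | clinically plausible heterogeneity without sign flips after clipping to [0, 1] |
| focal lesions per patient | Poisson(5) | disseminated plaques; HC receive none |
| lesion radius / severity | 2–4 mm / 0.6–0.9 | typical MS plaque dimensions at 2 mm resolution; the severity range spans partially to fully blocking |
| lesion lateralization | per-subject Beta(2, 2) left share | wide between-subject variation in lesion asymmetry, independent of group — the substrate of the lesion-load sign test |
| motor fatigue score | 12 + 35·(left severity) + N(0, 3), clipped to the group's side of the 27 cutoff | the score increases with left-crossing damage, so the score–LI correlation has a known positive sign |

Subjects are deterministic functions of the cohort seed; per-stage seeds
derive from one global seed via `SeedSequence` spawning, so a single
integer reproduces the entire experiment.

Against this generator the pipeline recovers, with the default reduced
seeding of 12 seeds/voxel: mean CST ACM-LI of the FMS group above the NFMS
group (separation ≈ 10–12 LI points); a positive partial correlation
between CST ACM-LI and the motor-fatigue score; and a negative partial
correlation between whole-NAWM ACM-LI and lesion-load LI.

## What the phantom does not emulate

Realistic gyrified anatomy, susceptibility/eddy distortions, and head
motion are absent (preprocessing for these is upstream of the method);
fiber dispersion and bottlenecks beyond two discrete crossing populations
are not modeled; lesion placement follows configurable priors rather than
an empirical spatial distribution, since none is available; registration
error is zero by construction. Passing tests therefore demonstrate the
internal correctness and the qualitative mechanism directions of the
method — not that effect sizes on real cohorts would match.

## Problem sizes used by the test suite and acceptance script

Chosen to keep the whole suite within a few minutes on one CPU: mechanism
tests use the full 40³ phantom at 6 seeds/voxel over 10 RNG replicates;
conservation checks run 30 seeds/voxel on the 40³ phantom; cohort
experiments use 10 subjects/group at 12 seeds/voxel; permutation
calibration uses 100 null replicates × 500 permutations on 4³ maps (60 ×
300 in the acceptance script) with dh = 0.15 (the calibration property is
dh-independent); TFCE oracles use 6³ maps with dh = peak/100. The tracker
defaults themselves (300 seeds/voxel, 5000 permutations) remain the
method's reference configuration.

## Known limitations

* The single-peak `extract_peaks` field cannot represent crossings; runs
  on fitted data therefore underestimate crossing effects. This mirrors
  the DTI-vs-CSD distinction in real pipelines and is why cohort runs use
  the ground-truth field.
* ACM counts are launch-density dependent; comparisons are only meaningful
  at fixed `seeds_per_voxel`, which the cohort pipeline enforces.
* The repeated-measures decomposition is exact only for two within-subject
  levels; more levels would require a genuine mixed model.
* Exhaustive permutation enumeration treats the observed labeling as one
  of the enumerated relabelings; with the (b+1)/(m+1) estimator the
  smallest attainable p is 2/(m+1) in that regime.
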