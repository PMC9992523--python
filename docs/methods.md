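# Methods

`habmpm` simulates a quantitative multi-parameter mapping (MPM) study of
the habenula end to end: a synthetic cohort of digital phantoms is imaged
with a three-weighting multi-echo spoiled gradient-echo (FLASH) protocol,
quantitative maps are estimated from the simulated signals, and the
native- and group-space analyses a habenula characterisation study would
run are applied to the results. Because the phantom's tissue parameters
are known exactly, every stage can be validated against ground truth.

## Forward model

Each voxel carries ground-truth longitudinal relaxation rate R1 (1/s),
effective transverse relaxation rate R2* (1/s), water content PD (percent
units, p.u.), magnetisation-transfer saturation δ (p.u.), an effective
amplitude A ∝ PD, a transmit-field fraction f_T and a receive sensitivity
c_RX. The noise-free signal of weighting w at echo time TE is the
steady-state spoiled gradient-echo (Ernst) equation with mono-exponential
decay:

    S_w(TE) = c_RX · A · sin(f_T α_w) · (1 − d_w) (1 − E1)
              / (1 − (1 − d_w) cos(f_T α_w) E1) · exp(−TE · R2*),

with E1 = exp(−TR·R1), nominal flip angle α_w, and d_w the per-TR
fractional saturation of longitudinal magnetisation (zero except for the
MT-weighted scan). Spoiling is assumed ideal; the MT preparation pulse
(4 ms Gaussian, 2 kHz off-resonance, 220°) is carried as metadata, not
simulated mechanistically.

The realised MT saturation depends on the local transmit field through
the empirical linear law

    d = δ · (1 − C·f_T) / (1 − C),   C = 0.4,

which is exactly the relation the standard MTsat transmit-bias correction
inverts. This makes the generative model and the estimator chain mutually
consistent: with a literal `d = δ` the downstream correction would
*introduce* a ±5–8% error at f_T = 0.9/1.1 rather than remove one.

Noise is Rician: independent zero-mean Gaussian noise of SD σ on both
quadrature channels followed by magnitude. σ is set from a target SNR
(default 100), defined as the mean noise-free brain signal of the first
PD-weighted echo divided by σ. A Gaussian noise switch exists for oracle
tests. Background voxels are exactly zero before noise.

## Phantom geometry and cohort

The template grid is 48×64×48 voxels at 0.8 mm isotropic (a thalamic
field of view, not a whole head): a white-matter ellipsoidal shell
encloses two grey-matter thalamic blocks separated by a 2.4 mm
cerebrospinal-fluid slab (the third ventricle); two ellipsoidal habenulae
(semi-axis ratio 1.6 : 2.8 : 2.0) abut the ventricle posterior-dorsally.
Habenula masks are rasterised by taking exactly round(V / voxel volume)
voxels of smallest ellipsoidal distance, so the template habenula is
38 voxels = 19.46 mm³ for the default 19.26 mm³ calibration. Anterior
and posterior commissure landmarks sit on the midline, 19.2 mm apart.

Default tissue parameters (mean ± between-subject SD):

| tissue   | R1 (1/s)    | R2* (1/s)    | PD (p.u.)    | MTsat (p.u.) |
|----------|-------------|--------------|--------------|--------------|
| WM       | 1.05 ± 0.04 | 21.0 ± 1.0   | 69.0 ± 1.5   | 2.00 ± 0.10  |
| GM       | 0.70 ± 0.03 | 16.0 ± 1.0   | 83.0 ± 1.5   | 0.90 ± 0.08  |
| CSF      | 0.25 ± 0.02 | 1.5 ± 0.3    | 100.0 ± 0    | 0            |
| habenula | 0.86 ± 0.03 | 19.11 ± 1.87 | 76.21 ± 1.52 | 1.05 ± 0.08  |

The habenula row is the calibration point of the pipeline — the cohort
means and SDs the full analysis must recover. WM/GM/CSF values are
typical 3 T literature values; WM PD = 69 p.u. doubles as the
proton-density calibration reference, so that convention is internally
consistent. These values also fix the sign pattern of the
habenula/surround contrast (hyperintense on R1, R2* and MTsat,
hypointense on PD).

Each cohort subject (default 26, reproducible from
`(master_seed, subject_index)`) is drawn by: (a) rescaling the habenula
ellipsoids to a volume from N(19.26, 2.03²) mm³ before deformation;
(b) jittering each tissue's parameters by the between-subject SDs;
(c) applying a smooth random displacement field (maximum amplitude
1.2 mm, inverted by fixed-point iteration; the forward/inverse round
trip is verified to < 0.1 voxel, with redraw on failure); (d) drawing
transmit (range [0.9, 1.1]) and receive (range [0.7, 1.3]) fields as
random linear-plus-mild-quadratic polynomials over the grid. Coil fields
vary over centimetres in reality, so across this small field of view a
low-order polynomial is the realistic shape — and it keeps the fields
resolvable by the 8 mm receive-calibration scans. Labels and masks are
warped with nearest-neighbour interpolation and parameter volumes are
re-filled from the warped labels, so tissue probabilities remain a
partition of unity and truth volumes are piecewise constant.

The deformation's random Jacobian makes realised mask volumes scatter
around the drawn volume by a few percent without bias, adding a second,
anatomically plausible source of volumetric variability.

## Acquisition protocol

T1-weighted: α = 21°; PD-weighted: α = 6°; MT-weighted: α = 6°; common
TR = 25.0 ms. PDw/T1w acquire eight echoes and MTw six. The echo grid is
TE_n = 2.30 + (n − 1)·2.314 ms, chosen so the sixth echo lands on
13.87 ms; an exactly uniform 2.30 ms spacing cannot end at 13.87 ms, so
the spacing is a documented choice and configurable. The transmit-field
map is supplied noise-free; the receive-calibration pair (the true
receive field sampled on an ~8 mm grid, plus a unit body-coil companion)
receives 0.5% Gaussian noise.

## Map estimation

1. **Joint decay fit.** Ordinary least squares on
   ln S_w(TE) = ln S_w(0) − R2*·TE jointly over all weightings and
   echoes, with one shared slope and one intercept per weighting. All
   voxels share the design matrix, so the fit is a single pseudoinverse
   product. Voxels with any non-positive signal are excluded (counted);
   R2* is clamped at zero. The MTw train participates with its own
   intercept and no echo-count balancing.
2. **R1 and amplitude.** Dual-flip-angle rational approximations on the
   T1w/PDw intercepts with transmit-corrected angles a_w = f_T·α_w:

       R1 = ½ (S_T1 a_T1/TR − S_PD a_PD/TR) / (S_PD/a_PD − S_T1/a_T1)
       A  = S_PD S_T1 (TR a_T1/a_PD − TR a_PD/a_T1)
            / (S_T1 TR a_T1 − S_PD TR a_PD)

   Voxels with near-degenerate denominators, non-finite or non-positive
   results are masked and counted.
3. **Proton density.** A is divided by the receive-sensitivity estimate
   (ratio of the calibration pair, tricubically upsampled to the map
   grid, clamped positive), then scaled by one global constant so that
   mean PD over the white-matter mask equals 69 p.u. (configurable).
4. **MT saturation.** δ = (A·a_MT/S_MT − 1)·R1·TR − a_MT²/2, followed by
   the empirical transmit-bias correction δ·(1 − 0.4)/(1 − 0.4·f_T)
   (on by default, switchable), reported in percent units and masked
   outside [−0.5, 10] p.u.

TR and TE are carried in milliseconds in metadata and converted to
seconds internally, so rates are always 1/s.

### Accuracy envelopes (established against the exact signal equation)

At protocol settings the rational approximations are biased by design:
R1 is recovered within 2% over R1 ∈ [0.5, 1.5] 1/s (about −1.2% at the
habenula value), A within 2% (about +0.3%), and MTsat within 3% relative
for δ ∈ (0, 2] p.u. (about +1.4% at 1.05 p.u.), with |bias| < 0.02 p.u.
at δ = 0. Rician noise at SNR 100 adds < 0.5% to ROI means. At SNR 50
the log-domain OLS decay fit acquires a measurable R2* bias (~1.5%,
bounded at 2% in the tests) because late, low-SNR echoes enter the log
fit unweighted; R1, PD and MTsat stay within 1%.

## Native-space analysis

ROI statistics use the phantom's ground-truth habenula masks (replacing
manual delineation; a drawing interface is out of scope). The AC–PC
reorientation machinery of the manual workflow is implemented and tested
separately: a rigid transform places the AC–PC midpoint at the origin
with the AC→PC direction along −y (the alignment convention is fixed
here; only the alignment itself is prescribed by the workflow), maps are
resampled trilinearly and masks with nearest-neighbour, and the
round-trip cost on habenula-sized masks is quantified (Dice ≥ 0.8,
volume change ≤ 15%, ROI-mean shift < 2%).

Statistics are arithmetic mean and population SD (ddof = 0,
configurable). Volumes come from voxel counts. The normalising brain
mask is voxels whose *summed* WM+GM+CSF probability exceeds 0.9; the
per-class-union reading is implemented as an option. The habenula
carries its own probability class, so it is excluded from the brain
mask; at 38 voxels the effect is negligible.

The surround-GM reference is the one-voxel dilation of the habenula mask
(6-connected by default — a radius-1 Euclidean ball on the lattice
contains only face neighbours; 26-connected available), minus the
habenula, intersected with GM probability > 0.9. CNR is
(habenula mean − GM mean) / habenula SD, sign preserved; the
denominator uses the habenula SD only, exactly as the study defines it.

## Group-space analysis

True nonlinear registration is not re-estimated: each subject's stored
ground-truth subject→template deformation is composed with a random
rigid perturbation (translation SD 0.4 mm per axis, seeded) standing in
for residual registration error — the phenomenon of interest when
normalising a ~19 mm³ structure, independent of any particular
registration algorithm. Maps are interpolated trilinearly; habenula
masks are carried as trilinear weight images in [0, 1]
(nearest-neighbour available) and both are smoothed with an isotropic
0.8 mm-FWHM Gaussian. Cohort-average maps are voxelwise means; the
probability atlas is the voxelwise mean of the warped mask weights.

With zero misalignment and no smoothing the binary masks realign exactly
(atlas maximum 1, guaranteed by the < 0.1 voxel warp round-trip bound
with nearest-neighbour warping); with the default 0.4 mm misalignment
over 26 subjects no voxel stays inside every subject's habenula and the
maximum drops to ~0.85–0.9 — the qualitative signature of imperfect
overlap. Fractional-weight warping is what produces this signature;
averaging the smoothed weights also means the atlas maximum is not
exactly k/n.

The fixed GM reference ROI for the threshold sweep is the one-voxel
dilation of the atlas support (any positive probability) minus that
support, intersected with the cohort-average GM probability > 0.9. The
sweep thresholds default to 0.05–0.95 in steps of 0.05; for each
threshold the ROI is atlas > p and the CNR of every cohort-average map
is computed against the fixed GM ROI, with empty-ROI thresholds recorded
as missing. ROI volume is non-increasing in the threshold by
construction.

The sweep's informative range is bounded below by ROI contamination
(thresholds < 0.3 admit GM and CSF partial-volume voxels, biasing CNR —
the same effect the study describes) and above by ROI degeneracy (below
~16 voxels the within-ROI SD, and hence CNR, is unstable); the
qualitative assertions (R1 tops the CNR curves; CNR trends upward with
threshold) are evaluated there.

## What the generator does and does not emulate

Emulated: the three-weighting multi-echo protocol with its flip angles,
TR and echo trains; transmit- and receive-field inhomogeneity and their
calibration data; between-subject variation of tissue parameters,
habenula volume and anatomy; magnitude (Rician) noise; residual
group-space misalignment.

Not emulated: k-space sampling, parallel-imaging reconstruction and its
spatially varying noise; imperfect RF spoiling; chemical
shift/susceptibility effects; within-tissue heterogeneity and partial
volume beyond voxelisation (truth volumes are piecewise constant per
tissue); actual registration error structure (our misalignment is a
rigid draw); full-head anatomy. Consequently native-space CNR values are
several-fold larger than on real data, where within-ROI heterogeneity
dominates the habenula SD; the brain-normalised habenula volume
(~0.17% here) is far larger than a whole-brain value (~8×10⁻³ %)
because the desk-scale phantom brain is ~24 cm³, not ~1.4 L. Passing
tests therefore validate the estimation chain and the qualitative
structure of the analyses, not absolute CNR or normalised-volume levels.

## Numerical choices

- Seeds: every stochastic stage derives from
  `(master_seed, subject_index, stage_constant)` via `SeedSequence`;
  reported values are pure functions of the configuration.
- Deformation inversion: 30 fixed-point iterations, linear
  interpolation; acceptance bound 0.1 voxel, at most 5 redraws.
- Receive upsampling: tricubic, clamped to a small positive floor;
  degenerate ratios replaced by 1 before interpolation.
- Masked voxels are excluded and counted, never filled.
- Problem sizes: the default grid (48×64×48) holds ~73k brain voxels;
  a full cohort run (26 subjects, simulation through sweep) computes in
  about a minute on one core. Unit tests use a 32×44×32 grid.

## Known limitations

- The uniform-interior phantom makes within-ROI SD almost purely
  noise-driven, so CNR magnitudes are optimistic (see above); only their
  sign pattern and ordering are meaningful.
- The sweep's native/group CNR crossing threshold is reported but sits
  high (~0.8) for the same reason; on real data the study finds ~0.3.
- The rational-approximation biases are inherent to the estimator family
  and documented rather than corrected; enabling a nonlinear fit would
  trade speed for removing them.
- The misalignment model is translational; rotational registration error
  and subject-specific failure modes are not represented.
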