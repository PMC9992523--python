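# habmpm — digital-phantom multi-parameter mapping of the habenula

The habenula is a small (~15–30 mm³) epithalamic nucleus between the
mediodorsal thalamus and the third ventricle, of wide interest in
affective neuroscience but hard to image: at 0.8 mm resolution it spans
only a few dozen voxels and partial-volume effects dominate. Quantitative
multi-parameter mapping (MPM) characterises it by four physical
parameters — the longitudinal relaxation rate R1 = 1/T1, the effective
transverse relaxation rate R2\*, proton density PD, and the
magnetisation-transfer saturation MTsat — estimated from three multi-echo
spoiled gradient-echo (FLASH) scans with T1, PD and MT weighting.

`habmpm` is a testbed for that entire measurement chain. It is aimed at
quantitative-MRI methodologists who want to know what an MPM pipeline
does to a structure this small: it simulates a cohort of labelled digital
phantoms whose habenula tissue parameters are calibrated to published
in-vivo cohort values, forward-models the acquisition, estimates the
maps, and runs the habenula analyses — ROI statistics, volumetry,
contrast-to-noise ratio (CNR) against the surrounding grey matter, and a
group-space probability atlas with a CNR-versus-threshold sweep — against
known ground truth.

## The model in brief

Noise-free FLASH signal per weighting w and echo time TE:

    S_w(TE) = c_RX · A · sin(f_T α_w) · (1 − d_w)(1 − E1)
              / (1 − (1 − d_w) cos(f_T α_w) E1) · e^(−TE·R2*),
    E1 = exp(−TR·R1)

with transmit-field fraction f_T, receive sensitivity c_RX, and d_w the
per-TR MT saturation (MTw scan only). Estimation inverts this chain:

- one joint log-linear fit of all echo trains with a shared R2\* and one
  TE = 0 intercept per weighting;
- dual-flip-angle rational approximations for R1 and the effective
  amplitude A from the T1w/PDw intercepts, with B1-corrected angles;
- PD = A over the upsampled receive-sensitivity estimate, globally
  scaled so mean white-matter PD = 69 p.u.;
- MTsat δ = (A·a_MT/S_MT − 1)·R1·TR − a_MT²/2 with an empirical
  transmit-bias correction (1 − 0.4)/(1 − 0.4·f_T).

Native-space CNR is (habenula mean − surround-GM mean)/habenula SD, the
surround being a one-voxel 6-connected shell restricted to GM. In group
space, subjects are warped to the template with their known deformations
plus a seeded 0.4 mm random misalignment standing in for registration
error; the voxelwise mean of the warped habenula masks is the
probability atlas that drives the threshold sweep.

See `docs/methods.md` for assumptions, parameter defaults, accuracy
envelopes and limitations.

## Worked example

```python
import habmpm as h

report = h.run_all(h.RunConfig(), out_dir="results/run1")  # ~1 min
print(h.summarize(report)[1])
```

prints (default configuration, master seed 1, 26 subjects):

```
Cohort summary
==============
subjects: 26   config: ae42af960c40bd6f

Habenula ROI means (cohort mean +/- SD):
  MTsat  1.059 +/- 0.0666 p.u.
  PD     76.49 +/- 1.86 p.u.
  R1     0.853 +/- 0.0292 1/s
  R2s    18.68 +/- 1.66 1/s

Volumes (mm^3): left 20.48 +/- 3.37, right 19.46 +/- 3.06, mean 19.97 +/- 2.57
Normalised volume (% of brain): 0.1661 +/- 0.0215

CNR ranking (native, by cohort mean): R1 > R2s > MTsat > PD
  R1     CNR +19.14
  R2s    CNR +5.443
  MTsat  CNR +4.687
  PD     CNR -12.66

Atlas maximum probability: 0.8699 (attained at 1 voxel(s))
Sweep CNR first exceeds native mean for R1 at p > 0.80
...
```

Reading this: the pipeline recovers the habenula calibration values
(R1 0.86 1/s, R2\* 19.11 1/s, PD 76.21 p.u., MTsat 1.05 p.u.) to within
a few percent — the residuals are the documented estimator biases plus
cohort sampling scatter. R1 gives the strongest habenula/GM contrast and
PD the only negative one (the habenula is water-poorer than surrounding
GM). With residual misalignment no template voxel lies inside every
subject's habenula, so the atlas maximum stays below 1. CNR magnitudes
are higher than in vivo because the phantom's habenula interior is
homogeneous; see the methods note.

The same pipeline is scriptable from the shell:

```sh
habmpm run-all --seed 1 --out results/run1
habmpm simulate-cohort --seed 1 --out cohort/      # write NIfTI + sidecars
habmpm fit-maps --subject cohort/sub-01 --out maps/sub-01
habmpm native-analysis --cohort cohort/ --out native.csv
```

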