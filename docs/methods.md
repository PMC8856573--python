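# Methods

## Partial-volume maps from FOD tissue components

The WM, GM and CSF tissue components are taken as the l = 0
spherical-harmonic coefficient volume of each CSD output (volume 0 of the 4D
WM FOD image; scalar GM/CSF images as-is). No √(4π) or other tissue-uniform
rescaling is applied: any factor common to the three components at a voxel
cancels in the normalisation

    PV_A = TC_A / (TC_W + TC_G + TC_C).

Consequences worth being explicit about:

- **Negative coefficients** (spherical-harmonic ringing) are clamped to zero
  before normalisation, since fractions must be non-negative.
- **Degenerate voxels**: where the component sum is ≤ 1e-12 (background,
  skull gaps) the voxel is marked invalid and synthesises to exactly zero.
  The outputs are therefore effectively skull-stripped.
- **Per-tissue scale is a user responsibility.** The normalisation removes
  globally uniform and per-voxel-common factors, but *per-tissue* factors
  (e.g. unequal response-function amplitudes, spatially varying
  normalisation of the FODs) do not cancel and will bias the fractions.
  The package does not attempt to correct this.
- No resampling is done: the four inputs must already share a grid (checked
  to 1e-4 mm on shape, voxel size and affine), as they do when they come
  from one CSD run. The output affine is copied bit-exactly, so synthetic
  images are natively aligned to the diffusion data.

## Signal models

All times are in milliseconds, flip angles in degrees at the interface,
proton density ρ relative to CSF. Defaults (3T literature values):

| tissue | T1 | T2 | T2\* | ρ |
|--------|-----|------|------|-----|
| WM | 830 | 80 | 53 | 0.7 |
| GM | 1330 | 110 | 66 | 0.8 |
| CSF | 4000 | 1000 | 250 | 1.0 |

Sequences: MPRAGE α = 9°, TE = 2.9, TI = 900, TR = 2300 (the ADNI protocol);
spin echo TE = 80, TR = 4500 (typical clinical T2w). Both blocks and the
tissue table are overridable through the YAML config, because relaxometry
shifts with age and disease; the defaults describe healthy adult brain.

**Spin echo.** S_se = ρ(1 − e^(−TR/T1))e^(−TE/T2). T1 recovery during TE
itself is neglected — the standard idealisation, wrong by well under 1% for
the default TE/TR — and T2 (not T2\*) governs the decay because the echo
refocuses static-field inhomogeneity.

**MPRAGE.** S_mp = |ρ sin α (1 − 2e^(−TI/T1) + e^(−TR/T1)) e^(−TE/T2\*)|.
This is the single-excitation simplification of the inversion-prepared
gradient echo: perfect inversion, TI of recovery, one low-flip readout with
T2\* echo decay, and **complete saturation of longitudinal magnetisation by
the readout train** before the remaining TR − TI of recovery. The
saturation assumption is what closes the recursion into this form; without
it the steady state carries an extra factor 1/(1 + e^(−TR/T1)) (about −6%
for WM at the defaults). Echo-train length and echo spacing are not
parameters of this model; a fuller readout model would need them. The
magnitude is taken because MR images are magnitude images — with the default
values CSF at TI = 900 ms is past its null but unrecovered, so its
pre-magnitude signal is slightly negative, and |·| is what makes CSF *dark*
rather than "most negative", reproducing the expected MPRAGE appearance.

**Stepwise oracle.** `bloch_oracle` propagates Mz through explicit
blocks — inversion (Mz → −Mz), relaxation (Mz → ρ + (Mz−ρ)e^(−t/T1)),
excitation (records Mz·sin α·e^(−TE/decay); Mz → Mz·cos α when the
saturation flag is set), and a spoiler (Mz → 0, the readout-saturation
idealisation above) — from equilibrium until consecutive cycles agree to
1e-9, raising if they do not. It shares no code with the closed forms; the
test suite confirms each closed form is the exact fixed point of its block
sequence for all three tissues.

## Synthesis and inversion

Synthesis is the convex combination of the three pure-tissue signals with
the PV weights, so every synthesized intensity lies inside the pure-signal
hull and the map is linear in the fractions — both checked exhaustively on
the phantom. Output units are the arbitrary units of the signal model;
an optional affine rescale exists for toolchains that expect a fixed range
(structural contrasts are qualitative, so no radiometric meaning is lost).

`recover_pv` is a validation utility: per voxel it solves the 3×3 linear
system {T1w equation, T2w equation, ΣPV = 1} by least squares, clamps to
[0, 1] and renormalises. The tissue-signal design matrix has condition
number ≈ 244 at the defaults (a conditioning error is raised above 1e12,
e.g. for degenerate registries). Noiseless synthetic input is recovered to
machine precision; under 1% Rician noise on both contrasts a pre-build
Monte-Carlo simulation of the inversion (200k uniform-simplex voxels)
put the RMS fraction error at ≈ 0.050, which is the frozen tolerance used
by the tests — the phantom itself, dominated by pure voxels where clamping
is effective, measures ≈ 0.043.

## Evaluation metrics

- **Tissue contrast** CN = |S_A − S_B| / (S_A + S_B). The magnitude
  convention makes the value a contrast *size* whichever tissue is
  brighter, matching how positive contrasts are reported for both T1w
  (WM > GM) and T2w (GM > WM). ROI means warn below 20 voxels or when the
  ROI is not 6-connected, but still return a value — ROI placement is the
  user's call.
- **ZNCC** uses population (divisor-N) standard deviations within a single
  user-supplied mask Ω. Invariant to independent positive affine intensity
  maps of either image; anti-correlation gives −1 (the default T1w and T2w
  synthetic contrasts correlate at ≈ −0.95 on the phantom).
- **Generalised Dice (gDSC)** pools Dice numerators and denominators across
  labels: gDSC = 2ΣΣ i·s / ΣΣ(i+s). It is implemented as a *similarity*
  (1 = identical), which is the convention under which reported values in
  this field (≈ 0.5–0.8) make sense; `dissimilarity=True` exposes the
  complementary form for auditing. With one label it reduces exactly to
  binary Dice; two empty masks score 1 by convention.
- **Interface restriction** keeps label voxels having at least one
  18-connected neighbour (6 faces + 12 edges, corners excluded) inside the
  WM mask — the GM/WM interface from which tractography is seeded.

## The phantom

A nested-sphere geometry (CSF "ventricle" ⊂ WM core ⊂ GM ribbon ⊂
background) on a 64³ grid at 2 mm isotropic by default — the resolution
regime of typical diffusion acquisitions — with an optional spherical
CSF-filled cavity standing in for resection cavities. Crisp labels become
partial volumes by Gaussian smoothing of each tissue indicator (σ = 2 mm)
followed by voxel-wise renormalisation, which guarantees the sum-to-one
property the synthesis model assumes while producing realistic mixed
boundaries. The emitted tissue components are the ground-truth fractions
times a smooth, strictly positive per-voxel modulation field shared by the
three tissues (amplitude ±20%, seeded): this exercises the normalisation
non-trivially while cancelling exactly, so the pipeline must recover the
ground truth to 1e-9. Optional per-tissue constants (`tc_scales`, default
(1, 1, 1)) emulate unequal response amplitudes; they deliberately do *not*
cancel, mirroring the per-tissue-scale caveat above. Optional Rician noise
(two-channel Gaussian magnitude) corrupts the components at a chosen
fraction of each map's maximum.

What the phantom does **not** emulate: anatomically realistic geometry and
cortical folding, spherical-harmonic structure beyond l = 0 (higher FOD
volumes are zero-filled), spatially correlated CSD estimation error,
susceptibility distortion, and scanner intensity non-uniformity beyond the
smooth shared modulation. Passing tests therefore demonstrate correctness
of the normalisation → simulation → evaluation chain, not robustness to
real-data artefacts such as response-function miscalibration.

## Numerical and design choices

- Denominator guard 1e-12 in the normalisation; grid tolerance 1e-4 mm;
  oracle steady-state tolerance 1e-9; recovery conditioning limit 1e12.
- Problem sizes: the test suite runs mostly on a 32³/4 mm phantom, with the
  end-to-end property checks at the default 64³/2 mm; both complete in
  seconds.
- Degenerate rescale (constant image) maps everything to the lower bound.
- All NIfTI outputs are written as float32 via in-memory serialisation,
  gzip with mtime = 0 and atomic rename: identical inputs give
  byte-identical files and failed runs leave no partial outputs.
- Voxel indices are 0-based; orientation is carried entirely by the input
  affine.

## Known limitations

- The simplified MPRAGE solution ignores the echo train; pure-tissue
  contrasts computed from it will differ somewhat from ROI measurements on
  real scanner MPRAGEs (which also include partial-volume impurity in any
  measurement ROI).
- One relaxometry table is applied to the whole brain: focal pathology that
  changes T1/T2 locally is rendered only through its effect on the CSD
  tissue components, not through altered relaxometry.
- Synthetic images inherit the diffusion resolution (no super-resolution is
  attempted), and non-brain tissue is not synthesized.
- The method presumes usable multi-tissue CSD output; it adds no
  requirements beyond those of CSD-based tractography itself, but cannot
  rescue datasets that fail there.
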