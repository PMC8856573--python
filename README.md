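# dwisynth

Synthetic T1-weighted and T2-weighted structural MR images generated from
diffusion MRI, for pipelines whose structural scans are missing or
motion-corrupted.

## The problem

Most diffusion-MRI analyses (Freesurfer parcellation, atlas-driven
tractography, tract-wise FA/MD sampling) require an aligned structural image.
Diffusion series tolerate motion well — corrupted volumes can simply be
dropped — but a motion-ruined T1w or T2w scan cannot be repaired and its loss
can make an otherwise good diffusion dataset unanalysable. Multi-tissue
constrained spherical deconvolution (MSMT-CSD or SS3T-CSD), however, already
produces white-matter, grey-matter and CSF tissue components from diffusion
data alone. `dwisynth` turns those components into physically simulated
structural contrasts, in native diffusion space, with no registration step.

## The model

From the FOD tissue components `TC_W`, `TC_G`, `TC_C` (the l = 0
spherical-harmonic coefficient of each component), partial-volume fractions
are formed by voxel-wise normalisation:

    PV_A = TC_A / (TC_W + TC_G + TC_C),   A ∈ {W, G, C}

Each contrast is then a partial-volume-weighted mixture of steady-state
Bloch-equation solutions with 3T literature relaxometry
(WM: T1 830 / T2 80 / T2\* 53 ms, ρ 0.7; GM: 1330 / 110 / 66 ms, ρ 0.8;
CSF: 4000 / 1000 / 250 ms, ρ 1.0 — ρ relative to CSF):

    S_T1w = Σ_A PV_A · S_mp(Θ_mp, Φ_A)      (MPRAGE)
    S_T2w = Σ_A PV_A · S_se(Θ_se, Φ_A)      (spin echo)

with the closed forms

    S_se = ρ (1 − e^(−TR/T1)) e^(−TE/T2)
    S_mp = | ρ sin α (1 − 2 e^(−TI/T1) + e^(−TR/T1)) e^(−TE/T2*) |

Defaults are the ADNI MPRAGE protocol (α = 9°, TE = 2.9 ms, TI = 900 ms,
TR = 2300 ms) and a clinical T2w spin echo (TE = 80 ms, TR = 4500 ms); both
sequences and all relaxometry values are overridable via a YAML config, e.g.
to match an aged or pathological population.

The package also ships the evaluation metrics used to compare synthetic and
acquired images (ROI tissue contrast, zero-normalized cross-correlation,
binary and generalised Dice with GM/WM-interface restriction), a stepwise
Bloch-propagation oracle that independently verifies the closed forms, a
least-squares partial-volume recovery for end-to-end validation, and a
digital three-tissue phantom so everything is testable without scanner data.

## Worked example

```python
import numpy as np
from dwisynth import (PhantomSpec, default_config, generate_phantom,
                      mprage_signal, spin_echo_signal, synthesize,
                      recover_pv, zncc)
from dwisynth.tissue_maps import compute_pv_maps

cfg = default_config()
for lab, tis in cfg.registry.items():
    print(f"{lab.upper():3s}  T1w {mprage_signal(cfg.mprage, tis):.4f}"
          f"   T2w {spin_echo_signal(cfg.spin_echo, tis):.4f}")

ph = generate_phantom(PhantomSpec(seed=42))
pv = compute_pv_maps(ph.components)
t1w = synthesize(pv, cfg.mprage, cfg.registry)
t2w = synthesize(pv, cfg.spin_echo, cfg.registry)
print(f"T1w/T2w ZNCC inside the brain: {zncc(t1w.data, t2w.data, pv.valid):.3f}")
rec = recover_pv(t1w, t2w, cfg.mprage, cfg.spin_echo, cfg.registry, valid=pv.valid)
print(f"max |recovered PV - truth|: {np.abs(rec.stacked() - ph.truth.stacked()).max():.2e}")
```

prints

```
WM   T1w 0.0401   T2w 0.2564
GM   T1w 0.0193   T2w 0.3735
CSF  T1w 0.0053   T2w 0.6234
T1w/T2w ZNCC inside the brain: -0.951
max |recovered PV - truth|: 4.65e-14
```

The signal ordering is the expected one: on T1w, WM is brightest and CSF is
suppressed (0.0401 > 0.0193 > 0.0053); on T2w, CSF is hyperintense
(0.6234 > 0.3735 > 0.2564). The strong negative ZNCC between the two
synthetic contrasts reflects their inverted tissue ordering, and the
partial-volume recovery closes the loop: inverting the two synthesized
images reproduces the phantom's ground-truth fractions to machine precision.

## Command line

```sh
dwisynth phantom --out-dir ph/                      # digital phantom + ground truth
dwisynth synthesize --wmfod wmfod.nii.gz --gm gm.nii.gz --csf csf.nii.gz \
    --mask mask.nii.gz --contrast both --out-prefix sub01 --save-pv
dwisynth evaluate --ref invivo_t1w.nii.gz --test sub01_t1w.nii.gz \
    --mask mask.nii.gz --out metrics.csv
```

Every output gets a JSON sidecar with the parameters used, the package
version and SHA-256 checksums of the inputs; reruns with identical inputs
are byte-identical.

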