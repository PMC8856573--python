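"""Digital three-tissue phantom with known ground-truth partial volumes.

The phantom emulates the input set of the synthesis pipeline — three
non-negative tissue-component volumes (a 4D "FOD-like" WM image whose
first volume carries the component, scalar GM and CSF images) plus a
binary brain mask — on a grid in the resolution regime of typical
diffusion acquisitions (default 64^3 voxels at 2 mm isotropic).

Geometry is a set of nested spheres: a CSF "ventricle" inside a WM core
inside a GM ribbon, surrounded by background; an optional spherical
CSF-filled cavity stands in for resection cavities and cystic lesions.
Crisp tissue labels are turned into partial volumes by Gaussian
smoothing of each indicator followed by voxel-wise renormalisation, so
the ground truth sums to one exactly at every in-brain voxel — the
property the synthesis model assumes.

The tissue-component files are the ground-truth fractions multiplied by
a smooth positive per-voxel modulation field shared by all three
tissues, which exercises the normalisation non-trivially: the shared
factor must cancel exactly in the partial-volume ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grid import VolumeGrid
from .nifti_io import save_deterministic
from .tissue_maps import PVMapSet, TissueComponentSet

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "write_phantom", "add_rician_noise"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the nested-sphere phantom.

    All lengths in mm. ``smoothness_mm`` is the Gaussian sigma applied to
    the crisp tissue indicators to create partial-volume boundaries
    (0 gives a piecewise-pure phantom). ``noise_sigma`` is the Rician
    noise level applied to the emitted tissue-component maps, as a
    fraction of each map's maximum (0 = noiseless). The component maps
    are the ground-truth fractions times a smooth, strictly positive
    per-voxel modulation field (1 +/- ``modulation_amplitude``, common to
    the three tissues, emulating spatial intensity modulation of the FOD
    amplitudes); because the field is shared it cancels exactly in the
    partial-volume normalisation. ``tc_scales`` optionally applies
    additional per-tissue constants — these do NOT cancel in the
    normalisation (they mimic unequal response-function amplitudes, under
    which the recovered fractions are rescalings of the truth), so the
    default is (1, 1, 1).
    """

    shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 2.0
    ventricle_radius_mm: float = 12.0
    wm_radius_mm: float = 36.0
    gm_thickness_mm: float = 10.0
    smoothness_mm: float = 2.0
    lesion: bool = False
    lesion_center_mm: tuple = (20.0, 0.0, 0.0)  # offset from grid centre
    lesion_radius_mm: float = 8.0
    noise_sigma: float = 0.0
    seed: int = 0
    tc_scales: tuple = (1.0, 1.0, 1.0)
    modulation_amplitude: float = 0.2
    n_fod_volumes: int = 6

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 < self.ventricle_radius_mm < self.wm_radius_mm):
            raise ValueError("require 0 < ventricle radius < WM radius")
        if self.gm_thickness_mm <= 0:
            raise ValueError("GM thickness must be positive")
        outer = self.wm_radius_mm + self.gm_thickness_mm
        half_extent = min(self.shape) * self.voxel_size_mm / 2.0
        if outer >= half_extent:
            raise ValueError(
                f"phantom radius {outer} mm exceeds half grid extent {half_extent} mm"
            )
        if self.lesion and self.lesion_radius_mm <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass
class Phantom:
    """Generated phantom: ground truth plus the component set a CSD run would give."""

    truth: PVMapSet
    components: TissueComponentSet
    spec: PhantomSpec


def _radius_field(spec: PhantomSpec):
    center = (np.array(spec.shape) - 1) / 2.0
    coords = np.indices(spec.shape).astype(float)
    offsets = (coords - center.reshape(3, 1, 1, 1)) * spec.voxel_size_mm
    return np.sqrt((offsets**2).sum(axis=0)), offsets


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Build the phantom deterministically from its spec.

    Crisp labels (CSF ventricle / WM core / GM ribbon / background, plus
    the optional lesion) are smoothed per-tissue and renormalised inside
    the brain mask so fractions sum to one exactly. The component maps
    are the fractions times ``tc_scales``; with ``noise_sigma > 0`` they
    are additionally Rician-corrupted (seeded, so reproducible).
    """
    r, offsets = _radius_field(spec)
    outer = spec.wm_radius_mm + spec.gm_thickness_mm

    csf = r < spec.ventricle_radius_mm
    wm = (r >= spec.ventricle_radius_mm) & (r < spec.wm_radius_mm)
    gm = (r >= spec.wm_radius_mm) & (r < outer)
    if spec.lesion:
        lesion_center = np.asarray(spec.lesion_center_mm, dtype=float)
        d = np.sqrt(((offsets - lesion_center.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
        in_lesion = d < spec.lesion_radius_mm
        csf = csf | in_lesion
        wm = wm & ~in_lesion
        gm = gm & ~in_lesion
    brain = csf | wm | gm

    indicators = [ind.astype(float) for ind in (wm, gm, csf)]
    if spec.smoothness_mm > 0:
        sigma_vox = spec.smoothness_mm / spec.voxel_size_mm
        indicators = [ndimage.gaussian_filter(ind, sigma_vox) for ind in indicators]
    total = sum(indicators)
    valid = brain & (total > 1e-12)
    denom = np.where(valid, total, 1.0)
    fracs = [np.where(valid, ind / denom, 0.0) for ind in indicators]

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    grid = VolumeGrid(shape=tuple(spec.shape), affine=affine)
    truth = PVMapSet(pv_wm=fracs[0], pv_gm=fracs[1], pv_csf=fracs[2],
                     valid=valid, grid=grid)

    rng = np.random.default_rng(spec.seed)
    modulation = _modulation_field(spec, rng)
    tcs = []
    for frac, scale in zip(fracs, spec.tc_scales):
        tc = frac * scale * modulation
        if spec.noise_sigma > 0:
            sigma = spec.noise_sigma * tc.max()
            tc = _rician(tc, sigma, rng)
        tcs.append(tc)
    components = TissueComponentSet(
        tc_wm=tcs[0], tc_gm=tcs[1], tc_csf=tcs[2], mask=valid, grid=grid
    )
    return Phantom(truth=truth, components=components, spec=spec)


def write_phantom(phantom: Phantom, out_dir) -> dict:
    """Write the phantom in the exact file layout the pipeline consumes.

    Emits wmfod.nii.gz (4D, component in volume 0, higher spherical-
    harmonic volumes zero-filled), gm.nii.gz, csf.nii.gz, mask.nii.gz
    and truth_pv.nii.gz (4D WM/GM/CSF ground truth). Returns the path of
    each file by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = phantom.spec
    affine = phantom.truth.grid.affine

    fod = np.zeros(tuple(spec.shape) + (spec.n_fod_volumes,), dtype=np.float32)
    fod[..., 0] = phantom.components.tc_wm
    paths = {}
    items = [
        ("wmfod", fod),
        ("gm", phantom.components.tc_gm.astype(np.float32)),
        ("csf", phantom.components.tc_csf.astype(np.float32)),
        ("mask", phantom.components.mask.astype(np.uint8)),
        ("truth_pv", phantom.truth.stacked().astype(np.float32)),
    ]
    for name, data in items:
        path = out_dir / f"{name}.nii.gz"
        save_deterministic(nib.Nifti1Image(data, affine), path)
        paths[name] = path
    return paths


def _modulation_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive per-voxel factor shared by the three components."""
    if spec.modulation_amplitude == 0:
        return np.ones(spec.shape)
    noise = rng.standard_normal(spec.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=4.0)
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth /= peak
    field = 1.0 + spec.modulation_amplitude * smooth
    return np.clip(field, 0.05, None)


def _rician(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    n1 = rng.normal(0.0, sigma, img.shape)
    n2 = rng.normal(0.0, sigma, img.shape)
    return np.sqrt((img + n1) ** 2 + n2**2)


def add_rician_noise(img: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Corrupt a magnitude image with Rician noise of scale ``sigma``.

    Returns sqrt((I + n1)^2 + n2^2) with n1, n2 independent zero-mean
    Gaussian fields of standard deviation sigma; sigma = 0 returns the
    input unchanged. Deterministic given the seed. On a zero image the
    output is Rayleigh-distributed with mean sigma*sqrt(pi/2).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    img = np.asarray(img, dtype=float)
    if sigma == 0:
        return img.copy()
    return _rician(img, sigma, np.random.default_rng(seed))
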