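"""Tissue-component extraction and partial-volume normalisation.

Multi-tissue constrained spherical deconvolution (MSMT-CSD or SS3T-CSD)
of a diffusion acquisition yields three fibre-orientation-distribution
(FOD) components: a 4D spherical-harmonic white-matter image and scalar
grey-matter and CSF images. The l=0 coefficient of each component scales
with the signal fraction of that tissue compartment in the voxel, so
normalising the three components voxel-wise,

    PV_A = TC_A / (TC_W + TC_G + TC_C),

turns them into partial-volume fractions that sum to one. Any per-tissue
or globally uniform scaling of the components cancels in the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import GridMismatchError, InputFileError
from .grid import GRID_TOL_MM, VolumeGrid

__all__ = [
    "TissueComponentSet",
    "PVMapSet",
    "load_component_image",
    "extract_tissue_components",
    "compute_pv_maps",
]

logger = logging.getLogger(__name__)

#: denominator guard for the partial-volume ratio; voxels whose component
#: sum falls at or below it are treated as background
PV_SUM_EPS = 1e-12


@dataclass
class TissueComponentSet:
    """Raw FOD-derived tissue components (WM, GM, CSF) on one grid.

    Values are non-negative FOD amplitudes in arbitrary units; negatives
    (spherical-harmonic ringing) must have been clamped to zero already.
    """

    tc_wm: np.ndarray
    tc_gm: np.ndarray
    tc_csf: np.ndarray
    mask: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        for name in ("tc_wm", "tc_gm", "tc_csf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative values")
            setattr(self, name, arr)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")


@dataclass
class PVMapSet:
    """Normalised partial-volume fractions (WM, GM, CSF) on one grid.

    At every *valid* voxel the three fractions lie in [0, 1] and sum to 1;
    at invalid voxels (background, or degenerate component sum) all three
    are exactly 0.
    """

    pv_wm: np.ndarray
    pv_gm: np.ndarray
    pv_csf: np.ndarray
    valid: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        for name in ("pv_wm", "pv_gm", "pv_csf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.grid.shape:
            raise ValueError("valid mask shape does not match grid")

    def stacked(self) -> np.ndarray:
        """(X, Y, Z, 3) array of fractions ordered WM, GM, CSF."""
        return np.stack([self.pv_wm, self.pv_gm, self.pv_csf], axis=-1)

    def to_nifti(self) -> nib.Nifti1Image:
        """4D NIfTI of the fractions, volumes ordered WM, GM, CSF."""
        img = nib.Nifti1Image(self.stacked().astype(np.float32), self.grid.affine)
        return img

    def valid_to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.valid.astype(np.uint8), self.grid.affine)


def load_component_image(path, volume_index: int = 0):
    """Load one 3D volume from a 3D or 4D NIfTI image.

    For a 4D spherical-harmonic FOD image, ``volume_index=0`` selects the
    l=0 coefficient volume, which carries the tissue-component amplitude.

    Returns
    -------
    (data, grid)
        The selected 3D float array and its :class:`VolumeGrid`.
    """
    path = Path(path)
    if not path.exists():
        raise InputFileError(f"input image not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types for bad files
        raise InputFileError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim == 3:
        n_vol = 1
    elif data.ndim == 4:
        n_vol = data.shape[3]
    else:
        raise InputFileError(f"{path}: expected 3D or 4D image, got {data.ndim}D")
    if not 0 <= volume_index < n_vol:
        raise IndexError(
            f"{path}: volume_index {volume_index} out of range for image "
            f"with {n_vol} volume(s)"
        )
    vol = data if data.ndim == 3 else data[..., volume_index]
    return np.asarray(vol, dtype=float), VolumeGrid.from_img(img)


def _check_grid(name: str, grid: VolumeGrid, ref: VolumeGrid) -> None:
    if grid.shape != ref.shape:
        raise GridMismatchError(
            f"{name}: dimensions {grid.shape} differ from reference {ref.shape}"
        )
    if not np.allclose(grid.affine, ref.affine, atol=GRID_TOL_MM, rtol=0.0):
        delta = np.abs(grid.affine - ref.affine).max()
        raise GridMismatchError(
            f"{name}: affine differs from reference by up to {delta:.3g} mm "
            f"(tolerance {GRID_TOL_MM} mm)"
        )


def extract_tissue_components(wm_fod, gm, csf, mask) -> TissueComponentSet:
    """Read the four input images and extract scalar tissue components.

    The WM component is the first (l=0) volume of the FOD image; GM and
    CSF images are used as-is (first volume if 4D). Negative values from
    spherical-harmonic ringing are clamped to zero. All four images must
    share one voxel grid within ``GRID_TOL_MM``; no resampling is done.
    """
    tc_w, grid = load_component_image(wm_fod, 0)
    tc_g, grid_g = load_component_image(gm, 0)
    tc_c, grid_c = load_component_image(csf, 0)
    mask_data, grid_m = load_component_image(mask, 0)
    _check_grid(f"gm image {gm}", grid_g, grid)
    _check_grid(f"csf image {csf}", grid_c, grid)
    _check_grid(f"mask image {mask}", grid_m, grid)

    mask_bool = mask_data > 0
    components = {}
    for name, arr in (("tc_wm", tc_w), ("tc_gm", tc_g), ("tc_csf", tc_c)):
        clamped = np.clip(arr, 0.0, None)
        components[name] = clamped
        if mask_bool.any() and not np.any(clamped[mask_bool] > 0):
            logger.warning("%s is zero everywhere inside the mask", name)
    return TissueComponentSet(grid=grid, mask=mask_bool, **components)


def compute_pv_maps(tc: TissueComponentSet, eps: float = PV_SUM_EPS) -> PVMapSet:
    """Normalise tissue components to partial-volume fractions.

    PV_A = TC_A / (TC_W + TC_G + TC_C) at every masked voxel whose
    component sum exceeds ``eps``; all other voxels are invalid and carry
    zero fractions. The ratio is invariant to any positive scaling of the
    components, globally or per voxel.
    """
    total = tc.tc_wm + tc.tc_gm + tc.tc_csf
    valid = tc.mask & (total > eps)
    if tc.mask.any() and not valid.any():
        logger.warning("no valid voxels: component sum <= %g everywhere in mask", eps)

    denom = np.where(valid, total, 1.0)
    out = {}
    for name, arr in (("pv_wm", tc.tc_wm), ("pv_gm", tc.tc_gm), ("pv_csf", tc.tc_csf)):
        pv = np.where(valid, arr / denom, 0.0)
        out[name] = pv
    return PVMapSet(grid=tc.grid, valid=valid, **out)
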