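"""Assembly of synthetic structural images from partial-volume maps.

Each voxel's intensity is the partial-volume-weighted sum of the three
pure-tissue steady-state signals,

    S = PV_W * S(theta, phi_W) + PV_G * S(theta, phi_G) + PV_C * S(theta, phi_C),

so a synthetic image is a convex combination of three constants and
inherits the voxel grid of its inputs — the output lives in native
diffusion space by construction. :func:`recover_pv` inverts the pair of
synthesis equations (plus the unit-sum constraint) voxel-wise, which
makes the forward model checkable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np

from .exceptions import ConditioningError
from .grid import VolumeGrid
from .nifti_io import save_deterministic
from .signal_models import (
    MPRAGEParams,
    PropertyRegistry,
    SpinEchoParams,
    mprage_signal,
    spin_echo_signal,
)
from .tissue_maps import PVMapSet

__all__ = ["SyntheticImage", "pure_tissue_signals", "synthesize", "write_image", "recover_pv"]

SequenceParams = Union[MPRAGEParams, SpinEchoParams]


@dataclass
class SyntheticImage:
    """A simulated structural image plus the provenance of its synthesis."""

    data: np.ndarray
    grid: VolumeGrid
    contrast: str  # "t1w" or "t2w"
    params: SequenceParams
    registry: PropertyRegistry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(f"data shape {self.data.shape} != grid {self.grid.shape}")


def pure_tissue_signals(seq: SequenceParams, registry: PropertyRegistry) -> dict:
    """Pure-tissue signal of each class for one sequence, as {label: signal}."""
    if isinstance(seq, MPRAGEParams):
        return {label: mprage_signal(seq, tis) for label, tis in registry.items()}
    if isinstance(seq, SpinEchoParams):
        return {label: spin_echo_signal(seq, tis) for label, tis in registry.items()}
    raise TypeError(f"unsupported sequence parameters {type(seq).__name__}")


def synthesize(pv: PVMapSet, seq: SequenceParams, registry: PropertyRegistry) -> SyntheticImage:
    """Simulate a structural image from partial-volume maps.

    Valid voxels get the PV-weighted sum of pure-tissue signals; invalid
    voxels (background) are exactly zero, so the output is effectively
    skull-stripped. Intensities are in the arbitrary units of the signal
    model; use the ``rescale`` option of :func:`write_image` if a fixed
    range is needed downstream.
    """
    signals = pure_tissue_signals(seq, registry)
    data = (
        pv.pv_wm * signals["wm"]
        + pv.pv_gm * signals["gm"]
        + pv.pv_csf * signals["csf"]
    )
    data = np.where(pv.valid, data, 0.0)
    contrast = "t1w" if isinstance(seq, MPRAGEParams) else "t2w"
    return SyntheticImage(data=data, grid=pv.grid, contrast=contrast,
                          params=seq, registry=registry)


def write_image(
    img: SyntheticImage,
    path,
    rescale: Optional[tuple] = None,
) -> Path:
    """Write a synthetic image as 32-bit float NIfTI-1 (atomically).

    If ``rescale=(lo, hi)`` is given, intensities are mapped affinely so
    that [min, max] -> [lo, hi]; a constant image has no range and maps
    entirely to ``lo``. The affine is copied from the grid bit-exactly.
    """
    path = Path(path)
    data = img.data
    if rescale is not None:
        lo, hi = float(rescale[0]), float(rescale[1])
        dmin, dmax = float(data.min()), float(data.max())
        if dmax > dmin:
            data = lo + (data - dmin) * (hi - lo) / (dmax - dmin)
        else:
            data = np.full_like(data, lo)
    out = nib.Nifti1Image(data.astype(np.float32), img.grid.affine)
    try:
        save_deterministic(out, path)
    except OSError as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc
    return path


def recover_pv(
    t1w: SyntheticImage,
    t2w: SyntheticImage,
    seq_t1: MPRAGEParams,
    seq_t2: SpinEchoParams,
    registry: PropertyRegistry,
    valid: Optional[np.ndarray] = None,
    cond_limit: float = 1e12,
) -> PVMapSet:
    """Invert the synthesis equations for the partial volumes, voxel-wise.

    Solves the 3x3 linear system {T1w equation, T2w equation, unit sum}
    for (PV_W, PV_G, PV_C) by least squares, then clamps to [0, 1] and
    renormalises. On noiseless synthetic input this recovers the
    generating fractions to machine precision; with noise it is a simple
    per-voxel estimator whose error grows with the conditioning of the
    tissue-signal matrix.

    ``valid`` selects the voxels to invert; by default any voxel with
    signal in either contrast (background synthesises to exactly zero in
    both, so zero-everywhere voxels are taken as background).
    """
    if t1w.grid.shape != t2w.grid.shape or not t1w.grid.matches(t2w.grid):
        raise ValueError("T1w and T2w images must share one grid")
    s1 = pure_tissue_signals(seq_t1, registry)
    s2 = pure_tissue_signals(seq_t2, registry)
    design = np.array(
        [
            [s1["wm"], s1["gm"], s1["csf"]],
            [s2["wm"], s2["gm"], s2["csf"]],
            [1.0, 1.0, 1.0],
        ]
    )
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > cond_limit:
        raise ConditioningError(
            f"tissue signal vectors are degenerate (condition number {cond:.3g})"
        )

    if valid is None:
        valid = (t1w.data != 0) | (t2w.data != 0)
    valid = np.asarray(valid, dtype=bool)

    rhs = np.stack(
        [t1w.data.ravel(), t2w.data.ravel(), np.ones(t1w.data.size)], axis=0
    )
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)  # (3, n_vox)
    sol = np.clip(sol, 0.0, 1.0)
    total = sol.sum(axis=0)
    valid_flat = valid.ravel() & (total > 0)
    total[total == 0] = 1.0
    sol /= total
    sol[:, ~valid_flat] = 0.0

    shape = t1w.grid.shape
    return PVMapSet(
        pv_wm=sol[0].reshape(shape),
        pv_gm=sol[1].reshape(shape),
        pv_csf=sol[2].reshape(shape),
        valid=valid_flat.reshape(shape),
        grid=t1w.grid,
    )
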