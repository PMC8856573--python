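"""Voxel-grid geometry shared by all image types.

All images consumed and produced by the pipeline live on a single voxel
grid in native diffusion space: the outputs inherit the affine of the
inputs verbatim, so no registration is ever needed between a synthetic
image and the diffusion data it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid"]

#: tolerance (mm) on voxel sizes and affine entries when deciding that two
#: images share a grid
GRID_TOL_MM = 1e-4


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D voxel grid: dimensions plus voxel-to-scanner affine.

    Parameters
    ----------
    shape
        Grid dimensions in voxels, three positive integers.
    affine
        4x4 matrix mapping 0-based voxel indices to scanner millimetre
        coordinates. Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        affine.setflags(write=False)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_sizes(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (norms of the affine's spatial columns)."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @classmethod
    def from_img(cls, img) -> "VolumeGrid":
        """Build a grid from a nibabel spatial image (first 3 dims)."""
        return cls(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))

    def matches(self, other: "VolumeGrid", tol: float = GRID_TOL_MM) -> bool:
        """True if shapes are equal and affines agree entrywise within `tol` mm."""
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol, rtol=0.0)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.array_equal(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.tobytes()))
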