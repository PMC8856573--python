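"""Image-similarity and overlap metrics for synthetic-vs-acquired comparison.

Implements the evaluation battery used to judge a synthetic structural
image against an acquired one:

- ROI mean signal and pairwise tissue contrast |S_A - S_B| / (S_A + S_B)
- zero-normalized cross-correlation (ZNCC) within a brain mask
- binary Dice and the multi-label generalised Dice similarity
  coefficient (gDSC)
- restriction of label maps to the GM/WM interface (18-connectivity)

ZNCC is preferred over range-sensitive similarity indices because T1w
and T2w intensities are qualitative: repeat scans and synthetic images
need not share an intensity range, and ZNCC is invariant to positive
affine intensity maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid

__all__ = [
    "LabelImage",
    "roi_mean_signal",
    "tissue_contrast",
    "zncc",
    "dice",
    "generalized_dice",
    "interface_restrict",
]

logger = logging.getLogger(__name__)

#: minimum recommended ROI size (voxels) for stable mean-signal estimates
MIN_ROI_VOXELS = 20


@dataclass
class LabelImage:
    """Integer label field with an optional label-id -> name dictionary.

    Label 0 is reserved for background.
    """

    labels: np.ndarray
    grid: VolumeGrid
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.shape != self.grid.shape:
            raise ValueError(f"labels shape {self.labels.shape} != grid {self.grid.shape}")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")

    def present_labels(self) -> list:
        return sorted(int(l) for l in np.unique(self.labels) if l != 0)


def roi_mean_signal(img: np.ndarray, roi: np.ndarray) -> float:
    """Mean intensity of `img` over the ROI mask.

    Warns (without failing) for ROIs below MIN_ROI_VOXELS voxels or that
    are not 6-connected, since small or fragmented ROIs give unstable
    means.
    """
    img = np.asarray(img, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if img.shape != roi.shape:
        raise ValueError(f"image shape {img.shape} != roi shape {roi.shape}")
    n = int(roi.sum())
    if n == 0:
        raise ValueError("ROI is empty")
    if n < MIN_ROI_VOXELS:
        logger.warning("ROI has only %d voxels (< %d recommended)", n, MIN_ROI_VOXELS)
    if roi.ndim == 3:
        _, n_comp = ndimage.label(roi, structure=ndimage.generate_binary_structure(3, 1))
        if n_comp > 1:
            logger.warning("ROI is not 6-connected (%d components)", n_comp)
    return float(img[roi].mean())


def tissue_contrast(s_a: float, s_b: float) -> float:
    """Tissue contrast |S_A - S_B| / (S_A + S_B), in [0, 1].

    Symmetric and invariant to a common positive scaling of both
    signals; the magnitude convention makes the value a contrast size
    regardless of which tissue is brighter.
    """
    denom = s_a + s_b
    if denom <= 0:
        raise ValueError(f"S_A + S_B must be positive, got {denom}")
    return abs(s_a - s_b) / denom


def zncc(img_a: np.ndarray, img_b: np.ndarray, mask: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two images within a mask.

    r = (1/N) sum_k (a_k - mu_a)(b_k - mu_b) / (sigma_a sigma_b) over the
    N masked voxels, with population (divisor-N) standard deviations.
    Bounded in [-1, 1]; +1 for any positive affine intensity relation,
    -1 for a negative one.
    """
    img_a = np.asarray(img_a, dtype=float)
    img_b = np.asarray(img_b, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not (img_a.shape == img_b.shape == mask.shape):
        raise ValueError("images and mask must share one shape")
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    a = img_a[mask]
    b = img_b[mask]
    sa = a.std()  # population std (ddof=0), matching the 1/N prefactor
    sb = b.std()
    if sa == 0 or sb == 0:
        raise ValueError("image is constant within the mask; ZNCC undefined")
    r = float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))
    return min(1.0, max(-1.0, r))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Binary Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share one shape")
    size = int(mask_a.sum()) + int(mask_b.sum())
    if size == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / size


def generalized_dice(
    img_i,
    img_s,
    labels=None,
    dissimilarity: bool = False,
) -> float:
    """Generalised Dice similarity coefficient over a set of labels.

    gDSC = 2 * sum_l |I_l ∩ S_l| / sum_l (|I_l| + |S_l|), the Dice
    numerators and denominators pooled across labels. With a single
    label this reduces exactly to binary Dice. An empty union over all
    labels scores 1 (identical emptiness).

    ``dissimilarity=True`` returns 1 - gDSC instead (an audit switch for
    the complementary convention).
    """
    arr_i = img_i.labels if isinstance(img_i, LabelImage) else np.asarray(img_i)
    arr_s = img_s.labels if isinstance(img_s, LabelImage) else np.asarray(img_s)
    if arr_i.shape != arr_s.shape:
        raise ValueError("label images must share one shape")
    if labels is None:
        labels = sorted(
            set(int(l) for l in np.unique(arr_i) if l != 0)
            | set(int(l) for l in np.unique(arr_s) if l != 0)
        )
    labels = list(labels)
    if not labels:
        raise ValueError("label list is empty")
    inter = 0
    total = 0
    for lab in labels:
        in_i = arr_i == lab
        in_s = arr_s == lab
        inter += int((in_i & in_s).sum())
        total += int(in_i.sum()) + int(in_s.sum())
    value = 1.0 if total == 0 else 2.0 * inter / total
    return 1.0 - value if dissimilarity else value


def _neighbor18_structure() -> np.ndarray:
    # faces + edges, no corners, no centre
    struct = ndimage.generate_binary_structure(3, 2)
    struct[1, 1, 1] = False
    return struct


def interface_restrict(labels, wm_mask: np.ndarray):
    """Keep only label voxels in 18-connected contact with white matter.

    A voxel survives if at least one of its 18 neighbours (6 faces + 12
    edges; the 8 corners do not count) lies inside ``wm_mask``. Used to
    restrict parcellation labels to the GM/WM interface from which
    tractography is seeded.
    """
    arr = labels.labels if isinstance(labels, LabelImage) else np.asarray(labels)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if arr.shape != wm_mask.shape:
        raise ValueError("labels and wm_mask must share one shape")
    touching = ndimage.binary_dilation(wm_mask, structure=_neighbor18_structure())
    restricted = np.where(touching, arr, 0)
    if isinstance(labels, LabelImage):
        return LabelImage(labels=restricted, grid=labels.grid, names=dict(labels.names))
    return restricted
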