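"""Deterministic, atomic NIfTI writing.

Plain ``to_filename`` on a ``.nii.gz`` path can embed a timestamp in the
gzip header, so two otherwise identical runs would differ at the byte
level. All pipeline outputs instead go through :func:`save_deterministic`,
which serialises in memory, gzip-compresses with mtime pinned to 0 and
writes via a temp-file-and-rename so a failed run never leaves a
truncated image behind.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import nibabel as nib

__all__ = ["save_deterministic"]


def save_deterministic(img: nib.Nifti1Image, path) -> Path:
    path = Path(path)
    raw = img.to_bytes()
    if path.name.endswith(".gz"):
        raw = gzip.compress(raw, mtime=0)
    tmp = path.with_name(path.name + ".part")
    try:
        with open(tmp, "wb") as fh:
            fh.write(raw)
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()
    return path
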