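"""Multi-page TIFF stack I/O.

Thin wrappers over :mod:`tifffile` so the rest of the package never touches
the format directly. Stacks are written one page per z slice; RI volumes as
32-bit float, label masks as 8-bit unsigned.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a 2D image or 3D (z, y, x) stack, one TIFF page per slice."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("expected a 2D image or 3D (z, y, x) stack")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (z, y, x) array (2D inputs gain a z axis)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale stack, got shape {arr.shape}")
    return arr
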