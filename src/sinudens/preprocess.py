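"""Preprocessing of tomographic slices: impulse-noise suppression and
Hounsfield display windowing.

Median filtering is applied slice-by-slice (tomographic images are 2-D
products; filtering across slices would mix anatomy separated by the
slice step).  Windowing maps an Hu interval ``[center − width/2,
center + width/2]`` linearly onto the 8-bit display range with clipping,
the standard soft-tissue display transform.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["median_filter", "hu_window_to_8bit"]


def median_filter(volume: Volume, window_radius: int = 1) -> Volume:
    """Per-slice 2-D median filter with a (2r+1)² neighbourhood.

    Edges are handled by reflection.  Removes isolated impulse voxels
    while never introducing values absent from the input neighbourhood.
    """
    r = int(window_radius)
    if r < 1:
        raise ValueError(f"window_radius must be >= 1, got {window_radius}")
    out = np.empty_like(volume.data)
    for k in range(volume.n_slices):
        out[k] = ndimage.median_filter(volume.data[k], size=2 * r + 1, mode="reflect")
    return Volume(out, volume.spacing_mm, volume.unit, volume.window)


def hu_window_to_8bit(volume: Volume, center: float, width: float) -> Volume:
    """Window an Hu volume to 8-bit display values.

    ``[center − width/2, center + width/2]`` maps linearly to [0, 255];
    values outside clip to the endpoints.  Rounding is half-up so the
    result is platform-independent.
    """
    if volume.unit != "hu":
        raise ValueError("hu_window_to_8bit requires a volume in Hu units")
    width = float(width)
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    lo = float(center) - width / 2.0
    scaled = (volume.data.astype(np.float64) - lo) / width * 255.0
    rounded = np.floor(scaled + 0.5)  # half-up
    clipped = np.clip(rounded, 0, 255).astype(np.uint8)
    return Volume(clipped, volume.spacing_mm, "8bit", window=(float(center), width))
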