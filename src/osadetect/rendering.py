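"""Shared raster helpers: colormap application and bilinear resizing.

A single perceptually uniform colormap (default ``viridis``) is pinned so that
rendered images are byte-stable across runs; tests rely on this determinism.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

IMAGE_SIZE = 224
DEFAULT_COLORMAP = "viridis"


def apply_colormap(u: np.ndarray, colormap: str = DEFAULT_COLORMAP) -> np.ndarray:
    """Map values in [0, 1] through a named colormap to an RGB float array."""
    cmap = colormaps[colormap]
    rgba = cmap(np.clip(u, 0.0, 1.0))
    return rgba[..., :3].astype(np.float64)


def resize_bilinear(img: np.ndarray, size: int = IMAGE_SIZE) -> np.ndarray:
    """Bilinearly resize an HxWx3 image to size x size, clipped to [0, 1].

    Axes that are shrunk are Gaussian-prefiltered (anti-aliasing) before the
    bilinear interpolation; an already correctly sized image passes through
    untouched.
    """
    if img.shape[:2] == (size, size):
        return np.clip(img, 0.0, 1.0)
    out = resize(img, (size, size), order=1, mode="reflect",
                 preserve_range=True, anti_aliasing=None)
    return np.clip(out, 0.0, 1.0)
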