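"""Synthetic colony-array plate images.

Renders a 16 x 24 grid of circular colonies on a uniform non-green
background.  Colony darkness d in [0, 1] sets the green channel to
``200 - 140 * d``, the same linear range the analyzer's darkness score
inverts, so generated darkness values are recoverable (up to the 0.5-1
clamp).
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk

__all__ = ["simulate_plate", "BACKGROUND_RGB"]

#: Background color; green does not dominate, so it segments as background.
BACKGROUND_RGB = (200, 190, 215)


def simulate_plate(
    radii: np.ndarray,
    darkness: np.ndarray,
    cell_px: int = 24,
    seed: int | None = None,
) -> np.ndarray:
    """Render a synthetic plate image.

    Parameters
    ----------
    radii
        (16, 24) array of colony radii in pixels; 0 means no colony.
    darkness
        (16, 24) array of colony darkness in [0, 1].
    cell_px
        Grid cell edge length in pixels.  Colonies larger than half a cell
        would overlap neighbours and are rejected.

    Returns a uint8 RGB image of shape (16*cell_px, 24*cell_px, 3).
    """
    radii = np.asarray(radii, dtype=float)
    darkness = np.asarray(darkness, dtype=float)
    if radii.shape != darkness.shape:
        raise ValueError("radii and darkness must have the same shape")
    if (radii < 0).any():
        raise ValueError("radii must be non-negative")
    if ((darkness < 0) | (darkness > 1)).any():
        raise ValueError("darkness must lie in [0, 1]")
    if (radii > cell_px / 2).any():
        raise ValueError("colony radius exceeds half a grid cell (overlap)")

    n_rows, n_cols = radii.shape
    img = np.empty((n_rows * cell_px, n_cols * cell_px, 3), dtype=np.uint8)
    img[..., 0] = BACKGROUND_RGB[0]
    img[..., 1] = BACKGROUND_RGB[1]
    img[..., 2] = BACKGROUND_RGB[2]

    for r in range(n_rows):
        for c in range(n_cols):
            radius = radii[r, c]
            if radius <= 0:
                continue
            center = ((r + 0.5) * cell_px, (c + 0.5) * cell_px)
            rr, cc = disk(center, radius, shape=img.shape[:2])
            green = int(round(200.0 - 140.0 * darkness[r, c]))
            img[rr, cc] = (40, green, 40)
    return img
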