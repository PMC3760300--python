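"""Small shared oracles, kept independent of the package internals."""

import numpy as np


def independent_box_count(pixels, eps):
    """Count nonempty eps-boxes by explicit tiling (no integral image)."""
    pixels = np.asarray(pixels)
    ny, nx = pixels.shape
    count = 0
    for i in range(0, ny, eps):
        for j in range(0, nx, eps):
            if pixels[i : i + eps, j : j + eps].sum() > 0:
                count += 1
    return count
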