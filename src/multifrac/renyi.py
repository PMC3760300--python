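"""Natural measures and the Renyi entropy spectrum H_alpha(eps).

At a box side ``eps`` the image is tiled into ``eps x eps`` squares and
the *natural measure* of box *i* is the fraction of the total image
intensity it contains,

    mu_i = (sum of intensities in box i) / (sum over the whole image),

so that ``sum_i mu_i = 1`` at every scale.  The order-``alpha`` Renyi
entropy of the box measures is

    H_alpha = 1 / (1 - alpha) * log( sum_i mu_i ** alpha ),    (nats)

with the usual limits: ``H_0`` is the log of the number of nonempty
boxes (box counting), and ``H_1`` is the Shannon entropy
``-sum mu_i log mu_i``.  Boxes with ``mu_i = 0`` contribute nothing to
any of the sums.  ``H_alpha`` is nonincreasing in ``alpha``.

The full spectrum over a grid of scales shares a single integral image,
so a dense scale sweep costs little more than one pass over the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .sat import IntensityImage, as_intensity_image, coarse_grain, compute_integral_image

__all__ = [
    "MeasureGrid",
    "EntropyCurve",
    "natural_measures",
    "renyi_entropy",
    "entropy_spectrum",
    "default_scales",
    "NATS_PER_BIT",
]

# 1 nat = 1/log(2) bits; curves are computed and stored in nats
NATS_PER_BIT = float(np.log(2.0))

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class MeasureGrid:
    """Per-box natural measures at one scale."""

    mu: np.ndarray
    eps: int

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if (mu < -_NORM_TOL).any():
            raise ValueError("box measures must be nonnegative")
        object.__setattr__(self, "mu", np.clip(mu, 0.0, None))

    @property
    def is_normalized(self) -> bool:
        return abs(float(self.mu.sum()) - 1.0) <= 1e-6


@dataclass(frozen=True)
class EntropyCurve:
    """Renyi entropies over a grid of scales and orders.

    ``H[i, j]`` is the entropy (nats) at ``scales[i]`` and ``alphas[j]``.
    """

    scales: np.ndarray
    alphas: np.ndarray
    H: np.ndarray
    image_id: str = "image"
    pixel_size: Optional[float] = None

    def scales_um(self) -> Optional[np.ndarray]:
        if self.pixel_size is None:
            return None
        return self.scales * self.pixel_size

    def column(self, alpha: float) -> np.ndarray:
        """Entropy values for one order ``alpha``."""
        j = np.nonzero(np.isclose(self.alphas, alpha))[0]
        if len(j) == 0:
            raise KeyError(f"order alpha={alpha} not in curve (has {self.alphas})")
        return self.H[:, j[0]]

    def to_frame(self, bits: bool = False) -> pd.DataFrame:
        """Tidy table: (image_id, eps_px, eps_um, alpha, H_nats [, H_bits])."""
        eps_um = self.scales_um()
        rows = {
            "image_id": np.repeat(self.image_id, self.H.size),
            "eps_px": np.repeat(self.scales, len(self.alphas)),
            "eps_um": (
                np.repeat(eps_um, len(self.alphas)) if eps_um is not None else np.nan
            ),
            "alpha": np.tile(self.alphas, len(self.scales)),
            "H_nats": self.H.ravel(),
        }
        df = pd.DataFrame(rows)
        if bits:
            df["H_bits"] = df["H_nats"] / NATS_PER_BIT
        return df


def natural_measures(img: Union[IntensityImage, np.ndarray], eps: int) -> MeasureGrid:
    """Box measures mu_i at scale ``eps`` (box sums over total intensity)."""
    im = as_intensity_image(img)
    if im.total <= 0:
        raise ValueError("image has zero total intensity; natural measures undefined")
    B = compute_integral_image(im)
    grid = coarse_grain(B, eps)
    return MeasureGrid(mu=grid / B.total, eps=int(eps))


def renyi_entropy(m: Union[MeasureGrid, np.ndarray], alpha: float) -> float:
    """Order-``alpha`` Renyi entropy of a normalised measure grid, in nats.

    ``alpha = 0``: log of the number of boxes with positive measure.
    ``alpha = 1``: Shannon entropy by its closed form (never a numeric
    limit).  Other orders use the generic formula restricted to the
    positive-measure boxes.
    """
    mu = m.mu if isinstance(m, MeasureGrid) else np.asarray(m, dtype=float)
    total = float(mu.sum())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"measures must sum to 1 (got {total}); normalise first")
    pos = mu[mu > 0].ravel()
    if alpha == 0:
        return float(np.log(pos.size))
    if alpha == 1:
        return float(-np.sum(pos * np.log(pos)))
    return float(np.log(np.sum(pos**alpha)) / (1.0 - alpha))


def default_scales(shape: tuple, max_points: int = 40) -> np.ndarray:
    """Default scale grid for an image of the given shape.

    All integers ``2 .. min(side)/4`` for small images; roughly
    ``max_points`` log-spaced integers for images above 512 px (the
    derivative is taken in log eps, so log spacing loses nothing).
    """
    top = max(int(min(shape) // 4), 2)
    if min(shape) <= 512 or top - 1 <= max_points:
        return np.arange(2, top + 1)
    grid = np.unique(
        np.round(np.geomspace(2, top, max_points)).astype(int)
    )
    return grid


def entropy_spectrum(
    img: Union[IntensityImage, np.ndarray],
    scales: Optional[Sequence[int]] = None,
    alphas: Sequence[float] = (0.0, 1.0, 2.0),
    allow_negative_alpha: bool = False,
) -> EntropyCurve:
    """Renyi entropies H_alpha(eps) over a grid of scales and orders.

    One integral image is shared across all scales.  Negative orders are
    refused by default: with empty boxes present, ``sum mu^alpha``
    diverges under the slightest noise.
    """
    im = as_intensity_image(img)
    if im.total <= 0:
        raise ValueError("image has zero total intensity")
    if scales is None:
        scales = default_scales(im.pixels.shape)
    scales = np.asarray(scales)
    if scales.size == 0:
        raise ValueError("empty scale list")
    if not np.issubdtype(scales.dtype, np.integer) or (scales < 1).any():
        raise ValueError("scales must be positive integers (pixels)")
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size == 0:
        raise ValueError("empty alpha list")
    if (alphas < 0).any() and not allow_negative_alpha:
        raise ValueError(
            "negative orders are refused by default (empty boxes make "
            "sum(mu**alpha) divergence-prone); pass allow_negative_alpha=True"
        )

    B = compute_integral_image(im)
    total = B.total
    H = np.empty((len(scales), len(alphas)), dtype=float)
    for i, eps in enumerate(scales):
        mu = coarse_grain(B, int(eps)) / total
        pos = mu[mu > 0].ravel()
        logpos = np.log(pos)
        for j, a in enumerate(alphas):
            if a == 0:
                H[i, j] = np.log(pos.size)
            elif a == 1:
                H[i, j] = -np.sum(pos * logpos)
            else:
                H[i, j] = np.log(np.sum(np.exp(a * logpos))) / (1.0 - a)
    return EntropyCurve(
        scales=scales,
        alphas=alphas,
        H=H,
        image_id=im.image_id,
        pixel_size=im.pixel_size,
    )
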