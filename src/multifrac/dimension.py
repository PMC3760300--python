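"""Scale-dependent generalized dimensions via LOWESS differentiation.

A real image has no limiting fractal dimension; what it has is a
scaling exponent that changes with the analysis scale.  We therefore
estimate

    D_alpha(eps) = - d H_alpha / d log(eps)

by locally weighted polynomial regression (LOWESS) of the entropy
against ``x = log(eps)``.  Around each evaluation point ``x0`` a
polynomial ``p`` of low degree is fitted by weighted least squares with
Gaussian weights

    w(x) = exp(-((x - x0) / sigma)**2),

and the derivative of the local fit, ``p'(x0)``, stands in for the
derivative of the underlying curve.  Larger ``sigma`` trades scale
resolution for noise resistance.  ``sigma`` is measured in natural-log
scale units; the defaults used throughout the package are
``sigma = 0.5`` and a quadratic local polynomial.

Fits at the extreme ends of the scale grid lean on one-sided weight
mass; those estimates carry an ``edge`` flag so users can trim them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .renyi import EntropyCurve

__all__ = [
    "DimensionCurve",
    "gaussian_weights",
    "lowess_fit",
    "lowess_derivative",
    "dimension_curve",
]

# weights below this are treated as numerically absent when checking
# that the local design has enough effective points
_EFFECTIVE_WEIGHT = 1e-8


@dataclass(frozen=True)
class DimensionCurve:
    """D_alpha(eps) estimates with the smoothing used to produce them.

    ``D[i, j]`` is the dimension estimate at ``scales[i]``, order
    ``alphas[j]``.  ``edge[i]`` is True where the local fit at scale i
    had one-sided weight mass (within ``sigma`` of the grid ends).
    """

    scales: np.ndarray
    alphas: np.ndarray
    D: np.ndarray
    sigma: float
    degree: int
    edge: np.ndarray
    image_id: str = "image"
    pixel_size: Optional[float] = None

    def scales_um(self) -> Optional[np.ndarray]:
        if self.pixel_size is None:
            return None
        return self.scales * self.pixel_size

    def column(self, alpha: float) -> np.ndarray:
        j = np.nonzero(np.isclose(self.alphas, alpha))[0]
        if len(j) == 0:
            raise KeyError(f"order alpha={alpha} not in curve (has {self.alphas})")
        return self.D[:, j[0]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: (image_id, eps_px, eps_um, alpha, D, sigma, degree, edge_flag)."""
        eps_um = self.scales_um()
        na = len(self.alphas)
        return pd.DataFrame(
            {
                "image_id": np.repeat(self.image_id, self.D.size),
                "eps_px": np.repeat(self.scales, na),
                "eps_um": np.repeat(eps_um, na) if eps_um is not None else np.nan,
                "alpha": np.tile(self.alphas, len(self.scales)),
                "D": self.D.ravel(),
                "sigma": self.sigma,
                "degree": self.degree,
                "edge_flag": np.repeat(self.edge, na),
            }
        )


def gaussian_weights(x0: float, xs: Sequence[float], sigma: float) -> np.ndarray:
    """Gaussian locality weights ``exp(-((x - x0)/sigma)**2)``."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    xs = np.asarray(xs, dtype=float)
    return np.exp(-(((xs - x0) / sigma) ** 2))


def lowess_fit(
    xs: Sequence[float],
    ys: Sequence[float],
    x0: float,
    sigma: float,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial coefficients around ``x0`` (ascending powers of x - x0).

    Minimises ``sum_i w_i (y_i - p(x_i))**2`` with Gaussian weights.
    Centring the basis on ``x0`` makes ``coef[1]`` the derivative of
    the local fit at ``x0``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be 1-D arrays of equal length")
    if len(np.unique(xs)) != len(xs):
        raise ValueError("abscissae must be distinct")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    w = gaussian_weights(x0, xs, sigma)
    effective = int(np.count_nonzero(w > _EFFECTIVE_WEIGHT))
    if effective < degree + 1:
        raise ValueError(
            f"rank-deficient local fit at x0={x0}: {effective} points with "
            f"nonnegligible weight, need >= {degree + 1}; increase sigma or "
            "densify the scale grid"
        )
    t = xs - x0
    V = np.vander(t, N=degree + 1, increasing=True)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(V * sw[:, None], ys * sw, rcond=None)
    return coef


def lowess_derivative(
    xs: Sequence[float],
    ys: Sequence[float],
    x0: float,
    sigma: float,
    degree: int = 2,
) -> float:
    """Derivative at ``x0`` of the Gaussian-weighted local polynomial fit."""
    if degree < 1:
        raise ValueError("derivative estimation needs degree >= 1")
    return float(lowess_fit(xs, ys, x0, sigma, degree)[1])


def dimension_curve(
    H: EntropyCurve,
    sigma: float = 0.5,
    degree: int = 2,
) -> DimensionCurve:
    """Differentiate an entropy curve into D_alpha(eps) = -dH/dlog(eps).

    The LOWESS fit is evaluated at the observed log-scale grid itself;
    no interpolation grid is introduced.  Requires at least
    ``degree + 2`` scales.
    """
    scales = np.asarray(H.scales)
    if len(scales) < max(4, degree + 2):
        raise ValueError(
            f"need at least {max(4, degree + 2)} scales to differentiate, "
            f"got {len(scales)}"
        )
    x = np.log(scales.astype(float))
    D = np.empty_like(H.H)
    for j in range(H.H.shape[1]):
        y = H.H[:, j]
        for i, x0 in enumerate(x):
            D[i, j] = -lowess_derivative(x, y, x0, sigma=sigma, degree=degree)
    edge = (x - x.min() < sigma) | (x.max() - x < sigma)
    return DimensionCurve(
        scales=scales,
        alphas=np.asarray(H.alphas),
        D=D,
        sigma=float(sigma),
        degree=int(degree),
        edge=edge,
        image_id=H.image_id,
        pixel_size=H.pixel_size,
    )
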