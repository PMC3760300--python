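"""Seeded generators of fractal renderings with known Hausdorff dimensions.

These are the validation fixtures for the dimension estimator: every
generator attaches the exact Hausdorff dimension of the mathematical
set it renders, so estimator tests consume only that metadata and never
hard-code per-fixture numbers.

Deterministic sets
------------------
* Koch snowflake boundary, D_H = log 4 / log 3 ~ 1.2619
* Quadric Koch island boundary (Minkowski sausage), D_H = 3/2
* Sierpinski carpet, D_H = log 8 / log 3 ~ 1.8928
* Pascal's triangle mod 3 (Lucas construction), D_H = log 6 / log 3 ~ 1.6309

Statistical sets
----------------
* Chaos-game Sierpinski triangle, D_H = log 3 / log 2 ~ 1.585
* Fractional Brownian surfaces (exact circulant-embedding synthesis,
  Hurst H = 3 - D); their level-set outlines have dimension D - 1.

Curves are rasterised at 1-px stroke width with no anti-aliasing:
fixtures are binary, because gray strokes would perturb the entropies
of order alpha > 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.draw import line as _draw_line

from .sat import IntensityImage

__all__ = [
    "FractalRendering",
    "koch_snowflake",
    "koch_island",
    "sierpinski_carpet",
    "pascal_mod3",
    "chaos_game_sierpinski",
    "brownian_surface",
    "surface_outline",
    "GENERATORS",
]


@dataclass(frozen=True)
class FractalRendering:
    """A rendered fractal plus the ground truth it was rendered from."""

    image: np.ndarray
    name: str
    theoretical_dimension: Optional[float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.size == 0:
            raise ValueError("rendering is empty")
        d = self.theoretical_dimension
        if d is not None and not (0.0 <= d <= 2.0):
            raise ValueError(f"theoretical planar dimension {d} outside [0, 2]")

    def to_intensity(self, pixel_size: Optional[float] = None) -> IntensityImage:
        return IntensityImage(
            self.image.astype(float), pixel_size=pixel_size, image_id=self.name
        )

    def metadata(self) -> dict:
        return {
            "name": self.name,
            "theoretical_dimension": self.theoretical_dimension,
            "shape": list(self.image.shape),
            "params": self.params,
        }


def _rasterize_polyline(points: np.ndarray, size: int, closed: bool = True) -> np.ndarray:
    """Draw a polyline of float vertices as 1-px binary strokes.

    Vertices are scaled to fit the canvas with a 2-px margin, preserving
    aspect ratio, then each segment is drawn with Bresenham's line.
    Returns the canvas and leaves the fitted vertices on the caller via
    the returned tuple.
    """
    pts = np.asarray(points, dtype=float)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = float(max(hi - lo))
    margin = 2.0
    scale = (size - 1 - 2 * margin) / span
    fitted = (pts - lo) * scale + margin
    # centre the shorter axis
    fitted += (size - 1 - 2 * margin - (hi - lo) * scale) / 2.0

    img = np.zeros((size, size), dtype=np.uint8)
    idx = np.rint(fitted).astype(int)
    n = len(idx)
    last = n if closed else n - 1
    for k in range(last):
        r0, c0 = idx[k % n][1], idx[k % n][0]
        r1, c1 = idx[(k + 1) % n][1], idx[(k + 1) % n][0]
        rr, cc = _draw_line(r0, c0, r1, c1)
        img[rr, cc] = 1
    seg_lengths = np.linalg.norm(np.diff(fitted, axis=0, append=fitted[:1]), axis=1)
    if closed:
        min_seg = float(seg_lengths.min())
    else:
        min_seg = float(seg_lengths[:-1].min()) if n > 1 else 0.0
    if min_seg < 1.0:
        warnings.warn(
            f"minimum rendered segment {min_seg:.2f} px is sub-pixel; "
            "reduce iterations or enlarge the canvas",
            stacklevel=3,
        )
    return img, min_seg


def _koch_refine(points: np.ndarray, closed: bool = True) -> np.ndarray:
    """One triadic Koch step: each segment -> 4 segments with a 60-degree bump."""
    z = points[:, 0] + 1j * points[:, 1]
    z2 = np.roll(z, -1) if closed else z[1:]
    z1 = z if closed else z[:-1]
    d = (z2 - z1) / 3.0
    a = z1 + d
    b = z1 + 2 * d
    peak = a + d * np.exp(-1j * np.pi / 3.0)
    new = np.empty(4 * len(z1) + (0 if closed else 1), dtype=complex)
    new[0::4][: len(z1)] = z1
    new[1::4] = a
    new[2::4] = peak
    new[3::4] = b
    if not closed:
        new[-1] = z[-1]
    return np.column_stack([new.real, new.imag])


def koch_snowflake(size_px: int = 1024, iterations: int = 5) -> FractalRendering:
    """Rasterised Koch snowflake boundary; D_H = log4/log3.

    Starts from an equilateral triangle and applies ``iterations``
    triadic refinements (3 * 4**k segments), then fits the curve to the
    canvas and draws 1-px strokes.
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    pts = np.array(
        [
            [0.0, 0.0],
            [1.0, 0.0],
            [0.5, math.sqrt(3.0) / 2.0],
        ]
    )
    for _ in range(iterations):
        pts = _koch_refine(pts, closed=True)
    img, min_seg = _rasterize_polyline(pts, size_px, closed=True)
    return FractalRendering(
        image=img,
        name=f"koch_snowflake_{size_px}px_k{iterations}",
        theoretical_dimension=math.log(4) / math.log(3),
        params={
            "size_px": size_px,
            "iterations": iterations,
            "segments": 3 * 4**iterations,
            "min_segment_px": min_seg,
        },
    )


def _quadric_refine(points: np.ndarray) -> np.ndarray:
    """One quadric Koch step: each segment -> 8 segments of 1/4 length."""
    z = points[:, 0] + 1j * points[:, 1]
    z2 = np.roll(z, -1)
    d = (z2 - z) / 4.0
    n = d * 1j  # left normal, length |d|
    out = np.empty(8 * len(z), dtype=complex)
    out[0::8] = z
    out[1::8] = z + d
    out[2::8] = z + d + n
    out[3::8] = z + 2 * d + n
    out[4::8] = z + 2 * d
    out[5::8] = z + 2 * d - n
    out[6::8] = z + 3 * d - n
    out[7::8] = z + 3 * d
    return np.column_stack([out.real, out.imag])


def koch_island(size_px: int = 2048, iterations: int = 4) -> FractalRendering:
    """Quadric Koch island (Minkowski sausage) boundary; D_H = 3/2.

    A square initiator whose edges are refined into 8 sub-segments of a
    quarter length per step (4 * 8**k segments total).  The minimum
    rendered segment length in pixels is recorded in ``params``: the
    curve is genuinely one-dimensional below that length, so the
    estimated dimension breaks from ~1 toward 3/2 around it.
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    for _ in range(iterations):
        pts = _quadric_refine(pts)
    img, min_seg = _rasterize_polyline(pts, size_px, closed=True)
    return FractalRendering(
        image=img,
        name=f"koch_island_{size_px}px_k{iterations}",
        theoretical_dimension=1.5,
        params={
            "size_px": size_px,
            "iterations": iterations,
            "segments": 4 * 8**iterations,
            "min_segment_px": min_seg,
        },
    )


def sierpinski_carpet(power_of_three: int = 7) -> FractalRendering:
    """Exact 3**k x 3**k binary Sierpinski carpet; D_H = log8/log3.

    A pixel (i, j) is filled unless some base-3 digit position has
    digit 1 in both i and j; filled-pixel count is exactly 8**k.
    """
    k = int(power_of_three)
    if k < 1:
        raise ValueError("power_of_three must be >= 1")
    n = 3**k
    ii = np.arange(n)
    filled = np.ones((n, n), dtype=bool)
    i = ii.copy()
    j = ii.copy()
    for _ in range(k):
        di = (i % 3)[:, None]
        dj = (j % 3)[None, :]
        filled &= ~((di == 1) & (dj == 1))
        i //= 3
        j //= 3
    return FractalRendering(
        image=filled.astype(np.uint8),
        name=f"sierpinski_carpet_3^{k}",
        theoretical_dimension=math.log(8) / math.log(3),
        params={"power_of_three": k, "size_px": n, "filled": int(8**k)},
    )


def pascal_mod3(size_px: int = 2187) -> FractalRendering:
    """Binomial coefficients not divisible by 3, rendered row by row.

    By Lucas' theorem C(n, k) is nonzero mod 3 exactly when every
    base-3 digit of k is <= the matching digit of n, so the image can be
    built digit-wise without computing any binomials.  The rendering is
    self-similar with characteristic triangle sizes 3, 9, 27, ... px;
    D_H = log6/log3.
    """
    n_rows = int(size_px)
    if n_rows < 3:
        raise ValueError("size_px must be >= 3")
    nn = np.arange(n_rows)
    ok = np.ones((n_rows, n_rows), dtype=bool)
    a = nn.copy()  # row index n
    b = nn.copy()  # column index k
    steps = int(math.ceil(math.log(n_rows) / math.log(3)))
    for _ in range(steps):
        ok &= (b % 3)[None, :] <= (a % 3)[:, None]
        a //= 3
        b //= 3
    ok &= nn[None, :] <= nn[:, None]  # triangle support k <= n
    return FractalRendering(
        image=ok.astype(np.uint8),
        name=f"pascal_mod3_{n_rows}px",
        theoretical_dimension=math.log(6) / math.log(3),
        params={"size_px": n_rows},
    )


def chaos_game_sierpinski(
    n_points: int,
    size_px: int = 2000,
    seed: int = 0,
    burn_in: int = 10,
) -> FractalRendering:
    """Statistical Sierpinski triangle by the chaos game; D_H = log3/log2.

    Starting from the triangle centroid, each step moves halfway toward
    a uniformly chosen vertex and plots the new point as a single
    pixel.  The first ``burn_in`` transient points are discarded, so the
    rendering contains exactly ``n_points`` plotted iterates (sparse
    renderings look point-like at small scales and only fill in the
    ideal scaling as n grows).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if size_px < 8:
        raise ValueError("size_px must be >= 8")
    rng = np.random.default_rng(seed)
    m = 1.0
    verts = np.array(
        [
            [size_px / 2.0, m],
            [m, size_px - 1 - m],
            [size_px - 1 - m, size_px - 1 - m],
        ]
    )
    p = verts.mean(axis=0)
    choices = rng.integers(0, 3, size=burn_in + n_points)
    pts = np.empty((burn_in + n_points, 2))
    for t, c in enumerate(choices):
        p = (p + verts[c]) / 2.0
        pts[t] = p
    kept = pts[burn_in:]
    img = np.zeros((size_px, size_px), dtype=np.uint8)
    idx = np.rint(kept).astype(int)
    img[idx[:, 1], idx[:, 0]] = 1
    return FractalRendering(
        image=img,
        name=f"chaos_sierpinski_n{n_points}_{size_px}px_s{seed}",
        theoretical_dimension=math.log(3) / math.log(2),
        params={
            "n_points": n_points,
            "size_px": size_px,
            "seed": seed,
            "burn_in": burn_in,
            "vertices": verts.tolist(),
        },
    )


def brownian_surface(
    size_px: int = 1025,
    surface_dimension: float = 2.5,
    seed: int = 0,
) -> FractalRendering:
    """Fractional Brownian random field by exact circulant-embedding synthesis.

    The graph of a fractional Brownian field with Hurst exponent H has
    dimension 3 - H, so a requested surface dimension D in (2, 3) maps
    to H = 3 - D.  Synthesis follows Stein's construction: a stationary
    Gaussian field with the compactly supported covariance

        c(r) = c0 + c2 r^2 - r^(2H)          (r <= 1)
        c(r) = beta (R - r)^3 / r            (1 < r <= R = 2)

    is drawn exactly by circulant embedding on a torus, and adding an
    independent random linear drift with variance 2 c2 per unit axis
    turns it into a field with the exact fractional-Brownian covariance
    (|s|^2H + |t|^2H - |s - t|^2H) / 2 on the unit square (beta, c2, c0
    are fixed by smoothness at r = 1; beta = 0 when 2H <= 1.5).  Unlike
    plain spectral (Fourier-filter) synthesis, the increment variance
    follows lag^(2H) without bias at low Hurst, which the
    structure-function check relies on.  The field is standardised to
    zero mean and unit variance (overall scale carries no geometric
    information).

    The rendering itself is a grayscale height field living in 3-space,
    so it carries no planar theoretical dimension; use
    :func:`surface_outline` to obtain the (D - 1)-dimensional level-set
    boundary fixture.
    """
    if not (2.0 < surface_dimension < 3.0):
        raise ValueError(
            f"surface_dimension must lie in (2, 3), got {surface_dimension}"
        )
    hurst = 3.0 - surface_dimension
    n = int(size_px)
    if n < 2:
        raise ValueError("size_px must be >= 2")
    alpha = 2.0 * hurst
    R = 2.0
    if alpha <= 1.5:
        beta, c2, c0 = 0.0, alpha / 2.0, 1.0 - alpha / 2.0
    else:
        beta = alpha * (2.0 - alpha) / (3.0 * R * (R**2 - 1.0))
        c2 = (alpha - beta * (R - 1.0) ** 2 * (R + 2.0)) / 2.0
        c0 = beta * (R - 1.0) ** 3 + 1.0 - c2
    # torus large enough that the kernel's support never wraps
    m = (2 if beta == 0.0 else 4) * (n - 1)
    h = 1.0 / (n - 1)
    ax = np.arange(m) * h
    ax = np.minimum(ax, m * h - ax)
    r = np.hypot(ax[:, None], ax[None, :])
    ker = np.where(
        r <= 1.0,
        c0 + c2 * r**2 - np.power(np.maximum(r, np.finfo(float).tiny), alpha),
        0.0,
    )
    if beta > 0.0:
        mid = (r > 1.0) & (r <= R)
        ker[mid] = beta * (R - r[mid]) ** 3 / r[mid]
    del r, ax
    lam = np.fft.fft2(ker).real
    del ker
    np.clip(lam, 0.0, None, out=lam)  # clip FFT round-off negatives
    rng = np.random.default_rng(seed)
    eps = (rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m))) / np.sqrt(2.0)
    Y = np.fft.fft2(np.sqrt(lam) * eps).real * (np.sqrt(2.0) / m)
    del lam, eps
    Y = Y[:n, :n]
    field = (Y - Y.mean()) / Y.std()
    return FractalRendering(
        image=field,
        name=f"brownian_surface_D{surface_dimension:g}_{n}px_s{seed}",
        theoretical_dimension=None,
        params={
            "size_px": n,
            "surface_dimension": surface_dimension,
            "hurst": hurst,
            "seed": seed,
        },
    )


def surface_outline(
    surface: FractalRendering,
    level: Optional[float] = None,
) -> FractalRendering:
    """Level-set boundary of a Brownian surface; dimension D_surface - 1.

    The super-level set ``field >= level`` (default: the median height,
    which splits the field roughly in half) is reduced to its boundary
    pixels: the set minus its one-pixel 8-connected erosion.
    """
    field = surface.image
    if level is None:
        level = float(np.median(field))
    mask = field >= level
    outline = mask & ~binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    d_surf = surface.params.get("surface_dimension")
    return FractalRendering(
        image=outline.astype(np.uint8),
        name=surface.name.replace("surface", "outline"),
        theoretical_dimension=None if d_surf is None else d_surf - 1.0,
        params={**surface.params, "level": level},
    )


GENERATORS = {
    "koch-snowflake": koch_snowflake,
    "koch-island": koch_island,
    "sierpinski-carpet": sierpinski_carpet,
    "pascal-mod3": pascal_mod3,
    "chaos-sierpinski": chaos_game_sierpinski,
    "brownian-surface": brownian_surface,
}
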