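"""Parametric leaf silhouettes with analytically known geometry.

Stands in for scanned leaves: every rendered raster comes with its exact
continuous-geometry ground truth (boundary, centroid, polar radii, classic
size traits), so the pixel-based measurement pipeline can be validated
end to end.

Shapes are defined in an upright leaf frame (length axis vertical, tip at
+y) by a polar boundary function about the shape's construction centre:

    circle           rho(theta) = a
    ellipse          rho(theta) = a b / sqrt(a^2 cos^2 + b^2 sin^2)
    rectangle        width 2b, height 2a
    parametric-leaf  tapered ellipse: the ellipse radius modulated by
                     1 - tip_taper * s^2 (1 - s^2) for s = sin(theta) > 0
                     and 1 - base_taper * s^2 (1 - s^2) for s < 0,

where a is the semi-length (mm) and b the semi-width (mm).  For asymmetric
taper the centroid moves off the construction centre; the ground truth is
evaluated on a dense (2^16-point) boundary polyline, which is exact to well
below raster resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phenotype import chord_widths

FAMILIES = ("circle", "ellipse", "rectangle", "parametric-leaf")
_DENSE = 1 << 16
_RASTER_DECIMATE = 8  # boundary points used for rasterization: _DENSE / this


@dataclass(frozen=True)
class LeafShapeParams:
    family: str = "parametric-leaf"
    a: float = 60.0            # semi-length, mm
    b: float = 40.0            # semi-width, mm
    tip_taper: float = 0.6
    base_taper: float = 0.15
    rotation_deg: float = 0.0  # rotation applied before rasterization
    pixels_per_mm: float = 11.811  # 300 dpi
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")
        if self.pixels_per_mm <= 0:
            raise ValueError("pixels_per_mm must be positive")


@dataclass
class LeafTruth:
    """Exact geometry of a rendered leaf, in the image mm frame (y up)."""

    boundary: np.ndarray  # (N, 2) dense closed polyline, mm
    centroid: np.ndarray  # (2,)
    L: float
    W: float
    W13: float
    W12: float
    W23: float
    A: float

    def radii(self, angles: np.ndarray) -> np.ndarray:
        """Ground-truth polar radii from the centroid at given angles (rad)."""
        d = self.boundary - self.centroid
        phi = np.arctan2(d[:, 1], d[:, 0])
        r = np.hypot(d[:, 0], d[:, 1])
        order = np.argsort(phi)
        return np.interp(np.asarray(angles), phi[order], r[order], period=2 * np.pi)


@dataclass
class RenderedLeaf:
    image: np.ndarray  # bool raster, True = leaf
    pixels_per_mm: float
    truth: LeafTruth


def _polar_boundary(params: LeafShapeParams, theta: np.ndarray) -> np.ndarray:
    a, b = params.a, params.b
    if params.family == "circle":
        rho = np.full_like(theta, a)
    elif params.family == "rectangle":
        with np.errstate(divide="ignore"):
            rho = np.minimum(
                np.abs(b / np.cos(theta)), np.abs(a / np.sin(theta))
            )
    else:
        rho = a * b / np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
        if params.family == "parametric-leaf":
            s = np.sin(theta)
            taper = np.where(s > 0, params.tip_taper, params.base_taper)
            rho = rho * (1.0 - taper * s * s * (1.0 - s * s))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])


def _polygon_centroid_area(pts: np.ndarray):
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy]), abs(area)


def _scanline_fill(pts: np.ndarray, height_px: int, width_px: int,
                   s: float) -> np.ndarray:
    """Rasterize the mm polygon: pixel centres inside the boundary are set.

    Even-odd scanline fill; pixel (row, col) centre sits at mm coordinates
    ((col+0.5)/s, (height-row-0.5)/s).
    """
    image = np.zeros((height_px, width_px), dtype=bool)
    y0, y1 = pts[:, 1], np.roll(pts[:, 1], -1)
    x0, x1 = pts[:, 0], np.roll(pts[:, 0], -1)
    keep = y0 != y1
    y0, y1, x0, x1 = y0[keep], y1[keep], x0[keep], x1[keep]
    slope = (x1 - x0) / (y1 - y0)
    for row in range(height_px):
        h = (height_px - row - 0.5) / s
        hit = (y0 - h) * (y1 - h) <= 0
        # count each crossing once: half-open edge intervals
        hit &= ~(y1 == h)
        if not hit.any():
            continue
        xs = np.sort(x0[hit] + (h - y0[hit]) * slope[hit])
        for a, b in zip(xs[0::2], xs[1::2]):
            c0 = int(np.ceil(a * s - 0.5))
            c1 = int(np.floor(b * s - 0.5))
            if c1 >= c0:
                image[row, max(c0, 0) : min(c1, width_px - 1) + 1] = True
    return image


def render_leaf(params: LeafShapeParams) -> RenderedLeaf:
    """Rasterize one leaf and return it with its exact ground truth.

    The raster is a single filled connected component; pixel (row, col)
    covers the mm square centred at ((col+0.5)/s, (H-row-0.5)/s).
    """
    theta = np.linspace(-np.pi, np.pi, _DENSE, endpoint=False)
    pts = _polar_boundary(params, theta)

    # classic traits in the upright leaf frame (rotation-invariant)
    centroid, area = _polygon_centroid_area(pts)
    ymin, ymax = pts[:, 1].min(), pts[:, 1].max()
    L = float(ymax - ymin)
    sub = pts[:: _RASTER_DECIMATE]
    w13, w12, w23 = chord_widths(sub, ymin + L * np.array([1 / 3, 1 / 2, 2 / 3]))
    grid = np.linspace(ymin + 1e-9 * L, ymax - 1e-9 * L, 2048)
    W = float(chord_widths(sub, grid).max())

    if params.rotation_deg:
        ang = np.deg2rad(params.rotation_deg)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        pts = pts @ R.T
        centroid = R @ centroid

    margin = 5.0  # mm of background around the silhouette
    shift = margin - pts.min(axis=0)
    pts = pts + shift
    centroid = centroid + shift

    s = params.pixels_per_mm
    width_px = int(np.ceil((pts[:, 0].max() + margin) * s))
    height_px = int(np.ceil((pts[:, 1].max() + margin) * s))
    image = _scanline_fill(pts[:: _RASTER_DECIMATE], height_px, width_px, s)

    truth = LeafTruth(
        boundary=pts, centroid=centroid, L=L, W=W,
        W13=float(w13), W12=float(w12), W23=float(w23), A=area,
    )
    return RenderedLeaf(image=image, pixels_per_mm=s, truth=truth)
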