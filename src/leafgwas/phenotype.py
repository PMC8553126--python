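"""Leaf-image morphometrics: contour, orientation, polar radii, size traits.

Measurement pipeline for scanned leaf silhouettes: extract the boundary of
the largest foreground component, normalize its orientation (principal axis
vertical, tip up, centroid at the origin), then derive

* 360 regular polar radii from the centroid across -pi..pi (the RD360
  multivariate shape phenotype) and reduced right-side sets RDk with k
  radii equally spaced on [-pi/2, pi/2] (k in {6, 9, 11, 16, 61});
* the classic size traits: length L, maximum width W, widths at 1/3, 1/2
  and 2/3 of the length from the base, area A and the L/W ratio.

All geometry is in mm (y up, angle 0 pointing to the leaf's right, tip at
+pi/2).  Pixel-to-mm conversion uses pixels_per_mm (300 dpi = 11.811).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label

REDUCED_KS = (6, 9, 11, 16, 61)
DPI_300 = 300.0 / 25.4  # 11.811 px/mm


class NoLeafError(ValueError):
    """Raised when an image contains no foreground component."""


@dataclass
class LeafContour:
    """Ordered closed leaf boundary in mm, counter-clockwise.

    ``points`` stores the ring without repeating the first vertex.
    """

    points: np.ndarray
    scale: float = DPI_300
    normalized: bool = False
    border_touch: bool = False
    axis_ambiguous: bool = False

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("contour needs >= 3 (x, y) points")
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        object.__setattr__(self, "points", pts)

    @property
    def closed_points(self) -> np.ndarray:
        return np.vstack([self.points, self.points[:1]])


def _shoelace(pts: np.ndarray):
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return x * yn - xn * y


def centroid(contour: LeafContour) -> np.ndarray:
    """Area-weighted polygon centroid (shoelace), not the vertex mean."""
    pts = contour.points
    cross = _shoelace(pts)
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        raise ValueError("zero-area polygon has no centroid")
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def polygon_area(contour: LeafContour) -> float:
    return float(abs(0.5 * _shoelace(contour.points).sum()))


def extract_contour(image: np.ndarray, scale: float = DPI_300) -> LeafContour:
    """Boundary of the largest foreground component, as mm polygon (y up).

    Grayscale inputs are binarized by Otsu's threshold; boolean/binary
    inputs pass through.  Raises :class:`NoLeafError` on empty foreground;
    flags components touching the image border.
    """
    img = np.asarray(image)
    if img.dtype == bool:
        binary = img
    else:
        vals = np.unique(img)
        if len(vals) <= 2:
            binary = img > (vals.max() / 2 if vals.max() > 0 else 0)
        else:
            binary = img > threshold_otsu(img)
    if not binary.any():
        raise NoLeafError("no leaf found")
    lab = label(binary)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    biggest = sizes.argmax()
    mask = lab == biggest
    border_touch = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    if border_touch:
        warnings.warn("leaf touches the image border", stacklevel=2)
    contours = find_contours(mask.astype(float), 0.5)
    # keep the outline enclosing the largest area (ignore interior holes)
    def enclosed(c):
        return abs(0.5 * _shoelace(c).sum())
    ring = max(contours, key=enclosed)
    h = mask.shape[0]
    xy = np.column_stack([(ring[:, 1] + 0.5) / scale, (h - ring[:, 0] - 0.5) / scale])
    if 0.5 * _shoelace(xy[:-1] if np.allclose(xy[0], xy[-1]) else xy).sum() < 0:
        xy = xy[::-1]
    return LeafContour(points=xy, scale=scale, border_touch=border_touch)


def _central_second_moments(pts: np.ndarray, c: np.ndarray):
    """Covariance matrix of the uniform lamina bounded by the polygon."""
    x, y = pts[:, 0] - c[0], pts[:, 1] - c[1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    ixx = (cross * (y * y + y * yn + yn * yn)).sum() / 12.0
    iyy = (cross * (x * x + x * xn + xn * xn)).sum() / 12.0
    ixy = (cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)).sum() / 24.0
    return np.array([[iyy, ixy], [ixy, ixx]]) / area


def normalize_orientation(contour: LeafContour) -> LeafContour:
    """Rotate the leaf so its principal axis is vertical with the tip at +y
    and translate the centroid to the origin.

    Near-circular outlines (principal-moment ratio < 1.05) have no defined
    axis: they are centred, flagged, and otherwise left untouched.
    """
    c = centroid(contour)
    pts = contour.points - c
    cov = _central_second_moments(contour.points, c)
    w, v = np.linalg.eigh(cov)
    ambiguous = w[1] / max(w[0], 1e-30) < 1.05
    if ambiguous:
        warnings.warn("principal axis ambiguous for near-circular contour", stacklevel=2)
        return replace(
            contour, points=pts, normalized=True, axis_ambiguous=True
        )
    major = v[:, 1]  # eigenvector of the larger moment
    ang = np.arctan2(major[1], major[0])
    rot = np.pi / 2 - ang
    R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    pts = pts @ R.T
    # tip = boundary point farthest from the centroid along the axis
    far = pts[np.abs(pts[:, 1]).argmax()]
    if far[1] < 0:
        pts = -pts
    return replace(contour, points=pts, normalized=True, axis_ambiguous=False)


@dataclass
class RadialProfile:
    """Regular polar radii from the leaf centroid.

    kind is RD360 for the full -pi..pi grid or RDk for right-side sets.
    """

    angles: np.ndarray
    radii: np.ndarray
    kind: str
    star_convex: bool = True
    contour: LeafContour | None = field(default=None, repr=False)


def _ray_radii(contour: LeafContour, angles: np.ndarray):
    """Radii along given directions; farthest intersection wins for
    non-star-convex outlines (flagged)."""
    pts = contour.points
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    un = np.unwrap(phi)
    # monotone winding about the origin <=> star-convex
    star = bool(np.all(np.diff(un) > 0) or np.all(np.diff(un) < 0))
    if star:
        # exact intersection of each ray with its single bracketing edge
        order = np.argsort(phi)
        phis, P = phi[order], pts[order]
        nv = len(P)
        ang = np.asarray(angles, dtype=float)
        i1 = np.searchsorted(phis, ang) % nv
        i0 = (i1 - 1) % nv
        p0, p1 = P[i0], P[i1]
        d = p1 - p0
        u = np.column_stack([np.cos(ang), np.sin(ang)])
        denom = u[:, 0] * d[:, 1] - u[:, 1] * d[:, 0]
        num = p0[:, 0] * d[:, 1] - p0[:, 1] * d[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = num / denom
        # ray parallel to the edge: fall back to the vertex radius
        scale = max(float(np.abs(num).max()), 1e-30)
        rr = np.where(np.abs(denom) > 1e-12 * scale, tt,
                      np.hypot(p0[:, 0], p0[:, 1]))
        return rr, True
    # general case: farthest ray-edge intersection
    p0 = pts
    p1 = np.roll(pts, -1, axis=0)
    d = p1 - p0
    out = np.empty(len(angles))
    for i, th in enumerate(np.asarray(angles, dtype=float)):
        u = np.array([np.cos(th), np.sin(th)])
        denom = d[:, 0] * (-u[1]) - d[:, 1] * (-u[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (p0[:, 0] * u[1] - p0[:, 1] * u[0]) / denom         # along edge
            tt = (d[:, 1] * p0[:, 0] - d[:, 0] * p0[:, 1]) / denom  # along ray
        hit = (s >= 0) & (s <= 1) & (tt > 0) & np.isfinite(tt)
        out[i] = tt[hit].max() if hit.any() else np.nan
    return out, False


def radial_profile(contour: LeafContour, n: int = 360) -> RadialProfile:
    """n regular polar radii at angles -pi + l*2pi/n, l = 0..n-1.

    The radius at each angle is interpolated linearly between the two
    boundary points bracketing the angle.  Requires a normalized contour
    (centroid at the origin).
    """
    if not contour.normalized:
        raise ValueError("contour must be orientation-normalized first")
    angles = -np.pi + 2 * np.pi * np.arange(n) / n
    radii, star = _ray_radii(contour, angles)
    if not star:
        warnings.warn("contour not star-convex about centroid; farthest intersection used",
                      stacklevel=2)
    kind = "RD360" if n == 360 else f"RD{n}"
    return RadialProfile(angles=angles, radii=radii, kind=kind,
                         star_convex=star, contour=contour)


def reduce_radii(profile: RadialProfile, k: int) -> RadialProfile:
    """Right-side radius set RDk: k radii equally spaced on [-pi/2, pi/2].

    Radii are re-interpolated from the source contour at exactly the grid
    angles (spacing 180/(k-1) degrees, endpoints inclusive).
    """
    if k not in REDUCED_KS:
        raise ValueError(f"unsupported k={k}; choose one of {REDUCED_KS}")
    if profile.contour is None:
        raise ValueError("profile lost its source contour; recompute radial_profile")
    angles = np.linspace(-np.pi / 2, np.pi / 2, k)
    radii, star = _ray_radii(profile.contour, angles)
    return RadialProfile(angles=angles, radii=radii, kind=f"RD{k:02d}",
                         star_convex=star, contour=profile.contour)


@dataclass
class LeafTraits:
    L: float
    W: float
    W13: float
    W12: float
    W23: float
    A: float
    LW: float


def chord_widths(pts: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Horizontal extent of the polygon cross-section at each height.

    Vectorized over levels; the width at a height is the x-range of the
    boundary crossings there (the bounding chord for lobed outlines).
    """
    y0, y1 = pts[:, 1], np.roll(pts[:, 1], -1)
    x0, x1 = pts[:, 0], np.roll(pts[:, 0], -1)
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    out = np.zeros(len(levels))
    # process in chunks to bound the (levels x edges) mask size
    chunk = max(1, int(4e6 // max(len(y0), 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(y1 != y0, x1 - x0, 0.0)
        denom = np.where(y1 != y0, y1 - y0, 1.0)
    for s in range(0, len(levels), chunk):
        h = levels[s : s + chunk, None]
        mask = ((y0[None, :] - h) * (y1[None, :] - h) < 0) | (y0[None, :] == h)
        xs = x0[None, :] + (h - y0[None, :]) / denom[None, :] * slope[None, :]
        lo = np.where(mask, xs, np.inf).min(axis=1)
        hi = np.where(mask, xs, -np.inf).max(axis=1)
        ok = mask.sum(axis=1) >= 2
        out[s : s + chunk] = np.where(ok, hi - lo, 0.0)
    return out


def classic_traits(contour: LeafContour, n_levels: int = 1024) -> LeafTraits:
    """L, W, fractional widths, area and L/W of a normalized contour."""
    if not contour.normalized:
        raise ValueError("contour must be orientation-normalized first")
    pts = contour.points
    ymin, ymax = pts[:, 1].min(), pts[:, 1].max()
    L = float(ymax - ymin)
    fracs = np.array([1 / 3, 1 / 2, 2 / 3])
    w13, w12, w23 = chord_widths(pts, ymin + L * fracs)
    grid = np.linspace(ymin + 1e-9 * L, ymax - 1e-9 * L, n_levels)
    W = float(max(chord_widths(pts, grid).max(), w13, w12, w23))
    A = polygon_area(contour)
    return LeafTraits(L=L, W=W, W13=float(w13), W12=float(w12), W23=float(w23),
                      A=A, LW=L / W)


def measure_image(image: np.ndarray, scale: float = DPI_300,
                  radius_kinds: tuple = ("RD360",)) -> dict:
    """Full single-leaf pipeline: contour -> normalize -> traits + radii."""
    contour = normalize_orientation(extract_contour(image, scale))
    out = {"contour": contour, "traits": classic_traits(contour)}
    rd360 = radial_profile(contour, 360)
    profiles = {}
    for kind in radius_kinds:
        if kind == "RD360":
            profiles[kind] = rd360
        else:
            profiles[kind] = reduce_radii(rd360, int(kind[2:]))
    out["profiles"] = profiles
    return out


def traits_table(results: dict[str, LeafTraits]) -> pd.DataFrame:
    """Per-leaf trait table (tree_id, L, W, W13, W12, W23, A, LW)."""
    rows = [
        {"tree_id": k, "L": t.L, "W": t.W, "W13": t.W13, "W12": t.W12,
         "W23": t.W23, "A": t.A, "LW": t.LW}
        for k, t in results.items()
    ]
    return pd.DataFrame(rows)
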