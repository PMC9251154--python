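"""Hough-transform detection of linear and circular mark points.

Lines use the normal parameterization ``rho = x cos(theta) + y
sin(theta)`` (x = col, y = row): every edge pixel maps to one sinusoid
in (theta, rho) space and concurrent sinusoids intersect at the line's
parameters.  Circles use the three-dimensional accumulator ``A(a, b,
r)``: an edge pixel on a circle of radius ``r`` votes for all centers
at distance ``r`` from it, so across radii each pixel sweeps out a cone
in parameter space whose apex-side intersections pile up at the true
(a, b, r).

Vote casting uses midpoint-circle rasterization of the center locus —
exact integer geometry, so a brute-force per-pixel loop reproduces the
accumulator bin-for-bin.  Accumulator bins are one pixel in a, b and
``r_step`` pixels in r; theta/rho bin sizes are configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._core import ImageSlice, ValidationError, as_array
from .preprocess import EdgeMap, detect_edges

__all__ = [
    "LineParams",
    "CircleParams",
    "LineAccumulator",
    "CircleAccumulator",
    "circle_perimeter_offsets",
    "hough_line_accumulate",
    "hough_line_peaks",
    "hough_circle_accumulate",
    "hough_circle_peaks",
    "refine_center",
    "find_circles",
]


@dataclass(frozen=True)
class LineParams:
    """A detected line in normal form, theta in [0, pi), rho in px."""

    theta: float
    rho: float
    votes: int = 0


@dataclass(frozen=True)
class CircleParams:
    """A detected circular mark point.

    ``(a, b)`` is the center as (row, col); ``refined_center`` holds
    the sub-pixel estimate once :func:`refine_center` has run.
    """

    a: float
    b: float
    r: float
    votes: int = 0
    refined_center: tuple[float, float] | None = None
    refinement_clipped: bool = False

    @property
    def center(self) -> tuple[float, float]:
        return self.refined_center if self.refined_center is not None else (self.a, self.b)


@dataclass
class LineAccumulator:
    votes: np.ndarray          # (n_theta, n_rho) int64
    thetas: np.ndarray         # bin centers, radians
    rhos: np.ndarray           # bin centers, px
    rho_resolution: float
    n_edge_pixels: int


@dataclass
class CircleAccumulator:
    votes: np.ndarray          # (H, W, n_r) int64, indexed by (a, b, r-bin)
    radii: np.ndarray          # integer radii, px
    perimeter_counts: np.ndarray  # bins cast per pixel at each radius
    n_edge_pixels: int


def _edge_points(edges) -> np.ndarray:
    if isinstance(edges, EdgeMap):
        return edges.points
    arr = np.asarray(edges)
    if arr.dtype == bool or arr.ndim == 2:
        return np.argwhere(arr.astype(bool))
    return arr  # already (N, 2) coordinates


def _edge_shape(edges) -> tuple[int, int]:
    if isinstance(edges, EdgeMap):
        return edges.binary.shape
    return np.asarray(edges).shape


def circle_perimeter_offsets(r: int) -> np.ndarray:
    """Integer (drow, dcol) offsets of the midpoint-circle of radius r.

    Classic 8-octant midpoint rasterization; offsets are unique and
    returned in lexicographic order so vote casting is reproducible.
    """
    r = int(r)
    if r < 0:
        raise ValidationError("radius must be >= 0")
    if r == 0:
        return np.zeros((1, 2), dtype=np.int64)
    pts = set()
    x, y, d = 0, r, 3 - 2 * r
    while x <= y:
        for dx, dy in ((x, y), (y, x)):
            pts.update({(dy, dx), (dy, -dx), (-dy, dx), (-dy, -dx)})
        if d < 0:
            d += 4 * x + 6
        else:
            d += 4 * (x - y) + 10
            y -= 1
        x += 1
    return np.array(sorted(pts), dtype=np.int64)


# --- lines ----------------------------------------------------------------

def hough_line_accumulate(edges, n_theta: int = 180,
                          rho_resolution: float = 1.0) -> LineAccumulator:
    """Fill the (theta, rho) accumulator from an edge map.

    Every edge pixel casts exactly one vote per theta bin, at
    ``rho = x cos(theta) + y sin(theta)`` binned to ``rho_resolution``.
    An empty edge map simply yields an all-zero accumulator.
    """
    if n_theta < 1:
        raise ValidationError("n_theta must be >= 1")
    if rho_resolution <= 0:
        raise ValidationError("rho_resolution must be > 0")
    h, w = _edge_shape(edges)
    pts = _edge_points(edges)
    thetas = np.arange(n_theta) * math.pi / n_theta
    rho_max = math.hypot(h - 1, w - 1)
    offset = int(math.ceil(rho_max / rho_resolution))
    rhos = (np.arange(2 * offset + 1) - offset) * rho_resolution
    votes = np.zeros((n_theta, 2 * offset + 1), dtype=np.int64)
    if len(pts):
        y = pts[:, 0].astype(float)
        x = pts[:, 1].astype(float)
        # (N, n_theta) signed distances; floor(v + 0.5) is the bin rule
        rho = np.outer(x, np.cos(thetas)) + np.outer(y, np.sin(thetas))
        idx = np.floor(rho / rho_resolution + 0.5).astype(np.int64) + offset
        ti = np.broadcast_to(np.arange(n_theta), idx.shape)
        np.add.at(votes, (ti.ravel(), idx.ravel()), 1)
    return LineAccumulator(votes=votes, thetas=thetas, rhos=rhos,
                           rho_resolution=rho_resolution, n_edge_pixels=len(pts))


def hough_line_peaks(acc: LineAccumulator, k: int = 4, min_votes: int = 1,
                     nms_radius: int = 2) -> list[LineParams]:
    """Top-k accumulator peaks with greedy non-maximum suppression.

    Candidates are ordered by votes descending, ties broken by
    ascending (theta, rho) bin index; a candidate within Chebyshev
    distance ``nms_radius`` (in bins) of an accepted peak is dropped.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    ti, ri = np.nonzero(acc.votes >= max(min_votes, 1))
    if len(ti) == 0:
        return []
    v = acc.votes[ti, ri]
    order = np.lexsort((ri, ti, -v))
    kept: list[tuple[int, int]] = []
    out: list[LineParams] = []
    for j in order:
        t, r = int(ti[j]), int(ri[j])
        if any(abs(t - t0) <= nms_radius and abs(r - r0) <= nms_radius
               for t0, r0 in kept):
            continue
        kept.append((t, r))
        out.append(LineParams(theta=float(acc.thetas[t]), rho=float(acc.rhos[r]),
                              votes=int(acc.votes[t, r])))
        if len(out) == k:
            break
    return out


# --- circles --------------------------------------------------------------

def hough_circle_accumulate(edges, r_min: int, r_max: int,
                            r_step: int = 1) -> CircleAccumulator:
    """Fill the 3-D accumulator A(a, b, r) from an edge map.

    For each edge pixel and each candidate radius the midpoint circle
    of centers at that distance receives one vote per bin; votes whose
    center falls outside the image are discarded.
    """
    if not (0 < r_min <= r_max):
        raise ValidationError("need 0 < r_min <= r_max")
    if r_step < 1:
        raise ValidationError("r_step must be >= 1")
    h, w = _edge_shape(edges)
    radii = np.arange(int(r_min), int(r_max) + 1, int(r_step), dtype=np.int64)
    if radii[0] > max(h, w):
        warnings.warn("radius range excludes all image-feasible circles",
                      stacklevel=2)
    pts = _edge_points(edges)
    votes = np.zeros((h, w, len(radii)), dtype=np.int64)
    perim = np.zeros(len(radii), dtype=np.int64)
    for ri, r in enumerate(radii):
        offs = circle_perimeter_offsets(int(r))
        perim[ri] = len(offs)
        if len(pts) == 0:
            continue
        centers = pts[:, None, :] + offs[None, :, :]   # (N, K, 2)
        a = centers[..., 0].ravel()
        b = centers[..., 1].ravel()
        ok = (a >= 0) & (a < h) & (b >= 0) & (b < w)
        np.add.at(votes[..., ri], (a[ok], b[ok]), 1)
    return CircleAccumulator(votes=votes, radii=radii, perimeter_counts=perim,
                             n_edge_pixels=len(pts))


def hough_circle_peaks(acc: CircleAccumulator, k: int = 4, min_votes: int = 1,
                       nms_radius: int = 2) -> list[CircleParams]:
    """Top-k circle candidates, ranked by perimeter-normalized votes.

    Raw votes grow with circle circumference, so ranking divides by
    the ideal per-radius perimeter bin count; without this large
    circles would always win.  Non-maximum suppression is applied in
    all three accumulator axes with Chebyshev radius ``nms_radius``
    bins, and exact ties are broken lexicographically by (a, b, r).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    a, b, ri = np.nonzero(acc.votes >= max(min_votes, 1))
    if len(a) == 0:
        return []
    raw = acc.votes[a, b, ri]
    norm = raw / acc.perimeter_counts[ri]
    order = np.lexsort((ri, b, a, -norm))
    kept: list[tuple[int, int, int]] = []
    out: list[CircleParams] = []
    for j in order:
        aa, bb, rr = int(a[j]), int(b[j]), int(ri[j])
        if any(abs(aa - a0) <= nms_radius and abs(bb - b0) <= nms_radius
               and abs(rr - r0) <= nms_radius for a0, b0, r0 in kept):
            continue
        kept.append((aa, bb, rr))
        out.append(CircleParams(a=float(aa), b=float(bb),
                                r=float(acc.radii[rr]),
                                votes=int(acc.votes[aa, bb, rr])))
        if len(out) == k:
            break
    return out


def refine_center(image, circle: CircleParams, window: float = 3.0) -> CircleParams:
    """Sub-pixel center refinement by intensity-weighted centroid.

    Pixels within ``window`` px of the circle's radius are weighted by
    their background-subtracted intensity and averaged.  The refined
    center never moves more than 1.5 px from the coarse one; a larger
    shift indicates a bad coarse detection and the coarse center is
    kept.  A refinement window clipped by the image border is flagged.
    """
    arr = as_array(image)
    h, w = arr.shape
    if not (0 <= circle.a < h and 0 <= circle.b < w):
        raise ValidationError("circle center outside image bounds")
    half = int(math.ceil(circle.r + window))
    r0, r1 = int(circle.a) - half, int(circle.a) + half + 1
    c0, c1 = int(circle.b) - half, int(circle.b) + half + 1
    clipped = r0 < 0 or c0 < 0 or r1 > h or c1 > w
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, h), min(c1, w)
    region = arr[r0:r1, c0:c1]
    rows, cols = np.mgrid[r0:r1, c0:c1].astype(float)
    # background from a low percentile: robust even when a filled marker
    # covers most of the window (the median would then sit on the marker)
    background = np.percentile(region, 10.0)
    bright = np.clip(region - background, 0.0, None)
    ca, cb, rr = float(circle.a), float(circle.b), float(circle.r)
    # iterate centroid + radius so the band re-centers on the marker:
    # the coarse radius may sit on one edge of a thick ring
    for _ in range(3):
        d = np.hypot(rows - ca, cols - cb)
        weights = bright * (np.abs(d - rr) <= window)
        total = weights.sum()
        if total <= 0:
            ca, cb = circle.a, circle.b
            break
        ca = float((weights * rows).sum() / total)
        cb = float((weights * cols).sum() / total)
        rr = float((weights * d).sum() / total)
    if math.hypot(ca - circle.a, cb - circle.b) > 1.5:
        ca, cb = circle.a, circle.b
    return CircleParams(circle.a, circle.b, circle.r, circle.votes,
                        refined_center=(ca, cb), refinement_clipped=clipped)


def find_circles(image, r_min: int, r_max: int, k: int = 4, *,
                 r_step: int = 1, min_votes: int = 1, nms_radius: int = 2,
                 canny_low: float = 5.0, canny_high: float = 15.0,
                 canny_sigma: float = 1.5, refine: bool = True,
                 refine_window: float = 3.0) -> list[CircleParams]:
    """Edge detection -> circle accumulation -> peaks -> refinement."""
    edges = detect_edges(image, low=canny_low, high=canny_high, sigma=canny_sigma)
    acc = hough_circle_accumulate(edges, r_min, r_max, r_step)
    peaks = hough_circle_peaks(acc, k=k, min_votes=min_votes, nms_radius=nms_radius)
    if refine:
        peaks = [refine_center(image, c, window=refine_window) for c in peaks]
    return peaks
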