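"""Matching detected mark points against a frame template.

The matching flow mirrors how a stereotactic frame is read off a scan:
first the reference anchor pair (the "AB" axis of the frame) is
located among the detections, collinear runs of markers (frame rods)
are grouped, and the remaining labels are assigned in a fixed order by
aligning the template onto the detections with a provisional
similarity transform.  Full rigid refinement in millimetres is the
register module's job.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import linear_sum_assignment

from ._core import ValidationError

__all__ = ["FrameTemplate", "FiducialSet", "MatchingError",
           "group_collinear", "match_marks"]


class MatchingError(RuntimeError):
    """No consistent anchor assignment between detections and template."""


@dataclass(frozen=True)
class FrameTemplate:
    """Labeled fiducial layout of a stereotactic frame, in mm.

    ``points`` maps label -> (x, y) or (x, y, z) template coordinates.
    ``anchors`` names the two labels spanning the reference A->B axis;
    by convention they are the uniquely most-separated pair of the
    template.  ``collinear_groups`` lists label runs expected to lie on
    a common rod.
    """

    points: dict[str, tuple[float, ...]]
    anchors: tuple[str, str]
    collinear_groups: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "points",
                           {str(k): tuple(float(x) for x in v)
                            for k, v in self.points.items()})
        object.__setattr__(self, "anchors", tuple(self.anchors))
        if len(self.anchors) != 2 or len(set(self.anchors)) != 2:
            raise ValidationError("anchor pair must be two distinct labels")
        for lab in self.anchors:
            if lab not in self.points:
                raise ValidationError(f"anchor label {lab!r} not in template")
        if len(self.points) < 3:
            raise ValidationError("a template needs at least 3 labeled points")

    @property
    def labels(self) -> list[str]:
        return list(self.points)

    def xy(self) -> np.ndarray:
        """In-plane (x, y) coordinates in template label order."""
        return np.array([self.points[l][:2] for l in self.points], dtype=float)

    @classmethod
    def from_yaml(cls, path) -> "FrameTemplate":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(points={k: tuple(v) for k, v in doc["points"].items()},
                   anchors=tuple(doc["anchors"]),
                   collinear_groups=tuple(tuple(g) for g in doc.get("collinear_groups", [])))

    def to_yaml(self, path) -> None:
        doc = {"points": {k: list(v) for k, v in self.points.items()},
               "anchors": list(self.anchors),
               "collinear_groups": [list(g) for g in self.collinear_groups]}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class FiducialSet:
    """Labeled correspondences between detections and template points."""

    matches: list[tuple[str, tuple[float, ...], tuple[float, ...]]]
    unmatched_detections: list[tuple[float, ...]] = field(default_factory=list)
    unmatched_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        labels = [m[0] for m in self.matches]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate label among matches")

    @property
    def labels(self) -> list[str]:
        return [m[0] for m in self.matches]

    def image_points(self) -> np.ndarray:
        return np.array([m[1] for m in self.matches], dtype=float)

    def template_points(self) -> np.ndarray:
        return np.array([m[2] for m in self.matches], dtype=float)


def _fit_line_tls(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line: returns (centroid, unit direction)."""
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    return c, vt[0]


def _line_residuals(pts: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    rel = pts - c
    return np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])


def group_collinear(points, tol_px: float = 0.5) -> list[list[int]]:
    """Find maximal groups of >= 3 points lying on a common line.

    For every point pair the through-line is hypothesised, inliers
    within ``tol_px`` perpendicular distance are collected, and the
    line is refit by total least squares with inliers re-selected.
    Groups that are subsets of larger groups are dropped; a point may
    belong to several groups (crossing rods).  Returned as lists of
    input indices, largest group first, ties by smallest first index.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    if np.allclose(pts, pts[0]):
        raise ValidationError("all points identical; collinearity undefined")

    n = len(pts)
    found: set[frozenset[int]] = set()
    for i, j in itertools.combinations(range(n), 2):
        d = pts[j] - pts[i]
        norm = np.hypot(*d)
        if norm == 0:
            continue
        d = d / norm
        inliers = np.nonzero(_line_residuals(pts, pts[i], d) <= tol_px)[0]
        if len(inliers) < 3:
            continue
        # refit on the inlier set and re-select, once
        c, d = _fit_line_tls(pts[inliers])
        inliers = np.nonzero(_line_residuals(pts, c, d) <= tol_px)[0]
        if len(inliers) >= 3:
            found.add(frozenset(int(x) for x in inliers))
    maximal = [g for g in found if not any(g < h for h in found if h is not g)]
    groups = [sorted(g) for g in maximal]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def _similarity_from_pair(p1, p2, q1, q2) -> tuple[complex, complex]:
    """Similarity z -> alpha*z + beta mapping p1->q1, p2->q2 (complex plane)."""
    zp1, zp2 = complex(p1[0], p1[1]), complex(p2[0], p2[1])
    zq1, zq2 = complex(q1[0], q1[1]), complex(q2[0], q2[1])
    alpha = (zq2 - zq1) / (zp2 - zp1)
    return alpha, zq1 - alpha * zp1


def match_marks(detections, template: FrameTemplate, tol: float = 3.0) -> FiducialSet:
    """Label detected mark points against the frame template.

    The template anchor pair A, B is tried against every ordered pair
    of detections; each hypothesis induces a similarity transform
    (rotation + isotropic scale + translation, no reflection) from
    template to image, under which the remaining labels are assigned
    one-to-one by minimum total distance.  The hypothesis keeping the
    most labels within ``tol`` (ties: smallest total residual, then
    lexicographic detection pair) wins.  Detections and labels left
    over are reported unmatched.

    Notes
    -----
    Detections may be (row, col) px or planar mm — matching is
    dimension-agnostic as long as template and detections are related
    by a similarity.  Only the in-plane (x, y) template coordinates
    participate.
    """
    det = np.asarray([getattr(p, "center", p) for p in detections], dtype=float)
    if det.ndim != 2 or det.shape[0] < 3:
        raise ValidationError("need at least 3 detections to match a frame")
    det = det[:, :2]
    labels = template.labels
    tpl = template.xy()
    ia, ib = labels.index(template.anchors[0]), labels.index(template.anchors[1])
    others = [i for i in range(len(labels)) if i not in (ia, ib)]

    best = None  # (n_matched, total_resid, pair, assignment)
    for i, j in itertools.permutations(range(len(det)), 2):
        if np.allclose(det[i], det[j]):
            continue
        alpha, beta = _similarity_from_pair(tpl[ia], tpl[ib], det[i], det[j])
        z = tpl[:, 0] + 1j * tpl[:, 1]
        proj = alpha * z + beta
        proj_xy = np.column_stack([proj.real, proj.imag])
        free_det = [m for m in range(len(det)) if m not in (i, j)]
        assignment = {ia: i, ib: j}
        resid = {ia: 0.0, ib: 0.0}
        if others and free_det:
            cost = np.linalg.norm(
                proj_xy[others][:, None, :] - det[free_det][None, :, :], axis=2)
            rr, cc = linear_sum_assignment(cost)
            for r_, c_ in zip(rr, cc):
                assignment[others[r_]] = free_det[c_]
                resid[others[r_]] = float(cost[r_, c_])
        kept = {l: m for l, m in assignment.items() if resid[l] <= tol}
        score = (-len(kept), sum(resid[l] for l in kept), i, j)
        if best is None or score < best[0]:
            best = (score, kept, dict(resid))

    if best is None or len(best[1]) < 3:
        best_resid = min(best[2].values()) if best else float("inf")
        raise MatchingError(
            f"no consistent anchor assignment (best residual {best_resid:.3g})")

    _, kept, _ = best
    # label order: anchors first, then remaining labels by template index
    ordered = [l for l in (ia, ib) if l in kept] + \
              [l for l in sorted(kept) if l not in (ia, ib)]
    matches = [(labels[l], tuple(det[kept[l]]), template.points[labels[l]])
               for l in ordered]
    matched_det = set(kept.values())
    unmatched_det = [tuple(det[m]) for m in range(len(det)) if m not in matched_det]
    unmatched_lab = [labels[l] for l in range(len(labels)) if l not in kept]
    return FiducialSet(matches=matches, unmatched_detections=unmatched_det,
                       unmatched_labels=unmatched_lab)
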