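"""Rigid image-to-frame registration, AC-PC targeting, and error metrics.

Once mark points are labeled, a rigid (rotation + translation)
transform from image millimetre space to frame millimetre space is fit
by orthogonal Procrustes.  Rigidity is deliberate: a stereotactic
frame does not scale or shear, and excluding those modes keeps the
residuals interpretable as millimetres of localization error.

Targeting works in the AC-PC coordinate system: origin at the midpoint
of the anterior and posterior commissures, Y along PC->AC, Z in the
midsagittal plane orthogonal to Y, X lateral completing a right-handed
frame (positive toward the patient's right).  The standard subthalamic
target window relative to that origin is X = +/-10 to +/-13 mm,
Y = -1 to -2 mm, Z = -2 to -6 mm; bounds are treated as inclusive.

Error vocabulary (standard in image-guided surgery):

* FLE — fiducial localization error, per-mark distance between the
  detected and true marker position;
* FRE — fiducial registration error, RMS residual of the fitted
  transform over the fiducials;
* TRE — target registration error, distance between the transformed
  target and its true frame-space position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core import ValidationError
from .match import FiducialSet
from .phantom import PhantomTruth

__all__ = [
    "FrameTransform",
    "ACPCSpec",
    "TargetCoordinate",
    "ErrorReport",
    "fit_rigid_transform",
    "apply_transform",
    "build_acpc",
    "target_coordinates",
    "evaluate_errors",
]

#: Inclusive target-window bounds in AC-PC mm: (|X|, Y, Z).
PROTOCOL_X = (10.0, 13.0)
PROTOCOL_Y = (-2.0, -1.0)
PROTOCOL_Z = (-6.0, -2.0)


@dataclass
class FrameTransform:
    """Rigid map q = R p + t with its per-fiducial fit residuals (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    rms: float = 0.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        d = self.translation.shape[0]
        if self.rotation.shape != (d, d):
            raise ValidationError("rotation/translation dimensionality mismatch")

    @property
    def dim(self) -> int:
        return self.translation.shape[0]

    def apply(self, points) -> np.ndarray:
        return apply_transform(self, points)

    def inverse(self) -> "FrameTransform":
        rt = self.rotation.T
        return FrameTransform(rotation=rt, translation=-rt @ self.translation)


@dataclass
class ACPCSpec:
    """AC-PC coordinate system: midpoint origin, orthonormal axes.

    ``axes`` rows are the X, Y, Z unit vectors expressed in the input
    (scanner/frame) coordinates; a point p maps to AC-PC coordinates
    as ``axes @ (p - origin)``.
    """

    ac: np.ndarray
    pc: np.ndarray
    origin: np.ndarray
    axes: np.ndarray

    def to_acpc(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = (p - self.origin) @ self.axes.T
        return out[0] if np.asarray(points).ndim == 1 else out

    def from_acpc(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.axes + self.origin
        return out[0] if np.asarray(points).ndim == 1 else out


@dataclass(frozen=True)
class TargetCoordinate:
    """A surgical target in AC-PC mm, with protocol-window flag."""

    x: float
    y: float
    z: float
    side: str
    within_protocol: bool


@dataclass
class ErrorReport:
    """Positioning-error summary for one registered phantom/scan."""

    fle_mm: dict[str, float]
    fre_mm: float
    tre_mm: list[float]

    @property
    def summary(self) -> dict[str, float]:
        v = np.array(list(self.fle_mm.values()) or [0.0])
        return {"fle_mean": float(v.mean()),
                "fle_sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "fle_max": float(v.max()),
                "fre": self.fre_mm,
                "tre_mean": float(np.mean(self.tre_mm)) if self.tre_mm else 0.0}


def _point_arrays(fiducials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fiducials, FiducialSet):
        return fiducials.image_points(), fiducials.template_points()
    src, dst = fiducials
    return np.asarray(src, dtype=float), np.asarray(dst, dtype=float)


def fit_rigid_transform(fiducials) -> FrameTransform:
    """Least-squares rigid transform via SVD orthogonal Procrustes.

    Accepts a :class:`~stereoloc.match.FiducialSet` (image points ->
    template points, both in mm) or a ``(src, dst)`` pair of (N, d)
    arrays.  Minimizes sum ||R p_i + t - q_i||^2 subject to R
    orthonormal with det +1 (no reflection, no scale).
    """
    src, dst = _point_arrays(fiducials)
    if src.shape != dst.shape or src.ndim != 2:
        raise ValidationError("source/destination point sets must match in shape")
    n, d = src.shape
    if n < 3:
        raise ValidationError("need at least 3 point correspondences")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    # rank < d-1 means the points do not pin down the rotation
    if np.linalg.matrix_rank(src - sc, tol=1e-9 * max(1.0, np.abs(src).max())) < d - 1 + (d == 2):
        raise ValidationError(
            f"degenerate fiducial configuration: rank-deficient in {d}-D "
            "(collinear or coincident points)")
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.ones(d)
    diag[-1] = sign if sign != 0 else 1.0
    rot = vt.T @ np.diag(diag) @ u.T
    t = dc - rot @ sc
    resid = np.linalg.norm((src @ rot.T + t) - dst, axis=1)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return FrameTransform(rotation=rot, translation=t, residuals=resid, rms=rms)


def apply_transform(transform: FrameTransform, points) -> np.ndarray:
    """Apply q = R p + t to one point or an (N, d) array of points."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != transform.dim:
        raise ValidationError(
            f"points are {p.shape[1]}-D but transform is {transform.dim}-D")
    out = p @ transform.rotation.T + transform.translation
    return out[0] if single else out


def build_acpc(ac, pc, midsagittal_point) -> ACPCSpec:
    """Construct the AC-PC coordinate system from three mm points.

    Origin is the AC-PC midpoint; Y runs PC->AC; Z is the component of
    (midsagittal - origin) orthogonal to Y, normalized; X = Y x Z
    completes a right-handed frame.  The midsagittal point must be off
    the AC-PC line.
    """
    ac = np.asarray(ac, dtype=float)
    pc = np.asarray(pc, dtype=float)
    ms = np.asarray(midsagittal_point, dtype=float)
    if ac.shape != (3,) or pc.shape != (3,) or ms.shape != (3,):
        raise ValidationError("ac, pc and midsagittal point must be 3-D")
    axis = ac - pc
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValidationError("AC and PC coincide")
    yhat = axis / norm
    origin = (ac + pc) / 2.0
    up = ms - origin
    up = up - (up @ yhat) * yhat
    upn = np.linalg.norm(up)
    if upn < 1e-9 * max(1.0, norm):
        raise ValidationError("midsagittal point is collinear with AC-PC")
    zhat = up / upn
    xhat = np.cross(yhat, zhat)
    return ACPCSpec(ac=ac, pc=pc, origin=origin,
                    axes=np.vstack([xhat, yhat, zhat]))


def target_coordinates(acpc: ACPCSpec, side: str, x_mm: float, y_mm: float,
                       z_mm: float) -> TargetCoordinate:
    """Place a target at (x, y, z) mm in AC-PC space on the given side.

    ``x_mm`` is the lateral magnitude; the sign is set by ``side``
    (right positive, left negative).  ``within_protocol`` checks the
    inclusive window |X| in [10, 13], Y in [-2, -1], Z in [-6, -2] mm.
    """
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    if not np.all(np.isfinite([x_mm, y_mm, z_mm])):
        raise ValidationError("target offsets must be finite")
    x = abs(x_mm) if side == "right" else -abs(x_mm)
    ok = (PROTOCOL_X[0] <= abs(x) <= PROTOCOL_X[1]
          and PROTOCOL_Y[0] <= y_mm <= PROTOCOL_Y[1]
          and PROTOCOL_Z[0] <= z_mm <= PROTOCOL_Z[1])
    return TargetCoordinate(x=float(x), y=float(y_mm), z=float(z_mm),
                            side=side, within_protocol=bool(ok))


def evaluate_errors(truth: PhantomTruth, fiducials: FiducialSet,
                    transform: FrameTransform, targets=(),
                    spacing_mm: tuple[float, float] = (1.0, 1.0)) -> ErrorReport:
    """Positioning-error report against phantom ground truth.

    FLE per mark is the distance between the detected image point and
    the true circle center scaled to mm; FRE is the RMS residual of
    the transform; TRE is evaluated for each requested target, given
    as ``(image_point_mm, true_frame_point_mm)`` pairs.

    Matched labels are associated with truth circles by nearest true
    center; a matched label with no truth circle within 5 px raises.
    """
    true_centers = np.asarray([(a, b) for a, b, _ in truth.true_circles], dtype=float)
    if len(true_centers) == 0:
        raise ValidationError("truth contains no circles")
    sp = np.asarray(spacing_mm, dtype=float)
    fle: dict[str, float] = {}
    for label, img_pt, _ in fiducials.matches:
        p = np.asarray(img_pt[:2], dtype=float)
        d_px = np.linalg.norm(true_centers - p, axis=1)
        i = int(np.argmin(d_px))
        if d_px[i] > 5.0:
            raise ValidationError(
                f"matched label {label!r} has no truth mark within 5 px")
        fle[label] = float(np.linalg.norm((true_centers[i] - p) * sp))
    tre = [float(np.linalg.norm(apply_transform(transform, np.asarray(img, float))
                                - np.asarray(frm, float)))
           for img, frm in targets]
    return ErrorReport(fle_mm=fle, fre_mm=transform.rms, tre_mm=tre)
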