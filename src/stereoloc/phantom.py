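"""Synthetic phantoms with known fiducial geometry, and synthetic cohorts.

The generators here stand in for stereotactic positioning scans: bright
ring (or disc) fiducials and straight rods rendered over a smooth
background, plus MR-magnitude-style noise.  Every rendered feature is
reported back in a :class:`PhantomTruth`, so detection, matching and
registration can be scored against exact ground truth without any
external data.  A cohort generator produces pre/post UPDRS score pairs
with exact per-category efficacy counts for the outcome statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._core import ImageSlice, ImageVolume, ValidationError

__all__ = [
    "CircleFeature",
    "LineFeature",
    "PhantomSpec",
    "PhantomTruth",
    "OutcomeRecord",
    "make_phantom_slice",
    "make_phantom_volume",
    "make_outcome_cohort",
]


@dataclass(frozen=True)
class CircleFeature:
    """A circular fiducial: center (a=row, b=col), radius r, all in px.

    Rendered as a bright annulus of the given thickness unless
    ``filled`` is set, in which case a solid disc is drawn.  Ring
    markers are the default because circle detection votes on edges.
    """

    a: float
    b: float
    r: float
    amplitude: float = 120.0
    thickness: float = 2.0
    filled: bool = False


@dataclass(frozen=True)
class LineFeature:
    """A straight rod in normal form: rho = x*cos(theta) + y*sin(theta).

    ``theta`` in radians within [0, pi); ``rho`` in px (x = col,
    y = row, both 0-based pixel centers).
    """

    theta: float
    rho: float
    amplitude: float = 100.0
    thickness: float = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic positioning slice/volume."""

    width: int = 128
    height: int = 128
    depth: int | None = None
    spacing_mm: tuple[float, ...] = (1.0, 1.0)
    circles: tuple[CircleFeature, ...] = ()
    lines: tuple[LineFeature, ...] = ()
    background: float = 20.0
    gradient_amplitude: float = 0.0
    noise_model: str = "gaussian"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "circles", tuple(
            c if isinstance(c, CircleFeature) else CircleFeature(*c)
            for c in self.circles))
        object.__setattr__(self, "lines", tuple(
            l if isinstance(l, LineFeature) else LineFeature(*l)
            for l in self.lines))

    def validate(self) -> None:
        if self.width < 4 or self.height < 4:
            raise ValidationError("image must be at least 4x4 px")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        for c in self.circles:
            if c.r < 2:
                raise ValidationError(f"circle radius {c.r} < 2 px")
            if not (0 <= c.a <= self.height - 1 and 0 <= c.b <= self.width - 1):
                raise ValidationError(
                    f"circle center ({c.a}, {c.b}) outside image bounds "
                    f"{self.height}x{self.width}")
        for l in self.lines:
            if not (0 <= l.theta < math.pi):
                raise ValidationError("line theta must lie in [0, pi)")


@dataclass
class PhantomTruth:
    """Ground truth for every rendered feature, in generation order."""

    true_circles: list[tuple[float, float, float]] = field(default_factory=list)
    true_lines: list[tuple[float, float]] = field(default_factory=list)
    true_ac: tuple[float, float, float] | None = None
    true_pc: tuple[float, float, float] | None = None
    frame_points: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def acpc_midpoint(self) -> tuple[float, float, float] | None:
        if self.true_ac is None or self.true_pc is None:
            return None
        return tuple((np.asarray(self.true_ac) + np.asarray(self.true_pc)) / 2.0)


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-patient pre/post UPDRS scores in a two-group trial."""

    patient_id: str
    group: str  # "observation" | "control"
    updrs_pre: float
    updrs_post: float

    def __post_init__(self):
        if self.updrs_pre <= 0:
            raise ValidationError("updrs_pre must be > 0 (improvement rate undefined)")
        if self.updrs_post < 0:
            raise ValidationError("updrs_post must be >= 0")


def _render_noiseless(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), float(spec.background))
    if spec.gradient_amplitude:
        # smooth tilted plane across the field of view
        img += spec.gradient_amplitude * (rows / max(h - 1, 1) + cols / max(w - 1, 1)) / 2.0
    for c in spec.circles:
        d = np.hypot(rows - c.a, cols - c.b)
        if c.filled:
            cov = np.clip(c.r - d + 0.5, 0.0, 1.0)
        else:
            cov = np.clip(c.thickness / 2.0 - np.abs(d - c.r) + 0.5, 0.0, 1.0)
        img += c.amplitude * cov
    for l in spec.lines:
        s = np.abs(cols * math.cos(l.theta) + rows * math.sin(l.theta) - l.rho)
        cov = np.clip(l.thickness / 2.0 - s + 0.5, 0.0, 1.0)
        img += l.amplitude * cov
    return img


def _add_noise(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sigma == 0:
        return img
    if spec.noise_model == "gaussian":
        return img + rng.normal(0.0, spec.noise_sigma, img.shape)
    # Rician: magnitude of a complex signal with iid Gaussian channels
    n1 = rng.normal(0.0, spec.noise_sigma, img.shape)
    n2 = rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.sqrt((img + n1) ** 2 + n2 ** 2)


def make_phantom_slice(spec: PhantomSpec) -> tuple[ImageSlice, PhantomTruth]:
    """Render one synthetic slice and its ground truth.

    The noiseless render is deterministic in the spec; noise is drawn
    from ``default_rng(spec.seed)`` so equal (spec, seed) gives
    bit-identical output.
    """
    spec.validate()
    img = _render_noiseless(spec)
    rng = np.random.default_rng(spec.seed)
    img = _add_noise(img, spec, rng)
    spacing = tuple(spec.spacing_mm[:2]) if len(spec.spacing_mm) >= 2 else (1.0, 1.0)
    truth = PhantomTruth(
        true_circles=[(c.a, c.b, c.r) for c in spec.circles],
        true_lines=[(l.theta, l.rho) for l in spec.lines],
    )
    return ImageSlice(img, spacing_mm=spacing), truth


def make_phantom_volume(
    spec: PhantomSpec,
    n_slices: int,
    ac_pc_geometry: dict | None = None,
) -> tuple[ImageVolume, PhantomTruth]:
    """Stack ``n_slices`` copies of the slice phantom into a volume.

    Fiducials are replicated at the same in-plane template position on
    every slice, mimicking frame rods running perpendicular to the
    scan plane.  ``ac_pc_geometry`` may carry ``{"ac": (x,y,z),
    "pc": (x,y,z)}`` in mm; these are recorded in the truth for
    downstream AC-PC construction tests.
    """
    spec.validate()
    if n_slices < 3:
        raise ValidationError("a volume needs at least 3 slices")
    if len(spec.spacing_mm) == 3:
        spacing = tuple(float(s) for s in spec.spacing_mm)
    elif len(spec.spacing_mm) == 2:
        spacing = (1.0,) + tuple(float(s) for s in spec.spacing_mm)
    else:
        raise ValidationError("spacing_mm must have 2 or 3 entries")
    if any(s <= 0 for s in spacing):
        raise ValidationError("spacings must be positive")

    base = _render_noiseless(spec)
    rng = np.random.default_rng(spec.seed)
    vol = np.stack([_add_noise(base.copy(), spec, rng) for _ in range(n_slices)])

    z_mid = spacing[0] * (n_slices - 1) / 2.0
    truth = PhantomTruth(
        true_circles=[(c.a, c.b, c.r) for c in spec.circles],
        true_lines=[(l.theta, l.rho) for l in spec.lines],
        frame_points=[(c.b * spacing[2], c.a * spacing[1], z_mid) for c in spec.circles],
    )
    if ac_pc_geometry is not None:
        truth.true_ac = tuple(float(v) for v in ac_pc_geometry["ac"])
        truth.true_pc = tuple(float(v) for v in ac_pc_geometry["pc"])
    return ImageVolume(vol, spacing_mm=spacing), truth


# --- synthetic outcome cohorts -------------------------------------------

#: (low, high) improvement-rate bands per efficacy category, percent.
#: Mirrors the outcome module's default classification thresholds
#: (markedly effective >= 50%, improved >= 20%).
DEFAULT_CATEGORY_BANDS = {
    "markedly_effective": (55.0, 90.0),
    "improved": (25.0, 45.0),
    "ineffective": (-15.0, 15.0),
}

CATEGORIES = ("markedly_effective", "ineffective", "improved")


def make_outcome_cohort(
    n_obs: int,
    n_ctl: int,
    category_counts: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    bands: dict[str, tuple[float, float]] | None = None,
) -> list[OutcomeRecord]:
    """Generate a two-group cohort with exact per-category efficacy counts.

    Parameters
    ----------
    n_obs, n_ctl : int
        Group sizes (observation / control).
    category_counts : dict
        ``{category: (observation_count, control_count)}``.  Counts per
        group must sum to the group size.  Defaults to the 40-patient
        two-arm trial composition 37/1/2 vs 35/2/3 (markedly effective /
        ineffective / improved).
    seed : int
        RNG seed; identical arguments give an identical cohort.
    bands : dict
        Improvement-rate band (lo, hi) sampled per category, percent.

    Each patient gets an integer preoperative UPDRS in [30, 80] and a
    postoperative score chosen so the improvement rate
    100*(pre - post)/pre falls inside the requested band.
    """
    if category_counts is None:
        category_counts = {
            "markedly_effective": (37, 35),
            "ineffective": (1, 2),
            "improved": (2, 3),
        }
    bands = dict(DEFAULT_CATEGORY_BANDS, **(bands or {}))
    for cat in category_counts:
        if cat not in bands:
            raise ValidationError(f"unknown efficacy category {cat!r}")
    for gi, (gname, gsize) in enumerate((("observation", n_obs), ("control", n_ctl))):
        total = sum(v[gi] for v in category_counts.values())
        if total != gsize:
            raise ValidationError(
                f"{gname} category counts sum to {total}, expected {gsize}")

    rng = np.random.default_rng(seed)
    records: list[OutcomeRecord] = []
    for gi, (gname, _) in enumerate((("observation", n_obs), ("control", n_ctl))):
        i = 0
        for cat in CATEGORIES:
            lo, hi = bands[cat]
            for _ in range(category_counts.get(cat, (0, 0))[gi]):
                pre = int(rng.integers(30, 81))
                rate = rng.uniform(lo, hi)
                post = round(pre * (1.0 - rate / 100.0), 1)
                post = max(post, 0.0)
                records.append(OutcomeRecord(
                    patient_id=f"{gname[:3]}-{i:03d}",
                    group=gname, updrs_pre=float(pre), updrs_post=post))
                i += 1
    return records
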