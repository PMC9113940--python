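"""C1-C2 relative motion: per-repeat sliding and twist, modes, motor steps.

The central apparatus consists of two microtubule halves (C1 and C2) joined
by flexible bridge proteins.  Aligning their 32-nm repeating units pairs each
C1 repeat with its C2 counterpart; the per-pair longitudinal offset is the
*sliding* (nm, signed) and the per-pair axial-orientation difference the
*twist* (deg).  A kernel-density mode summary characterises the sliding
distribution (two peaks 8 nm apart trace the two microtubule-binding states
of the KLP1 kinesin array on C2), a tail fraction quantifies how often the
twist exceeds a threshold, and a two-head hand-over-hand step model relates
the 16-nm step of the trailing kinesin head to the 8-nm displacement of the
tail-attached motor arm.  ``convex_side`` determines which of two paired
filament tracks lies on the convex (outer) side of a bend.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import ValidationError


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = a - 360.0 * np.floor((a + 180.0) / 360.0)
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


# --------------------------------------------------------------------------
# Paired repeats and sliding/twist
# --------------------------------------------------------------------------

@dataclass
class PairedRepeatSeries:
    """Repeat-indexed frames of the C1 and C2 filaments, paired one-to-one.

    ``arc_*`` are positions (nm) along each filament's own axis and must be
    strictly increasing with the repeat index; ``angle_*`` are axial
    orientations in degrees.
    """

    index: np.ndarray
    arc_c1: np.ndarray
    angle_c1: np.ndarray
    arc_c2: np.ndarray
    angle_c2: np.ndarray

    def __post_init__(self) -> None:
        arrays = {
            "index": np.asarray(self.index),
            "arc_c1": np.asarray(self.arc_c1, dtype=float),
            "angle_c1": np.asarray(self.angle_c1, dtype=float),
            "arc_c2": np.asarray(self.arc_c2, dtype=float),
            "angle_c2": np.asarray(self.angle_c2, dtype=float),
        }
        lengths = {len(a) for a in arrays.values()}
        if len(lengths) != 1:
            raise ValidationError("all series columns must have equal length")
        if lengths.pop() < 1:
            raise ValidationError("series must contain at least one repeat")
        for name in ("arc_c1", "arc_c2"):
            if np.any(np.diff(arrays[name]) <= 0):
                raise ValidationError(f"{name} must be strictly increasing")
        for name, arr in arrays.items():
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.index)


@dataclass
class SlidingTwistProfile:
    """Per-pair sliding (nm) and twist (deg) with the baseline convention used."""

    sliding: np.ndarray
    twist: np.ndarray
    baseline_mode: str
    baseline: float = 0.0


def compute_sliding_twist(
    series: PairedRepeatSeries, baseline_mode: str = "FIRST"
) -> SlidingTwistProfile:
    """Per-repeat C1-C2 sliding and twist.

    Sliding is the C2-minus-C1 arc-position difference with a baseline
    subtracted (FIRST repeat, MEDIAN, or NONE — repeats are aligned relative
    to each other but carry no absolute zero); twist is the wrapped
    orientation difference.
    """
    if baseline_mode not in ("FIRST", "MEDIAN", "NONE"):
        raise ValidationError(f"unknown baseline mode {baseline_mode!r}")
    raw = series.arc_c2 - series.arc_c1
    if baseline_mode == "FIRST":
        baseline = float(raw[0])
    elif baseline_mode == "MEDIAN":
        baseline = float(np.median(raw))
    else:
        baseline = 0.0
    twist = wrap_angle(series.angle_c2 - series.angle_c1)
    return SlidingTwistProfile(
        sliding=raw - baseline,
        twist=np.atleast_1d(twist),
        baseline_mode=baseline_mode,
        baseline=baseline,
    )


# --------------------------------------------------------------------------
# Distribution summaries
# --------------------------------------------------------------------------

@dataclass
class ModeSummary:
    """Modes of a 1D sample found by Gaussian kernel density estimation."""

    modes: np.ndarray  # sorted ascending, data units
    separations: np.ndarray  # pairwise |mode_i - mode_j|, i < j
    bandwidth: float  # kernel sigma actually used, data units
    densities: np.ndarray | None = None  # KDE density at each mode
    tail_fraction: float | None = None
    tail_threshold: float | None = None


def detect_modes(
    values,
    bandwidth: float | None = None,
    prominence_frac: float = 0.05,
    grid_size: int = 1024,
    tail_threshold: float | None = None,
) -> ModeSummary:
    """Locate the modes of a sample via a Gaussian KDE.

    The bandwidth (kernel sigma in data units) defaults to Silverman's rule;
    modes are local maxima of the density with prominence above
    ``prominence_frac`` of the peak density, refined by parabolic
    interpolation on the evaluation grid.  A sample of identical values has
    one mode at that value.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise ValidationError("mode detection needs at least 2 values")
    tail = fraction_exceeding(x, tail_threshold) if tail_threshold is not None else None

    std = float(np.std(x, ddof=1))
    if std == 0.0:
        return ModeSummary(
            modes=np.array([x[0]]),
            separations=np.array([]),
            bandwidth=0.0,
            densities=np.array([np.inf]),
            tail_fraction=tail,
            tail_threshold=tail_threshold,
        )

    if bandwidth is None:
        kde = gaussian_kde(x, bw_method="silverman")
    else:
        if bandwidth <= 0:
            raise ValidationError("bandwidth must be positive")
        kde = gaussian_kde(x, bw_method=bandwidth / std)
    h = float(kde.factor * std)

    lo, hi = x.min() - 3 * h, x.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    density = kde(grid)
    peaks, _ = find_peaks(density, prominence=prominence_frac * density.max())

    modes = []
    step = grid[1] - grid[0]
    for p in peaks:
        # parabolic sub-grid refinement through the peak and its neighbours
        y0, y1, y2 = density[p - 1], density[p], density[p + 1]
        denom = y0 - 2 * y1 + y2
        offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        modes.append(grid[p] + offset * step)
    order = np.argsort(modes)
    modes = np.asarray(modes)[order]
    densities = density[peaks][order]
    separations = np.array(
        [modes[j] - modes[i] for i in range(len(modes)) for j in range(i + 1, len(modes))]
    )
    return ModeSummary(
        modes=modes,
        separations=separations,
        bandwidth=h,
        densities=densities,
        tail_fraction=tail,
        tail_threshold=tail_threshold,
    )


def fraction_exceeding(values, threshold: float) -> float:
    """Fraction of values with absolute magnitude above the threshold."""
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 1:
        raise ValidationError("need at least one value")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    return float(np.mean(np.abs(x) > threshold))


# --------------------------------------------------------------------------
# Two-state kinesin step model
# --------------------------------------------------------------------------

#: Tubulin-dimer lattice spacing along a protofilament (nm).
SITE_SPACING_NM = 8.0
#: Hand-over-hand step of the trailing head: two lattice sites (nm).
HEAD_STEP_NM = 16.0


@dataclass
class MotorStepModel:
    """Two-head kinesin bound at consecutive lattice sites on one protofilament.

    Positions are nm along the protofilament axis, plus end positive.  The
    tail attachment point is the midpoint of the two bound heads, so a
    hand-over-hand step of the trailing head by ``step_length`` displaces the
    tail by half of it.  ``state`` alternates between the two
    microtubule-binding states of the array.
    """

    leading: float
    trailing: float
    site_spacing: float = SITE_SPACING_NM
    step_length: float = HEAD_STEP_NM
    state: str = "MTBS-1"

    def __post_init__(self) -> None:
        if self.leading <= self.trailing:
            raise ValidationError("leading head must be ahead of the trailing head")
        if self.state not in ("MTBS-1", "MTBS-2"):
            raise ValidationError(f"unknown state {self.state!r}")

    @property
    def tail_position(self) -> float:
        return 0.5 * (self.leading + self.trailing)


def motor_step(model: MotorStepModel) -> tuple[MotorStepModel, float]:
    """One hand-over-hand step; returns (new model, tail displacement in nm).

    The trailing head detaches and rebinds ``step_length`` toward the plus
    end — one site beyond the formerly leading head — while the leading head
    stays bound.  Head spacing is conserved, the state label toggles, and
    the tail (head midpoint) advances by half the step.
    """
    if not np.isclose(model.leading - model.trailing, model.site_spacing):
        raise ValidationError(
            "heads must be bound one site apart "
            f"({model.site_spacing} nm), got {model.leading - model.trailing} nm"
        )
    new_position = model.trailing + model.step_length
    stepped = replace(
        model,
        leading=new_position,
        trailing=model.leading,
        state="MTBS-2" if model.state == "MTBS-1" else "MTBS-1",
    )
    return stepped, stepped.tail_position - model.tail_position


# --------------------------------------------------------------------------
# Convex-side determination
# --------------------------------------------------------------------------

def polyline_length(points: np.ndarray) -> float:
    """Total length of a sampled curve (sum of segment lengths)."""
    pts = np.asarray(points, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def convex_side(curve_a, curve_b, rel_tol: float = 1e-3) -> str:
    """Which of two matched filament tracks lies on the convex (outer) side.

    Two filaments bending together sweep concentric arcs over a matched
    span; the outer one is strictly longer (arc length grows with bend
    radius).  Returns "A" or "B", or "UNDETERMINED" when the arc lengths
    agree within ``rel_tol`` relative (straight or parallel case).  Works
    for 3D tracks that need not lie in a plane, unlike a signed-curvature
    test.
    """
    a = np.atleast_2d(np.asarray(curve_a, dtype=float))
    b = np.atleast_2d(np.asarray(curve_b, dtype=float))
    if len(a) != len(b):
        raise ValidationError("curves must be sampled over the same index range")
    if len(a) < 3:
        raise ValidationError("need at least 3 samples per curve")
    len_a, len_b = polyline_length(a), polyline_length(b)
    scale = 0.5 * (len_a + len_b)
    if scale == 0 or abs(len_a - len_b) <= rel_tol * scale:
        return "UNDETERMINED"
    return "A" if len_a > len_b else "B"
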