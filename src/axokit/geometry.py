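"""Filament curve fitting, fixed-spacing resampling and lattice geometry.

Sub-tomogram workflows pick filament particles by hand along each microtubule
and later need regularly spaced, consistently oriented particles.  This
module fits an independent cubic polynomial per axis to the picked 3D
coordinates (parameterised by normalised cumulative chord length), resamples
the fitted curve at a fixed arc-length spacing (32 nm for the repeating unit,
8 nm for tubulin dimers) and assigns the two Euler angles that a filament
tangent determines (tilt and psi of a ZYZ convention; the in-plane rotation
stays undetermined).  It also measures inter-protofilament angles — the
central angles between adjacent protofilament centres about the microtubule
axis — from a lattice cross-section.

All lengths are in nm, all angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import DegenerateGeometryError, ValidationError

#: Bisection tolerance (in the curve parameter t) of arc-length inversion.
ARC_INVERSION_TOL = 1e-4
#: Absolute tolerance (nm) of the arc-length quadrature.
ARC_LENGTH_ABS_TOL = 1e-4


# --------------------------------------------------------------------------
# Tracks and fitted curves
# --------------------------------------------------------------------------

@dataclass
class FilamentTrack:
    """Manually picked 3D coordinates (nm) along one filament, start to end."""

    points: np.ndarray  # (n, 3)
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError("points must be an (n, 3) array")
        if len(pts) < 4:
            raise ValidationError("cubic fitting needs at least 4 points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValidationError("consecutive points must be distinct")
        self.points = pts


@dataclass
class Polynomial3:
    """Degree-three space curve: one cubic per axis over t in [0, 1].

    ``coeffs[axis, j]`` multiplies t**j (ascending order).  The parameter is
    normalised cumulative chord length of the fitted points.
    """

    coeffs: np.ndarray  # (3, 4)
    rms_residual: float = 0.0
    parameterization: str = "chord"

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (3, 4):
            raise ValidationError("coeffs must have shape (3, 4)")
        if self.rms_residual < 0:
            raise ValidationError("rms_residual must be >= 0")
        self.coeffs = c

    def point(self, t) -> np.ndarray:
        """Curve position(s) at parameter t; shape (3,) or (n, 3)."""
        t = np.asarray(t, dtype=float)
        powers = np.stack([np.ones_like(t), t, t**2, t**3], axis=-1)
        return powers @ self.coeffs.T

    def derivative(self, t) -> np.ndarray:
        """d(curve)/dt at parameter t; shape (3,) or (n, 3)."""
        t = np.asarray(t, dtype=float)
        powers = np.stack([np.ones_like(t), 2 * t, 3 * t**2], axis=-1)
        return powers @ self.coeffs[:, 1:].T

    def speed(self, t) -> np.ndarray:
        return np.linalg.norm(np.atleast_2d(self.derivative(t)), axis=-1)

    def tangent(self, t) -> np.ndarray:
        """Unit tangent at scalar parameter t."""
        d = self.derivative(float(t))
        norm = np.linalg.norm(d)
        if norm == 0:
            raise DegenerateGeometryError(f"zero curve derivative at t={t}")
        return d / norm


def chord_parameters(points: np.ndarray) -> np.ndarray:
    """Normalised cumulative chord-length parameters of an ordered point run."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    return t / t[-1]


def fit_curve(track: FilamentTrack) -> Polynomial3:
    """Least-squares cubic per axis against normalised chord-length parameters."""
    pts = track.points
    t = chord_parameters(pts)
    vander = np.vander(t, 4, increasing=True)
    coeffs, *_ = np.linalg.lstsq(vander, pts, rcond=None)
    fitted = vander @ coeffs
    # per-coordinate RMS: isotropic noise of width sigma gives residual ~ sigma
    rms = float(np.sqrt(np.mean((fitted - pts) ** 2)))
    return Polynomial3(coeffs=coeffs.T, rms_residual=rms)


# --------------------------------------------------------------------------
# Arc length and resampling
# --------------------------------------------------------------------------

def arc_length(curve: Polynomial3, t0: float = 0.0, t1: float = 1.0) -> float:
    """Arc length (nm) of the curve between parameters t0 <= t1."""
    if not 0.0 <= t0 <= t1 <= 1.0:
        raise ValidationError(f"need 0 <= t0 <= t1 <= 1, got ({t0}, {t1})")
    if t0 == t1:
        return 0.0
    value, _ = quad(
        lambda t: float(curve.speed(t)[0]), t0, t1, epsabs=ARC_LENGTH_ABS_TOL, limit=200
    )
    return float(value)


@dataclass
class ResampledParticle:
    """One resampled particle: position plus the tangent-determined angles.

    ``rot`` (the rotation about the filament axis) cannot be read off a
    tangent and is stored as 0 with ``rot_determined=False``.
    """

    position: np.ndarray  # (3,) nm
    tilt: float  # deg, [0, 180]
    psi: float  # deg, (-180, 180]
    rot: float = 0.0
    rot_determined: bool = False
    arc_position: float = 0.0  # nm from the curve start


def euler_from_tangent(tangent: np.ndarray) -> tuple[float, float]:
    """(tilt, psi) in degrees such that Rz(psi)·Ry(tilt)·Rz(0) maps +z onto the tangent.

    tilt = arccos(t_z) in [0, 180]; psi = atan2(t_y, t_x) in (-180, 180],
    conventionally 0 when the tangent is at a pole.  This is the ZYZ
    convention used by STAR-format angle tags.
    """
    v = np.asarray(tangent, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValidationError("tangent must be a non-zero vector")
    v = v / norm
    tilt = float(np.degrees(np.arccos(np.clip(v[2], -1.0, 1.0))))
    if np.hypot(v[0], v[1]) < 1e-12:
        psi = 0.0
    else:
        psi = float(np.degrees(np.arctan2(v[1], v[0])))
    if psi <= -180.0:
        psi += 360.0
    return tilt, psi


def _invert_arc_length(curve: Polynomial3, target: float, total: float) -> float:
    """Parameter t with arc_length(0, t) = target, by monotone bisection."""
    if target <= 0:
        return 0.0
    if target >= total:
        return 1.0
    return float(
        brentq(
            lambda t: arc_length(curve, 0.0, t) - target,
            0.0,
            1.0,
            xtol=ARC_INVERSION_TOL,
        )
    )


def resample_curve(curve: Polynomial3, spacing: float) -> list[ResampledParticle]:
    """Particles at arc positions 0, s, 2s, ... along the curve.

    Consecutive particles are separated by the requested spacing along the
    arc (within the inversion tolerance); each carries the tilt/psi pair of
    the local unit tangent.  A spacing longer than the curve yields the
    single particle at the start.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    total = arc_length(curve, 0.0, 1.0)
    n = int(np.floor(total / spacing + 1e-9)) + 1
    particles = []
    for i in range(max(n, 1)):
        s = i * spacing
        t = _invert_arc_length(curve, s, total)
        tilt, psi = euler_from_tangent(curve.tangent(t))
        particles.append(
            ResampledParticle(
                position=curve.point(t), tilt=tilt, psi=psi, arc_position=s
            )
        )
    return particles


# --------------------------------------------------------------------------
# Protofilament lattice geometry
# --------------------------------------------------------------------------

@dataclass
class LatticeCrossSection:
    """Protofilament centre coordinates in one microtubule cross-section.

    Centres may be 2D or coplanar 3D; ``closed`` marks a full ring (13
    protofilaments in a singlet microtubule).
    """

    pf_centers: np.ndarray  # (n, 2) or (n, 3)
    closed: bool = True
    center_fallback: bool = field(default=False, init=False)  # centroid used

    def __post_init__(self) -> None:
        pts = np.asarray(self.pf_centers, dtype=float)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise ValidationError("pf_centers must be (n, 2) or (n, 3)")
        if len(pts) < 3:
            raise ValidationError("need at least 3 protofilament centers")
        self.pf_centers = pts


def _to_plane(points: np.ndarray) -> np.ndarray:
    """Project coplanar 3D points onto their best-fit plane's 2D coordinates."""
    if points.shape[1] == 2:
        return points
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:2].T


def fit_circle_center(points2d: np.ndarray) -> np.ndarray:
    """Algebraic least-squares circle centre (Kåsa fit) of 2D points.

    Raises DegenerateGeometryError for collinear points, where no circle is
    defined.
    """
    x, y = points2d[:, 0], points2d[:, 1]
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    rhs = x**2 + y**2
    if np.linalg.matrix_rank(a_mat, tol=1e-9 * max(1.0, np.abs(a_mat).max())) < 3:
        raise DegenerateGeometryError("collinear centers: circle fit is singular")
    sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    return sol[:2]


def inter_pf_angles(section: LatticeCrossSection) -> np.ndarray:
    """Central angles (deg) between consecutive protofilament centres.

    The rotation axis point is the least-squares circle centre of the
    centres (falling back to the centroid if the numerical fit fails, with
    ``center_fallback`` flagged on the section).  For a closed ring the n
    cyclic angles sum to 360; an open section yields n-1 angles.
    """
    pts = _to_plane(section.pf_centers)
    try:
        center = fit_circle_center(pts)
    except np.linalg.LinAlgError:
        center = pts.mean(axis=0)
        section.center_fallback = True
    rel = pts - center
    theta = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    if section.closed:
        diffs = np.diff(np.append(theta, theta[0]))
    else:
        diffs = np.diff(theta)
    diffs = (diffs + 180.0) % 360.0 - 180.0
    signs = np.sign(diffs[diffs != 0])
    if len(signs) and not (np.all(signs > 0) or np.all(signs < 0)):
        raise DegenerateGeometryError(
            "centers do not wind monotonically about the fitted axis"
        )
    return np.abs(diffs)
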