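"""Optic-disc geometry: ellipse fitting and the cup-to-disc-ratio profile.

The optic nerve head is summarised by two ellipses in image pixel
coordinates — the cup and the disc.  From a segmented pair the module
extracts the 24-direction cup-to-disc-ratio profile (pCDR): for each
direction ``d = 1..24`` (anatomical angle ``d x 15`` degrees) the ratio of
the cup-boundary distance to the disc-boundary distance along a ray cast
from the *cup centre*.  It also computes the scalar measures used by the
Disc Damage Likelihood Scale: the rim-to-disc ratio at the narrowest rim
point (RTD), the vertical disc size in pixels (DSV) and the vertical
cup/disc ratio (vCDR).

Angle convention (recorded in :data:`CONVENTION` and embedded in model
files): angle 0 is the superior pole, the image y-axis points down
(raster order), and direction index increases anti-clockwise for right
eyes; left-eye profiles are mirrored about the vertical axis so that
anatomically homologous directions share the same index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

N_DIRECTIONS = 24
ANGLE_STEP_DEG = 360.0 / N_DIRECTIONS

#: Angle/orientation convention shared by profiles and fitted models.
CONVENTION = {"angle_zero": "superior", "mirror": "left", "y_down": True}

GROUP_LABELS = ("healthy", "glaucoma", "suspect", "unknown")
LATERALITIES = ("left", "right")


class GeometryError(ValueError):
    """Invalid geometric configuration (origin outside ellipse, etc.)."""


class InsufficientLandmarksError(GeometryError):
    """Fewer than the five points needed to determine a conic."""


class NonEllipseError(GeometryError):
    """Least-squares conic through the points is not an ellipse."""


class EmptyProfileError(ValueError):
    """A profile operation requires at least one observed direction."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in image pixel coordinates.

    ``rotation`` is the angle of the semi-major axis to the image x-axis,
    in radians, normalised to ``[0, pi)``.
    """

    center_x: float
    center_y: float
    semi_major: float
    semi_minor: float
    rotation: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise GeometryError(
                f"require semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )
        object.__setattr__(self, "rotation", float(self.rotation) % math.pi)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y], dtype=float)

    def to_canonical(self, points: np.ndarray) -> np.ndarray:
        """Map image points into the ellipse-aligned (canonical) frame."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        rot = np.array([[c, s], [-s, c]])
        return p @ rot.T

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """Evaluate ``(u/a)^2 + (v/b)^2 - 1``; negative strictly inside."""
        q = self.to_canonical(points)
        return (q[:, 0] / self.semi_major) ** 2 + (q[:, 1] / self.semi_minor) ** 2 - 1.0

    def contains(self, point, tol: float = 0.0) -> bool:
        return bool(self.implicit(np.asarray(point))[0] < -tol)

    def boundary_points(self, n: int) -> np.ndarray:
        """``n`` points on the boundary (uniform in parametric angle)."""
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        q = np.column_stack([self.semi_major * np.cos(t), self.semi_minor * np.sin(t)])
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        return q @ rot.T + self.center


@dataclass(frozen=True)
class LandmarkSet:
    """Expert-clicked boundary points for one structure of one eye."""

    eye_id: str
    structure: str  # "cup" or "disc"
    points: np.ndarray  # (n, 2) pixels

    def __post_init__(self) -> None:
        if self.structure not in ("cup", "disc"):
            raise ValueError(f"structure must be cup|disc, got {self.structure!r}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class DiscSegmentation:
    """A segmented eye: cup and disc ellipses plus laterality."""

    eye_id: str
    laterality: str
    cup: Ellipse
    disc: Ellipse
    group: str = "unknown"
    pixel_scale: float | None = None  # informational, pixels per unit

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be left|right, got {self.laterality!r}")
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group!r}")
        if not self.disc.contains((self.cup.center_x, self.cup.center_y)):
            raise GeometryError(
                f"eye {self.eye_id}: cup centre is not strictly inside the disc"
            )


@dataclass(frozen=True)
class CDRProfile:
    """The 24-direction cup-to-disc-ratio vector of one eye.

    ``values[d-1]`` is the CDR at canonical direction ``d`` (angle
    ``d x 15`` degrees from the superior pole); missing directions are NaN.
    """

    eye_id: str
    laterality: str
    group: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be left|right, got {self.laterality!r}")
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group!r}")
        v = np.asarray(self.values, dtype=float).reshape(-1)
        if v.shape != (N_DIRECTIONS,):
            raise ValueError(f"profile needs {N_DIRECTIONS} slots, got {v.shape}")
        obs = v[~np.isnan(v)]
        if obs.size == 0:
            raise EmptyProfileError(f"eye {self.eye_id}: profile has no observed value")
        if np.any((obs <= 0.0) | (obs >= 1.0)):
            raise ValueError(f"eye {self.eye_id}: CDR values must lie in (0, 1)")
        object.__setattr__(self, "values", v)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())


# ---------------------------------------------------------------------------
# ellipse fitting (direct least squares on the conic)
# ---------------------------------------------------------------------------


def _conic_to_ellipse(coeffs: np.ndarray) -> Ellipse:
    """Geometric parameters from conic ``Ax^2+Bxy+Cy^2+Dx+Ey+F=0``."""
    A, B, C, D, E, F = (float(c) for c in coeffs)
    Q = np.array([[A, B / 2.0], [B / 2.0, C]])
    if np.linalg.det(Q) <= 0:
        raise NonEllipseError("conic is not an ellipse (non-elliptic quadratic form)")
    if A + C < 0:  # orient so the quadratic form is positive definite
        A, B, C, D, E, F = -A, -B, -C, -D, -E, -F
        Q = -Q
    center = np.linalg.solve(2.0 * Q, -np.array([D, E]))
    k = center @ Q @ center - F
    if k <= 0:
        raise NonEllipseError("degenerate or imaginary ellipse")
    evals, evecs = np.linalg.eigh(Q)  # ascending; smaller eigenvalue = major axis
    axes = np.sqrt(k / evals)
    major_vec = evecs[:, 0]
    rotation = math.atan2(major_vec[1], major_vec[0])
    return Ellipse(center[0], center[1], axes[0], axes[1], rotation)


def fit_ellipse(landmarks: LandmarkSet) -> Ellipse:
    """Ellipse-constrained direct least-squares conic fit (Halir–Flusser).

    Requires at least five non-collinear points.  Use
    :func:`orthogonal_residuals` to report the per-point orthogonal
    distances of the fit.
    """
    pts = np.asarray(landmarks.points, dtype=float)
    if pts.shape[0] < 5:
        raise InsufficientLandmarksError(
            f"{landmarks.eye_id}/{landmarks.structure}: need >= 5 points, "
            f"got {pts.shape[0]}"
        )
    centroid = pts.mean(axis=0)
    x, y = (pts - centroid).T  # centring only conditions the solve
    if np.linalg.matrix_rank(np.column_stack([x, y]), tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise NonEllipseError(
            f"{landmarks.eye_id}/{landmarks.structure}: landmarks are collinear"
        )
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise NonEllipseError("degenerate landmark configuration") from exc
    M = S1 + S2 @ T
    M = np.vstack([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.where(np.isreal(cond) & (np.real(cond) > 0))[0]
    if ok.size == 0:
        raise NonEllipseError(
            f"{landmarks.eye_id}/{landmarks.structure}: best conic is not an ellipse"
        )
    a1 = np.real(evecs[:, ok[0]])
    coeffs = np.concatenate([a1, T @ a1])
    # undo the centring shift: x -> x - cx, y -> y - cy
    A, B, C, D_, E_, F_ = coeffs
    cx, cy = centroid
    D0 = D_ - 2.0 * A * cx - B * cy
    E0 = E_ - B * cx - 2.0 * C * cy
    F0 = F_ + A * cx * cx + B * cx * cy + C * cy * cy - D_ * cx - E_ * cy
    return _conic_to_ellipse(np.array([A, B, C, D0, E0, F0]))


def orthogonal_residuals(ellipse: Ellipse, points: np.ndarray) -> np.ndarray:
    """Orthogonal (shortest) distance from each point to the ellipse boundary.

    Solved per point by Newton iteration on the stationarity condition of
    the parametric boundary in the canonical frame; symmetric in all four
    quadrants.
    """
    q = np.abs(ellipse.to_canonical(np.asarray(points, dtype=float)))
    a, b = ellipse.semi_major, ellipse.semi_minor
    u, v = q[:, 0], q[:, 1]
    t = np.arctan2(a * v, b * u)  # good starting angle in the first quadrant
    for _ in range(60):
        ct, st = np.cos(t), np.sin(t)
        g = (b * b - a * a) * ct * st + u * a * st - v * b * ct
        dg = (b * b - a * a) * (ct * ct - st * st) + u * a * ct + v * b * st
        step = np.where(np.abs(dg) > 1e-14, g / np.where(dg == 0, 1.0, dg), 0.0)
        t = np.clip(t - step, 0.0, math.pi / 2.0)
    return np.hypot(a * np.cos(t) - u, b * np.sin(t) - v)


# ---------------------------------------------------------------------------
# rays and profiles
# ---------------------------------------------------------------------------


def direction_vector(angle_deg: float, laterality: str = "right") -> np.ndarray:
    """Image-frame unit vector for a canonical angle.

    Canonical angle 0 points to the superior pole (decreasing y, since the
    image y-axis points down).  For right eyes the angle increases with
    positive image x; left eyes are mirrored about the vertical axis.
    """
    if laterality not in LATERALITIES:
        raise ValueError(f"laterality must be left|right, got {laterality!r}")
    psi = math.radians(angle_deg)
    sign = 1.0 if laterality == "right" else -1.0
    return np.array([sign * math.sin(psi), -math.cos(psi)])


def _ray_distance(ellipse: Ellipse, origin: np.ndarray, direction: np.ndarray) -> float:
    """Distance from ``origin`` (strictly inside) to the boundary along ``direction``."""
    o = ellipse.to_canonical(origin)[0]
    c, s = math.cos(ellipse.rotation), math.sin(ellipse.rotation)
    rot = np.array([[c, s], [-s, c]])
    u = rot @ np.asarray(direction, dtype=float)
    a, b = ellipse.semi_major, ellipse.semi_minor
    alpha = (u[0] / a) ** 2 + (u[1] / b) ** 2
    beta = 2.0 * (o[0] * u[0] / a**2 + o[1] * u[1] / b**2)
    gamma = (o[0] / a) ** 2 + (o[1] / b) ** 2 - 1.0
    if gamma >= -1e-12:
        raise GeometryError("ray origin is on or outside the ellipse boundary")
    disc = beta * beta - 4.0 * alpha * gamma
    return float((-beta + math.sqrt(disc)) / (2.0 * alpha))


def ray_boundary_distance(
    ellipse: Ellipse, origin, angle_deg: float, laterality: str = "right"
) -> float:
    """Distance from ``origin`` to the ellipse boundary along a canonical angle."""
    return _ray_distance(
        ellipse, np.asarray(origin, dtype=float), direction_vector(angle_deg, laterality)
    )


def profile_angles_deg() -> np.ndarray:
    """Canonical angles for directions ``d = 1..24`` (15-degree spacing)."""
    return ANGLE_STEP_DEG * np.arange(1, N_DIRECTIONS + 1)


def extract_pcdr(seg: DiscSegmentation) -> CDRProfile:
    """The 24-direction CDR profile of a segmented eye.

    Rays are cast from the cup centre; both the cup and the disc boundary
    distances are measured along the same ray, so each CDR is a ratio of
    collinear distances and is invariant to image scale.  Directions where
    the cup boundary reaches or crosses the disc boundary are flagged and
    emitted as missing.
    """
    origin = seg.cup.center
    values = np.full(N_DIRECTIONS, np.nan)
    flagged: list[int] = []
    for i, angle in enumerate(profile_angles_deg()):
        u = direction_vector(angle, seg.laterality)
        t_cup = _ray_distance(seg.cup, origin, u)
        t_disc = _ray_distance(seg.disc, origin, u)
        if t_cup >= t_disc:
            flagged.append(i + 1)
            continue
        values[i] = t_cup / t_disc
    if flagged:
        warnings.warn(
            f"eye {seg.eye_id}: cup boundary reaches the disc boundary in "
            f"direction(s) {flagged}; emitted as missing",
            stacklevel=2,
        )
    return CDRProfile(seg.eye_id, seg.laterality, seg.group, values)


def canonical_orientation(raw_values, laterality: str) -> np.ndarray:
    """Map a raw image-order 24-vector to the canonical (mirrored) order.

    Right eyes keep their index order.  Left eyes are reflected about the
    vertical axis — canonical index ``d`` takes raw index ``24 - d`` (with
    ``d = 24`` fixed) — so anatomically homologous directions share an
    index.  The mapping is an involution.
    """
    v = np.asarray(raw_values, dtype=float).reshape(-1)
    if v.shape != (N_DIRECTIONS,):
        raise ValueError(f"expected {N_DIRECTIONS} slots, got {v.shape}")
    if laterality not in LATERALITIES:
        raise ValueError(f"laterality must be left|right, got {laterality!r}")
    if laterality == "right":
        return v.copy()
    out = np.empty_like(v)
    out[:-1] = v[:-1][::-1]  # d <-> 24-d for d = 1..23 (0-based reversal)
    out[-1] = v[-1]
    return out


# ---------------------------------------------------------------------------
# DDLS-related scalars
# ---------------------------------------------------------------------------


def rim_to_disc_narrowest(profile: CDRProfile) -> float:
    """Rim-to-disc ratio at the narrowest rim point: ``min_d (1 - CDR_d)``."""
    obs = profile.values[profile.observed_mask]
    return float(1.0 - obs.max())


def vertical_disc_size(disc: Ellipse) -> float:
    """Length (pixels) of the disc chord along the image vertical through its centre."""
    up = _ray_distance(disc, disc.center, np.array([0.0, -1.0]))
    down = _ray_distance(disc, disc.center, np.array([0.0, 1.0]))
    return up + down


def vertical_cdr(seg: DiscSegmentation) -> float:
    """Vertical cup/disc ratio along the image vertical through the cup centre.

    Returns NaN (with a warning) if the cup chord reaches the disc chord.
    """
    origin = seg.cup.center
    up, down = np.array([0.0, -1.0]), np.array([0.0, 1.0])
    cup_chord = _ray_distance(seg.cup, origin, up) + _ray_distance(seg.cup, origin, down)
    disc_chord = _ray_distance(seg.disc, origin, up) + _ray_distance(seg.disc, origin, down)
    if cup_chord >= disc_chord:
        warnings.warn(
            f"eye {seg.eye_id}: vertical cup chord reaches the disc chord", stacklevel=2
        )
        return float("nan")
    return cup_chord / disc_chord
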