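"""Two-eye viewing geometry, screen projection, and monocular magnification.

The coordinate frame is cyclopean: origin midway between the eyes, x
rightward, y upward, z toward the screen.  The screen plane sits at
``z = viewing_distance`` and screen coordinates are in cm with the origin
at the screen centre (the fixation point).  Angles are degrees at the
public interfaces and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

LEFT = "left"
RIGHT = "right"
EYES = (LEFT, RIGHT)

HORIZONTAL = "horizontal"
VERTICAL = "vertical"
UNIFORM = "uniform"
AXES = (HORIZONTAL, VERTICAL, UNIFORM)


class GeometryError(ValueError):
    """Raised when a projection or plane intersection is ill-posed."""


@dataclass(frozen=True)
class ViewingGeometry:
    """Binocular viewing geometry: eye separation and screen distance.

    Parameters
    ----------
    ipd_cm:
        Interocular distance in cm.  Default is a population-typical
        6.2 cm; the value is a free parameter of every prediction.
    distance_cm:
        Perpendicular distance from the eye plane to the screen in cm.
    """

    ipd_cm: float = 6.2
    distance_cm: float = 29.3

    def __post_init__(self) -> None:
        if self.ipd_cm <= 0:
            raise ValueError(f"interocular distance must be > 0, got {self.ipd_cm}")
        if self.distance_cm <= 0:
            raise ValueError(f"viewing distance must be > 0, got {self.distance_cm}")

    @property
    def vergence_rad(self) -> float:
        """Vergence angle at fixation, 2*atan(ipd / (2*distance))."""
        return 2.0 * np.arctan(self.ipd_cm / (2.0 * self.distance_cm))

    @property
    def vergence_deg(self) -> float:
        return float(np.degrees(self.vergence_rad))

    def eye_position(self, eye: str) -> np.ndarray:
        """Nodal-point position of *eye* in the cyclopean frame (cm)."""
        _check_eye(eye)
        sign = -1.0 if eye == LEFT else 1.0
        return np.array([sign * self.ipd_cm / 2.0, 0.0, 0.0])


@dataclass(frozen=True)
class MagnificationSpec:
    """A monocular image magnification: which eye, which axis, how much.

    ``percent=0`` is the identity for either eye.  ``uniform`` magnifies
    both screen axes equally.
    """

    eye: str = RIGHT
    axis: str = HORIZONTAL
    percent: float = 0.0

    def __post_init__(self) -> None:
        _check_eye(self.eye)
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.percent < 0:
            raise ValueError(f"percent must be >= 0, got {self.percent}")

    @property
    def factor(self) -> float:
        return 1.0 + self.percent / 100.0

    def factors_for_eye(self, eye: str) -> Tuple[float, float]:
        """(horizontal, vertical) scale factors this spec applies to *eye*."""
        _check_eye(eye)
        if eye != self.eye or self.percent == 0:
            return (1.0, 1.0)
        if self.axis == HORIZONTAL:
            return (self.factor, 1.0)
        if self.axis == VERTICAL:
            return (1.0, self.factor)
        return (self.factor, self.factor)


@dataclass(frozen=True)
class EyeImage:
    """Screen-plane coordinates (cm) of a point set as seen by one eye."""

    eye: str
    points: np.ndarray  # (N, 2), x rightward, y upward, origin at centre

    def __post_init__(self) -> None:
        _check_eye(self.eye)
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (N, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        object.__setattr__(self, "points", pts)


def _check_eye(eye: str) -> None:
    if eye not in EYES:
        raise ValueError(f"eye must be one of {EYES}, got {eye!r}")


def project_to_eye(
    world_points: np.ndarray, eye: str, geom: ViewingGeometry
) -> EyeImage:
    """Centrally project 3D points (cm) through one eye onto the screen plane.

    The projection ray runs from the eye's nodal point at
    ``(+/- ipd/2, 0, 0)`` through the world point to the plane
    ``z = distance_cm``.  A point lying on the screen plane projects to
    itself for both eyes.

    Raises
    ------
    GeometryError
        If any point lies at or behind the eye plane (z <= 0).
    """
    pts = np.atleast_2d(np.asarray(world_points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError(f"world_points must have shape (N, 3), got {pts.shape}")
    bad = np.nonzero(pts[:, 2] <= 0)[0]
    if bad.size:
        raise GeometryError(
            f"point(s) at or behind the eye plane (z <= 0): first offender "
            f"index {bad[0]}, coordinates {pts[bad[0]].tolist()}"
        )
    ex = geom.eye_position(eye)[0]
    t = geom.distance_cm / pts[:, 2]
    x = ex + t * (pts[:, 0] - ex)
    y = t * pts[:, 1]
    return EyeImage(eye=eye, points=np.column_stack([x, y]))


def apply_magnification(img: EyeImage, mag: MagnificationSpec) -> EyeImage:
    """Scale an eye's screen coordinates about the screen centre.

    Only the image of the magnified eye changes; point order is preserved.
    """
    fx, fy = mag.factors_for_eye(img.eye)
    if fx == 1.0 and fy == 1.0:
        return img
    return EyeImage(eye=img.eye, points=img.points * np.array([fx, fy]))


def size_ratios_analytic(mag: MagnificationSpec) -> Tuple[float, float]:
    """Small-patch horizontal and vertical size ratios (HSR, VSR).

    In the limit of a vanishingly small patch at fixation, magnifying one
    eye's image simply scales that eye's angular sizes by the
    magnification factor, so the interocular ratios are ratios of the
    per-eye scale factors.  HSR = right/left horizontal size, VSR =
    right/left vertical size.
    """
    rh, rv = mag.factors_for_eye(RIGHT)
    lh, lv = mag.factors_for_eye(LEFT)
    return (rh / lh, rv / lv)


def size_ratios_at_fixation(
    geom: ViewingGeometry,
    mag: MagnificationSpec,
    patch_halfwidth: float = 0.5,
) -> Tuple[float, float]:
    """Numerically computed interocular size ratios of a small patch.

    Projects the edge midpoints of a frontoparallel square patch centred
    at fixation to each eye, applies the magnification, and measures the
    horizontal and vertical angular sizes subtended at each eye's nodal
    point.  Returns ``(HSR, VSR)`` = right-eye / left-eye sizes.  With no
    magnification both ratios are 1 by symmetry.

    ``patch_halfwidth`` (cm) should be small relative to the viewing
    distance (<= 5% recommended) so the ratios approach the analytic
    small-patch limit.
    """
    h = float(patch_halfwidth)
    if h <= 0:
        raise GeometryError(f"patch_halfwidth must be > 0, got {patch_halfwidth}")
    d = geom.distance_cm
    # Edge midpoints of the patch; they lie on the screen plane so the
    # per-eye projection is the identity and only magnification acts.
    edges = np.array([[-h, 0.0], [h, 0.0], [0.0, -h], [0.0, h]])
    sizes = {}
    for eye in EYES:
        fx, fy = mag.factors_for_eye(eye)
        pts = edges * np.array([fx, fy])
        ex = geom.eye_position(eye)[0]
        # Horizontal angular size: azimuth difference of the two x-edges.
        az = np.arctan((pts[:2, 0] - ex) / d)
        # Vertical angular size: elevation difference of the two y-edges.
        el = np.arctan(pts[2:, 1] / np.hypot(pts[2:, 0] - ex, d))
        sizes[eye] = (az[1] - az[0], el[1] - el[0])
    hsr = sizes[RIGHT][0] / sizes[LEFT][0]
    vsr = sizes[RIGHT][1] / sizes[LEFT][1]
    return (float(hsr), float(vsr))


def backproject_to_plane(
    screen_xy: np.ndarray, slant_deg: float, geom: ViewingGeometry
) -> np.ndarray:
    """Intersect cyclopean view rays with a plane slanted about the vertical.

    The plane passes through fixation ``(0, 0, d)`` and is rotated by
    ``slant_deg`` about the vertical axis; positive slant puts the right
    side of the plane farther from the observer.  Rays run from the
    cyclopean point (the origin) through each screen position.

    Returns the (N, 3) world points.  Raises :class:`GeometryError` when a
    ray is parallel to, or diverges from, the plane (grazing slant).
    """
    xy = np.atleast_2d(np.asarray(screen_xy, dtype=float))
    if abs(slant_deg) >= 90:
        raise GeometryError(f"|slant| must be < 90 deg, got {slant_deg}")
    d = geom.distance_cm
    tan_s = np.tan(np.radians(slant_deg))
    denom = d - xy[:, 0] * tan_s
    bad = np.nonzero(denom <= 1e-9 * d)[0]
    if bad.size:
        raise GeometryError(
            f"view ray misses the slanted plane (grazing slant {slant_deg} deg) "
            f"for screen point {xy[bad[0]].tolist()}"
        )
    t = d / denom
    return np.column_stack([t * xy[:, 0], t * xy[:, 1], t * d])


def slanted_plane_points(
    uv: np.ndarray, slant_deg: float, geom: ViewingGeometry
) -> np.ndarray:
    """Embed in-plane coordinates (u, v) on the slanted plane through fixation.

    ``u`` runs along the rotated horizontal direction, ``v`` up; the plane
    is rotated by ``slant_deg`` about the vertical axis through
    ``(0, 0, d)`` with positive slant moving the right side away.
    """
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    s = np.radians(slant_deg)
    x = uv[:, 0] * np.cos(s)
    z = geom.distance_cm + uv[:, 0] * np.sin(s)
    return np.column_stack([x, uv[:, 1], z])
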