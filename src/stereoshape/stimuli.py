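"""Dichoptic stimulus synthesis: disparity-isolating dot clouds and quads.

Two stimuli are produced, mirroring a stereoscopic adjustment experiment:

* a circular random-dot cloud whose slant about the vertical axis can be
  set *without* changing its on-screen (cyclopean) outline or dot
  density, so binocular disparity is the only usable slant cue;
* a quadrilateral whose right-side corner heights encode a shape ratio
  to be nulled.

Screen positions are stored in degrees of visual angle; the tangent
mapping at the viewing distance converts to cm and to display pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .geometry import (
    EYES,
    LEFT,
    RIGHT,
    GeometryError,
    MagnificationSpec,
    ViewingGeometry,
    apply_magnification,
    backproject_to_plane,
    project_to_eye,
    EyeImage,
)

DEFAULT_REGION_DIAMETER_DEG = 16.0
DEFAULT_INNER_DIAMETER_DEG = 8.0
DEFAULT_DENSITY_INNER = 0.31  # dots / deg^2, central disc
DEFAULT_DENSITY_OUTER = 0.062  # dots / deg^2, outer annulus
DEFAULT_DOT_DIAMETER_DEG = 0.05
QUAD_SIDE_DEG = 16.0


def deg_to_cm(deg: np.ndarray, distance_cm: float) -> np.ndarray:
    """Tangent mapping from visual degrees to screen cm."""
    return distance_cm * np.tan(np.radians(np.asarray(deg, dtype=float)))


def cm_to_deg(cm: np.ndarray, distance_cm: float) -> np.ndarray:
    """Inverse of :func:`deg_to_cm`."""
    return np.degrees(np.arctan(np.asarray(cm, dtype=float) / distance_cm))


@dataclass(frozen=True)
class DotCloudStimulus:
    """A disparity-isolating random dot cloud.

    ``cyclopean_deg`` is the on-screen dot layout and never changes with
    the slant setting; ``left_deg``/``right_deg`` are the per-eye screen
    positions after slant-induced disparity and monocular magnification.
    """

    cyclopean_deg: np.ndarray  # (N, 2)
    left_deg: np.ndarray  # (N, 2)
    right_deg: np.ndarray  # (N, 2)
    dot_diameter_deg: float = DEFAULT_DOT_DIAMETER_DEG
    region_diameter_deg: float = DEFAULT_REGION_DIAMETER_DEG
    inner_diameter_deg: float = DEFAULT_INNER_DIAMETER_DEG
    densities: Tuple[float, float] = (DEFAULT_DENSITY_INNER, DEFAULT_DENSITY_OUTER)
    slant_deg: float = 0.0
    seed: int = 0

    def eye_positions(self, eye: str) -> np.ndarray:
        return self.left_deg if eye == LEFT else self.right_deg


@dataclass(frozen=True)
class QuadStimulus:
    """A quadrilateral with a fixed 16-degree left side.

    Corners in degrees, ordered top-left, top-right, bottom-right,
    bottom-left.  Only the right corners' y positions are adjustable.
    """

    corners_deg: np.ndarray  # (4, 2)
    side_deg: float = QUAD_SIDE_DEG


def zone_dot_counts(
    region_diameter_deg: float = DEFAULT_REGION_DIAMETER_DEG,
    inner_diameter_deg: float = DEFAULT_INNER_DIAMETER_DEG,
    density_inner: float = DEFAULT_DENSITY_INNER,
    density_outer: float = DEFAULT_DENSITY_OUTER,
) -> Tuple[int, int]:
    """Dot counts for the central disc and the outer annulus.

    Counts are area times density, rounded to the nearest integer; the
    defaults give 16 central and 9 outer dots.
    """
    r_in = inner_diameter_deg / 2.0
    r_out = region_diameter_deg / 2.0
    n_inner = int(round(np.pi * r_in**2 * density_inner))
    n_outer = int(round(np.pi * (r_out**2 - r_in**2) * density_outer))
    return n_inner, n_outer


def generate_dot_cloud(
    seed: int,
    geom: ViewingGeometry,
    region_diameter_deg: float = DEFAULT_REGION_DIAMETER_DEG,
    inner_diameter_deg: float = DEFAULT_INNER_DIAMETER_DEG,
    density_inner: float = DEFAULT_DENSITY_INNER,
    density_outer: float = DEFAULT_DENSITY_OUTER,
    dot_diameter_deg: float = DEFAULT_DOT_DIAMETER_DEG,
) -> DotCloudStimulus:
    """Sample a two-zone random dot cloud, frontoparallel at the screen.

    Dots are drawn uniformly within each density zone by rejection
    sampling from a seeded generator, so the same seed always yields the
    same stimulus.  At the initial zero slant every dot lies on the
    screen plane, so its per-eye projections coincide with the cyclopean
    position.
    """
    rng = np.random.default_rng(seed)
    n_inner, n_outer = zone_dot_counts(
        region_diameter_deg, inner_diameter_deg, density_inner, density_outer
    )
    r_in = inner_diameter_deg / 2.0
    r_out = region_diameter_deg / 2.0
    inner = _sample_annulus(rng, n_inner, 0.0, r_in)
    outer = _sample_annulus(rng, n_outer, r_in, r_out)
    cyclopean = np.vstack([inner, outer])
    return DotCloudStimulus(
        cyclopean_deg=cyclopean,
        left_deg=cyclopean.copy(),
        right_deg=cyclopean.copy(),
        dot_diameter_deg=dot_diameter_deg,
        region_diameter_deg=region_diameter_deg,
        inner_diameter_deg=inner_diameter_deg,
        densities=(density_inner, density_outer),
        slant_deg=0.0,
        seed=seed,
    )


def _sample_annulus(
    rng: np.random.Generator, n: int, r_min: float, r_max: float
) -> np.ndarray:
    """Uniform points in an annulus by rejection from the bounding square."""
    out = np.empty((0, 2))
    while out.shape[0] < n:
        cand = rng.uniform(-r_max, r_max, size=(max(4 * n, 16), 2))
        r = np.hypot(cand[:, 0], cand[:, 1])
        keep = cand[(r >= r_min) & (r < r_max)]
        out = np.vstack([out, keep])
    return out[:n]


def set_cloud_slant(
    stim: DotCloudStimulus,
    slant_deg: float,
    geom: ViewingGeometry,
    mag: MagnificationSpec | None = None,
) -> DotCloudStimulus:
    """Set the cloud's slant without altering its on-screen layout.

    Each dot's cyclopean screen position is back-projected onto the plane
    at ``slant_deg`` through fixation, the resulting world point is
    re-projected to each eye, and the monocular magnification (if any) is
    applied to the magnified eye's screen coordinates.  Because the
    cyclopean positions are held fixed, the stimulus outline and the dot
    density histogram are invariant to the slant setting — only the
    disparities change.
    """
    if abs(slant_deg) > 60:
        raise GeometryError(f"|slant| must be <= 60 deg, got {slant_deg}")
    mag = mag or MagnificationSpec(percent=0.0)
    d = geom.distance_cm
    cyc_cm = deg_to_cm(stim.cyclopean_deg, d)
    world = backproject_to_plane(cyc_cm, slant_deg, geom)
    per_eye = {}
    for eye in EYES:
        img = project_to_eye(world, eye, geom)
        img = apply_magnification(img, mag)
        per_eye[eye] = cm_to_deg(img.points, d)
    return replace(
        stim,
        left_deg=per_eye[LEFT],
        right_deg=per_eye[RIGHT],
        slant_deg=float(slant_deg),
    )


def generate_quad(ratio: float, side_deg: float = QUAD_SIDE_DEG) -> QuadStimulus:
    """Quadrilateral whose right/left height ratio is ``ratio``.

    The left side is fixed at ``side_deg``; the right-side height change
    is split equally between the top-right and bottom-right corners, so a
    ratio of 1.05 puts the right corners at +/- 8.4 degrees.
    """
    if not ratio > 0:
        raise ValueError(f"shape ratio must be > 0, got {ratio}")
    h = side_deg / 2.0
    hr = h * ratio
    corners = np.array(
        [[-h, h], [h, hr], [h, -hr], [-h, -h]]
    )
    return QuadStimulus(corners_deg=corners, side_deg=side_deg)


def quad_shape_ratio(stim: QuadStimulus) -> float:
    """Right-side height divided by left-side height of a quad."""
    c = stim.corners_deg
    left_h = c[0, 1] - c[3, 1]
    right_h = c[1, 1] - c[2, 1]
    if left_h <= 0 or right_h <= 0:
        raise ValueError("degenerate quadrilateral: non-positive side height")
    return float(right_h / left_h)


@dataclass(frozen=True)
class DisplaySpec:
    """Pixel grid of the stereoscopic display."""

    pixel_pitch_mm: float = 0.27
    resolution: Tuple[int, int] = (1920, 1080)  # (width, height)

    @property
    def pitch_cm(self) -> float:
        return self.pixel_pitch_mm / 10.0


def deg_to_pixels(
    deg_xy: np.ndarray, display: DisplaySpec, geom: ViewingGeometry
) -> np.ndarray:
    """Degrees to (column, row) pixel coordinates, screen centre at centre."""
    cm = deg_to_cm(np.atleast_2d(deg_xy), geom.distance_cm)
    w, h = display.resolution
    col = cm[:, 0] / display.pitch_cm + (w - 1) / 2.0
    row = (h - 1) / 2.0 - cm[:, 1] / display.pitch_cm  # row index grows downward
    return np.column_stack([col, row])


def render_pair(
    stim: DotCloudStimulus | QuadStimulus,
    display: DisplaySpec,
    geom: ViewingGeometry,
) -> Tuple[np.ndarray, np.ndarray]:
    """Rasterise left/right images of a stimulus as uint8 grayscale arrays.

    Dots render white on a dark gray background; quads render as a filled
    near-black polygon on the same background.  Rendering is
    deterministic: identical stimulus and display give byte-identical
    arrays.  Raises :class:`ValueError` if the stimulus exceeds the
    display, reporting the clipped extent.
    """
    from PIL import Image, ImageDraw

    w, h = display.resolution
    background = round(0.02 * 255)  # 2% luminance gray
    images = []
    for eye in EYES:
        img = Image.new("L", (w, h), color=background)
        draw = ImageDraw.Draw(img)
        if isinstance(stim, DotCloudStimulus):
            px = deg_to_pixels(stim.eye_positions(eye), display, geom)
            _check_on_screen(px, (w, h))
            radius_px = (
                deg_to_cm(stim.dot_diameter_deg / 2.0, geom.distance_cm)
                / display.pitch_cm
            )
            r = max(float(radius_px), 0.5)
            for x, y in px:
                draw.ellipse([x - r, y - r, x + r, y + r], fill=255)
        else:
            px = deg_to_pixels(stim.corners_deg, display, geom)
            _check_on_screen(px, (w, h))
            draw.polygon([tuple(p) for p in px], fill=round(0.009 * 255))
        images.append(np.asarray(img, dtype=np.uint8))
    return images[0], images[1]


def _check_on_screen(px: np.ndarray, size: Tuple[int, int]) -> None:
    w, h = size
    off = (px[:, 0] < 0) | (px[:, 0] > w - 1) | (px[:, 1] < 0) | (px[:, 1] > h - 1)
    if np.any(off):
        bad = px[off]
        raise ValueError(
            f"stimulus extends off the display: {int(off.sum())} point(s) "
            f"clipped, first at pixel ({bad[0, 0]:.1f}, {bad[0, 1]:.1f}) "
            f"outside {w}x{h}"
        )
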