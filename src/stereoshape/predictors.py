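"""Geometric predictions: magnification -> slant, slant -> trapezoid shape.

Monocular horizontal magnification creates a horizontal size ratio (HSR)
between the eyes' images consistent with a surface slanted toward the
magnified eye (the geometric effect); vertical magnification creates a
vertical size ratio (VSR) that drives slant the opposite way (the induced
effect); uniform magnification leaves HSR/VSR = 1 and so specifies no
slant at all.  The closed-form predictor used throughout is

    sigma = arctan( ln(HSR / VSR) / mu )

with ``mu`` the vergence angle at fixation.  Positive slant means the
right side of the surface is farther from the observer.

A slanted square projects as a trapezoid: the near vertical edge is
taller.  If a frontoparallel object's disparities signal a slant sigma,
the shape percept consistent with both cues is the trapezoid whose
right/left height ratio equals the perspective convergence of a square at
slant sigma:

    ratio = (d + w*sin sigma) / (d - w*sin sigma)

for an object of half-width ``w`` at distance ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .geometry import (
    EYES,
    LEFT,
    RIGHT,
    GeometryError,
    MagnificationSpec,
    ViewingGeometry,
    apply_magnification,
    project_to_eye,
    slanted_plane_points,
)

MAX_VALID_PERCENT = 20.0  # documented validity range of the closed form


@dataclass(frozen=True)
class ObjectSpec:
    """A (half-)square object and the distance it is viewed from.

    ``half_width`` is half the object's horizontal extent in cm;
    ``viewing_distance`` may differ from the screen distance when the
    object is a real thing held in the hand.
    """

    half_width: float = 3.75
    viewing_distance: float = 35.0

    def __post_init__(self) -> None:
        if not 0 < self.half_width < self.viewing_distance:
            raise ValueError(
                f"need 0 < half_width < viewing_distance, got "
                f"{self.half_width} and {self.viewing_distance}"
            )


def predicted_slant_closed_form(
    mag: MagnificationSpec, geom: ViewingGeometry
) -> float:
    """Disparity-specified slant (degrees) for a monocular magnification.

    Uses the small-patch size ratios implied by ``mag`` and the exact
    vergence angle of ``geom``.  Signs: right-eye horizontal magnification
    gives positive slant (right side farther, surface facing the magnified
    eye); right-eye vertical gives negative slant; uniform gives exactly 0.
    Valid for magnifications up to ~20%.
    """
    if mag.percent > MAX_VALID_PERCENT:
        raise ValueError(
            f"closed form is documented for percent <= {MAX_VALID_PERCENT}, "
            f"got {mag.percent}"
        )
    # log(HSR/VSR) as a difference of per-eye log factors, so eye-swap
    # and horizontal/vertical symmetries are exact in floating point
    rh, rv = mag.factors_for_eye(RIGHT)
    lh, lv = mag.factors_for_eye(LEFT)
    log_ratio = (np.log(rh) - np.log(lh)) - (np.log(rv) - np.log(lv))
    sigma = np.arctan(log_ratio / geom.vergence_rad)
    return float(np.degrees(sigma))


def _magnified_patch_images(
    mag: MagnificationSpec,
    geom: ViewingGeometry,
    halfwidth: float,
    n_grid: int,
) -> dict:
    """Per-eye screen images of a magnified frontoparallel grid patch."""
    u = np.linspace(-halfwidth, halfwidth, n_grid)
    uu, vv = np.meshgrid(u, u)
    world = np.column_stack(
        [uu.ravel(), vv.ravel(), np.full(uu.size, geom.distance_cm)]
    )
    images = {}
    for eye in EYES:
        img = project_to_eye(world, eye, geom)
        images[eye] = apply_magnification(img, mag).points
    return images


def predicted_slant_numeric(
    mag: MagnificationSpec,
    geom: ViewingGeometry,
    patch_halfwidth: float = 0.2,
    n_grid: int = 7,
    tol_deg: float = 0.01,
    bounds_deg: float = 60.0,
) -> float:
    """Brute-force slant estimate: best-fitting plane to magnified images.

    Independent check on the closed form.  A grid patch on the screen is
    projected to both eyes and the magnification applied; then the slant
    of a physically slanted plane is searched whose un-magnified two-eye
    projections best match the magnified images in the least-squares
    sense.  The quantities that carry no slant information are free
    nuisance parameters of the fit, mirroring what is unknown to an
    observer: the object's overall size in each eye (an overall
    interocular magnification is not a slant cue) and a shared
    width/height aspect ratio (the object's shape is exactly what is in
    question).  What remains to drive the fit is the horizontal-vs-
    vertical *anisotropy* of the interocular transform, so the fit
    reproduces the geometric effect for horizontal magnification, the
    induced effect for vertical, and a null for uniform.

    The patch is kept small relative to the viewing distance because the
    slanted plane's *monocular* keystone distortion — a perspective cue
    the disparity-isolating stimuli deliberately withhold — is absent
    from the magnified target images and would otherwise bias the fit;
    it enters the residual only at second order in the patch size.

    The search is deterministic: a 1-degree grid over
    ``[-bounds_deg, bounds_deg]`` followed by bounded refinement to
    ``tol_deg``; the nuisance scales are solved by nested 1-D bounded
    minimisation (aspect) around closed-form per-eye scales.
    """
    target = _magnified_patch_images(mag, geom, patch_halfwidth, n_grid)
    u = np.linspace(-1.0, 1.0, n_grid) * patch_halfwidth
    uu, vv = np.meshgrid(u, u)
    uv = np.column_stack([uu.ravel(), vv.ravel()])

    def sse_at(slant_deg: float) -> float:
        world = slanted_plane_points(uv, slant_deg, geom)
        imgs = {eye: project_to_eye(world, eye, geom).points for eye in EYES}

        def sse_aspect(aspect: float) -> float:
            err = 0.0
            for eye in EYES:
                pred = imgs[eye] * np.array([aspect, 1.0])
                t = target[eye]
                # optimal per-eye uniform scale in closed form
                denom = float(np.sum(pred * pred))
                s = float(np.sum(pred * t)) / denom if denom > 0 else 1.0
                err += float(np.sum((s * pred - t) ** 2))
            return err

        res = minimize_scalar(
            sse_aspect, bounds=(0.5, 2.0), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.fun)

    coarse = np.arange(-bounds_deg, bounds_deg + 0.5, 1.0)
    errs = np.array([sse_at(s) for s in coarse])
    i = int(np.argmin(errs))
    lo = coarse[max(i - 1, 0)]
    hi = coarse[min(i + 1, coarse.size - 1)]
    res = minimize_scalar(
        sse_at, bounds=(lo, hi), method="bounded",
        options={"xatol": tol_deg / 2.0},
    )
    if not res.success:  # pragma: no cover - bounded search always converges
        raise GeometryError(f"slant search failed to converge: {res.message}")
    return float(res.x)


def perspective_shape_ratio(slant_deg: float, obj: ObjectSpec) -> float:
    """Right/left projected-height ratio of a square at slant ``slant_deg``.

    This is the perspective convergence of a square of half-width ``w`` at
    distance ``d`` slanted by sigma: the right edge sits at distance
    ``d + w*sin(sigma)`` and the left at ``d - w*sin(sigma)``, so viewed
    from the cyclopean point their projected heights are in the ratio

        (d + w*sin sigma) / (d - w*sin sigma)

    Equivalently: the shape percept of a frontoparallel square whose
    retinal image is reinterpreted at slant sigma.
    """
    if abs(slant_deg) >= 90:
        raise ValueError(f"|slant| must be < 90 deg, got {slant_deg}")
    d = obj.viewing_distance
    w = obj.half_width
    offset = w * np.sin(np.radians(slant_deg))
    if abs(offset) >= d:
        raise ValueError(
            f"object edge at or behind the eye: |w*sin(slant)| = {abs(offset):.3g} "
            f">= viewing distance {d}"
        )
    return float((d + offset) / (d - offset))


def nulling_shape_ratio(slant_deg: float, obj: ObjectSpec) -> float:
    """On-screen shape ratio that cancels the percept at ``slant_deg``.

    The adjustment that makes a stimulus look square is the reciprocal of
    the perceived distortion: ``perspective_shape_ratio(-slant_deg, obj)``.
    """
    return perspective_shape_ratio(-slant_deg, obj)


def predicted_shape_curve(
    signed_mags: np.ndarray,
    slant_responses_deg: np.ndarray,
    obj: ObjectSpec,
    eval_mags: np.ndarray,
) -> np.ndarray:
    """Predict shape-task settings from slant-task settings.

    Each recorded slant-task response (the physical slant that nulled the
    percept) is mapped to the shape-task setting it predicts via
    :func:`perspective_shape_ratio`; a third-order polynomial in signed
    magnification (left-eye conditions negative, right-eye positive) is
    least-squares fitted to those predictions and evaluated at
    ``eval_mags``.
    """
    x = np.asarray(signed_mags, dtype=float)
    resp = np.asarray(slant_responses_deg, dtype=float)
    if x.shape != resp.shape:
        raise ValueError("signed_mags and slant_responses_deg must align")
    if np.unique(x).size < 4:
        raise ValueError(
            f"need >= 4 distinct signed magnification levels for a cubic fit, "
            f"got {np.unique(x).size}"
        )
    predicted = np.array([perspective_shape_ratio(s, obj) for s in resp])
    coeffs = np.polynomial.polynomial.polyfit(x, predicted, deg=3)
    return np.polynomial.polynomial.polyval(
        np.asarray(eval_mags, dtype=float), coeffs
    )


def real_object_shape_prediction(
    mag: MagnificationSpec, geom: ViewingGeometry, obj: ObjectSpec
) -> float:
    """Predicted drawn right/left shape ratio for a magnified real object.

    Composes the closed-form disparity slant (at the object's viewing
    distance) with the perspective shape ratio.  For a 3.8% horizontal
    magnifier over the right eye, a 7.5-cm square at 35 cm, and a 6.2 cm
    interocular distance this is ~1.05: the right side should look about
    5% taller.
    """
    geom_obj = ViewingGeometry(
        ipd_cm=geom.ipd_cm, distance_cm=obj.viewing_distance
    )
    slant = predicted_slant_closed_form(mag, geom_obj)
    return perspective_shape_ratio(slant, obj)
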