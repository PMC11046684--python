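"""Predict the shape illusion produced by a monocular horizontal magnifier.

Builds the viewing geometry of someone holding a 7.5-cm square at 35 cm
while wearing a 3.8% horizontal magnifier over the right eye, and prints
the disparity-specified slant and the trapezoidal shape ratio the
geometry predicts they will perceive.
"""

from stereoshape import (
    MagnificationSpec,
    ObjectSpec,
    ViewingGeometry,
    predicted_slant_closed_form,
    real_object_shape_prediction,
)

geom = ViewingGeometry(ipd_cm=6.2, distance_cm=35.0)
obj = ObjectSpec(half_width=3.75, viewing_distance=35.0)
mag = MagnificationSpec(eye="right", axis="horizontal", percent=3.8)

slant = predicted_slant_closed_form(mag, geom)
ratio = real_object_shape_prediction(mag, geom, obj)

print(f"magnification: {mag.percent}% {mag.axis}, {mag.eye} eye")
print(f"disparity-specified slant: {slant:+.2f} deg "
      "(positive = right side farther)")
print(f"predicted drawn shape ratio (right/left): {ratio:.4f}")
print()
print("A ratio above 1 means the right side of the square should look")
print(f"about {100 * (ratio - 1):.1f}% taller than the left — the")
print("trapezoid consistent with a square image on a slanted surface.")

print("\nSlant predictions across the screen-experiment grid (29.3 cm):")
screen = ViewingGeometry(ipd_cm=6.2, distance_cm=29.3)
for axis in ("horizontal", "vertical", "uniform"):
    row = [predicted_slant_closed_form(
        MagnificationSpec("right", axis, p), screen) for p in (3, 6, 9, 12)]
    print(f"  {axis:10s} " + "  ".join(f"{s:+6.2f}" for s in row)
          + "   deg at 3/6/9/12%")
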