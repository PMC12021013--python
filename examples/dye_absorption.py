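"""Measure a dye solution's absorption coefficient from a half-ball-lens image.

A 5-mm half-ball lens resting in a drop of dye produces a radially symmetric
intensity falloff: the dye layer depth at distance d from the touch point is
h = R - sqrt(R^2 - d^2), so ln(I) is linear in h with slope -alpha.
"""

from tiettd import (
    LensGeometry,
    dye_osmolality,
    fit_absorption,
    halfball_image,
    radial_profile,
    recommended_max_concentration,
)

TRUE_ALPHA = 0.15  # um^-1, typical for 7 mg/ml Acid Blue 9
lens = LensGeometry(radius=5000.0)

image = halfball_image(TRUE_ALPHA, lens, i0=4000.0, pixel_size=10.0, shape=(256, 256))
profile = radial_profile(image, center=(127.5, 127.5), pixel_size=10.0)
alpha, r2 = fit_absorption(profile, lens)

print(f"true alpha    : {TRUE_ALPHA:.4f} 1/um")
print(f"fitted alpha  : {alpha:.4f} 1/um   (r^2 = {r2:.6f})")
print("r^2 should be no less than 0.9999 for a usable calibration.\n")

depth = 40.0  # um chamber from adhesive-tape spacer
print(f"max dye concentration for a {depth:.0f}-um chamber: "
      f"{recommended_max_concentration(depth):.2f} mg/ml")
print(f"osmolality added by 7 mg/ml dye : {dye_osmolality(7.0):.2f} mosm/kg")
print(f"osmolality added by 80 mg/ml dye: {dye_osmolality(80.0):.1f} mosm/kg "
      "(bacterial imaging; osmotic effect is no longer negligible)")
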