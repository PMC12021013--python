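"""Calibration of the TIE coefficient s and the dye absorption coefficient alpha.

Two independent calibrations feed the quantification step:

* **Bead-in-oil TIE calibration.**  Silica beads of known diameter are imaged
  in a series of index oils; the background-corrected integrated phase per
  bead, divided by the bead volume, is regressed against the oil index.  The
  negative slope g converts reconstructed phase per volume into refractive
  index difference, and the empirical coefficient

      s = 1 / (0.185 * g)     [um]

  replaces the ideal prefactor 0.86*lambda in the protein-concentration
  relation.  With an ideal (undamped) solver g equals 2*pi/lambda and s
  reduces to the theoretical value 0.86*lambda.

* **Half-ball-lens absorption measurement.**  A plano-convex half-ball lens
  (radius R = 5000 um) rests on a slide in a drop of dye.  The dye layer depth
  at radial distance d from the touch point is h = R - sqrt(R^2 - d^2), so the
  slope of ln(I) against h along the radial intensity profile gives -alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import REFRACTIVE_INCREMENT

__all__ = [
    "BeadObservation",
    "CalibrationFit",
    "LensGeometry",
    "sphere_volume",
    "fit_bead_calibration",
    "theoretical_s",
    "halfball_depth",
    "radial_profile",
    "fit_absorption",
]


@dataclass(frozen=True)
class BeadObservation:
    """One bead (or bead group) measured in one index oil.

    ``t_bead`` is the background-corrected integrated phase for the whole
    group, A*(mean T - T_bkg); it is divided by ``n_beads_in_group`` before
    regression.
    """

    n_oil: float
    t_bead: float
    n_beads_in_group: int = 1

    def __post_init__(self) -> None:
        if not (1.3 <= self.n_oil <= 1.6):
            raise ValueError(f"n_oil {self.n_oil} outside plausible oil range [1.3, 1.6]")
        if self.n_beads_in_group < 1:
            raise ValueError("n_beads_in_group must be >= 1")


@dataclass(frozen=True)
class CalibrationFit:
    """Result of the bead-in-oil regression.

    ``slope`` is the fitted slope of t_bead/V_bead against n_oil (negative for
    correctly ordered defocus images); ``g = -slope`` is the phase response
    per unit index difference per um^3, and ``s = 1/(0.185*g)`` in um.
    ``n_bead`` is recorded as metadata only; it enters the intercept, not the
    slope.
    """

    slope: float
    intercept: float
    g: float
    s: float
    r_squared: float
    n_bead: float | None = None
    v_bead: float | None = None
    wavelength: float | None = None


@dataclass(frozen=True)
class LensGeometry:
    """Half-ball lens geometry: radius in um, touch-point center in pixels (y, x)."""

    radius: float = 5000.0
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("lens radius must be positive")


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere from its diameter, (pi/6) d^3, in um^3 for um input."""
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    return np.pi / 6.0 * diameter**3


def theoretical_s(wavelength: float) -> float:
    """Ideal-solver value of s: lambda/(2*pi*0.185) = 0.86*lambda, in um.

    Serves as the sanity reference for bead calibrations; an undamped exact
    TIE inversion should reproduce it.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength / (2.0 * np.pi * REFRACTIVE_INCREMENT)


def fit_bead_calibration(
    obs: Iterable[BeadObservation],
    v_bead: float,
    n_bead: float | None = None,
    wavelength: float | None = None,
) -> CalibrationFit:
    """Least-squares bead-in-oil calibration.

    Regresses per-bead integrated phase, normalized by the mean bead volume
    ``v_bead`` (um^3), against the oil refractive index.  The response per
    unit index difference is g = -slope and the empirical coefficient is
    s = 1/(0.185*g).

    Raises
    ------
    ValueError
        If fewer than two distinct oils are supplied, or if g <= 0 (a
        positive slope indicates swapped over/under focused images).
    """
    obs = list(obs)
    if v_bead <= 0:
        raise ValueError("v_bead must be positive")
    x = np.array([o.n_oil for o in obs], dtype=float)
    y = np.array([o.t_bead / o.n_beads_in_group / v_bead for o in obs], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("bead calibration needs at least 2 distinct oil indices")
    fit = stats.linregress(x, y)
    g = -fit.slope
    if g <= 0:
        raise ValueError(
            "non-negative calibration slope: integrated phase should decrease "
            "with oil index; over/under focused images are probably swapped"
        )
    return CalibrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        g=float(g),
        s=float(1.0 / (REFRACTIVE_INCREMENT * g)),
        r_squared=float(fit.rvalue**2),
        n_bead=n_bead,
        v_bead=v_bead,
        wavelength=wavelength,
    )


def halfball_depth(d, lens: LensGeometry):
    """Dye-layer depth under a half-ball lens at radial distance d (um).

    h(d) = R - sqrt(R^2 - d^2); monotonically increasing from 0 at the touch
    point to R at the lens edge.  Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any() or (d > lens.radius).any():
        raise ValueError("radial distance must lie in [0, lens radius]")
    h = lens.radius - np.sqrt(lens.radius**2 - d**2)
    return float(h) if h.ndim == 0 else h


def radial_profile(
    image: np.ndarray,
    center: tuple[float, float],
    pixel_size: float,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Annular mean intensity profile around a center point.

    Pixels are binned by radial distance in annuli of ``bin_width`` pixels;
    each bin reports the mean radius (converted to um via ``pixel_size``) and
    the mean intensity of its pixels.

    Returns
    -------
    DataFrame with columns ``radius_um``, ``intensity``, ``n_pixels``.
    """
    image = np.asarray(image, dtype=float)
    cy, cx = center
    ny, nx = image.shape
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError(f"center {center} lies outside image of shape {image.shape}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    yy, xx = np.indices(image.shape)
    r = np.hypot(yy - cy, xx - cx)
    idx = (r / bin_width).astype(np.intp)
    counts = np.bincount(idx.ravel())
    sum_i = np.bincount(idx.ravel(), weights=image.ravel())
    sum_r = np.bincount(idx.ravel(), weights=r.ravel())
    valid = counts > 0
    return pd.DataFrame(
        {
            "radius_um": sum_r[valid] / counts[valid] * pixel_size,
            "intensity": sum_i[valid] / counts[valid],
            "n_pixels": counts[valid].astype(int),
        }
    )


def fit_absorption(
    profile: pd.DataFrame | Sequence[tuple[float, float]],
    lens: LensGeometry,
    dark: float = 0.0,
    exclude_inner_fraction: float = 0.05,
    drop_last: bool = True,
    min_points: int = 10,
    r2_threshold: float = 0.9999,
) -> tuple[float, float]:
    """Fit the dye absorption coefficient from a half-ball radial profile.

    Radii are converted to depths via :func:`halfball_depth` and ln(I - dark)
    is regressed against depth; alpha is the negative slope in um^-1.

    Points with radius below ``exclude_inner_fraction`` of the lens radius are
    dropped (the very low depths near the touch point are unreliable), as is
    the final bin (historically reported incorrectly by the profiling plugin).
    A coefficient of determination below ``r2_threshold`` triggers a quality
    warning but does not abort.

    Returns
    -------
    (alpha, r_squared)
    """
    if isinstance(profile, pd.DataFrame):
        radii = profile["radius_um"].to_numpy(dtype=float)
        intens = profile["intensity"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(profile), dtype=float)
        radii, intens = arr[:, 0], arr[:, 1]
    if drop_last and radii.size > 1:
        radii, intens = radii[:-1], intens[:-1]
    keep = (radii >= exclude_inner_fraction * lens.radius) & (radii <= lens.radius)
    radii, intens = radii[keep], intens[keep]
    if radii.size < min_points:
        raise ValueError(
            f"only {radii.size} usable profile points after exclusions "
            f"(need >= {min_points})"
        )
    corrected = intens - dark
    if (corrected <= 0).any():
        raise ValueError("profile intensities must exceed the dark level")
    h = halfball_depth(radii, lens)
    y = np.log(corrected)
    if np.ptp(y) == 0:
        warnings.warn(
            "constant radial profile: absorption coefficient is 0 and r^2 is undefined",
            stacklevel=2,
        )
        return 0.0, float("nan")
    fit = stats.linregress(h, y)
    r2 = float(fit.rvalue**2)
    if r2 < r2_threshold:
        warnings.warn(
            f"absorption fit quality r^2 = {r2:.6f} below {r2_threshold}; "
            "check centering, dark level and exclusion bounds",
            stacklevel=2,
        )
    return float(-fit.slope), r2
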