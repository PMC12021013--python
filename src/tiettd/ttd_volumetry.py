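"""Cell volumetry by transmission through an absorbing dye (TTD).

An impermeant, strongly absorbing extracellular dye (typically Acid Blue 9)
fills the space between coverslip and slide.  A cell with an intact membrane
excludes the dye, thinning the absorbing layer above it, so the cell appears
brighter than the background in direct relation to its height.  Beer-Lambert
inversion converts the intensity ratio into a thickness profile,

    h(x, y) = (ln I(x, y) - ln I_bkg) / alpha,

and summing h over an ROI gives the cell volume.  Natural logarithms are used
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DyeSolution",
    "TTDImage",
    "HeightMap",
    "height_map",
    "roi_volume",
    "recommended_max_concentration",
    "dye_osmolality",
]

#: Osmolality added per unit dye concentration, mosm*ml/(kg*mg), for AB9.
OSMOLALITY_SLOPE = 2.25


@dataclass(frozen=True)
class DyeSolution:
    """An absorbing dye solution used as the TTD contrast medium.

    ``absorption_coefficient`` (alpha, um^-1) is measured for each batch with
    the half-ball-lens method (:mod:`tiettd.calibration`); for AB9 at 7 mg/ml
    it is typically 0.15-0.16 um^-1.
    """

    concentration: float = 7.0  # mg/ml
    absorption_coefficient: float | None = None  # um^-1
    osmolality_slope: float = OSMOLALITY_SLOPE

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.absorption_coefficient is not None and self.absorption_coefficient <= 0:
            raise ValueError("absorption_coefficient must be positive when set")

    def require_alpha(self) -> float:
        if self.absorption_coefficient is None:
            raise ValueError(
                "dye absorption coefficient is not set; measure it first "
                "(calibrate alpha) or supply it explicitly"
            )
        return self.absorption_coefficient


@dataclass(frozen=True)
class TTDImage:
    """A dye-exclusion transmission image.

    ``background_log_intensity`` is the mean natural log of the background
    intensity (ln I_bkg); when None it must be derived from a background ROI.
    """

    intensity: np.ndarray
    pixel_size: float
    background_log_intensity: float | None = None
    dark_level: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.intensity.ndim != 2:
            raise ValueError("TTD image must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.dark_level < 0:
            raise ValueError("dark_level must be >= 0")

    def log_intensity(self) -> np.ndarray:
        """Natural log of the dark-subtracted intensity.

        Raises on non-positive pixels: a pixel at or below the dark level
        indicates saturation or a misconfigured dark level, not a valid
        measurement, so quantification refuses to clamp it silently.
        """
        corrected = self.intensity - self.dark_level
        if (corrected <= 0).any():
            bad = int((corrected <= 0).sum())
            worst = float(corrected.min())
            raise ValueError(
                f"{bad} pixel(s) non-positive after dark subtraction "
                f"(minimum {worst:g} counts); check dark level and exposure"
            )
        return np.log(corrected)


@dataclass(frozen=True)
class HeightMap:
    """2-D sample thickness field h(x, y) in um."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("height map must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def height_map(img: TTDImage, dye: DyeSolution) -> HeightMap:
    """Convert a TTD image into a thickness map, h = (ln I - ln I_bkg)/alpha.

    Invariant under joint rescaling of I and I_bkg (exposure changes cancel in
    the log ratio).  Requires ``img.background_log_intensity``; use
    :func:`roi_volume` when the background is defined by a label image instead.
    """
    alpha = dye.require_alpha()
    if img.background_log_intensity is None:
        raise ValueError(
            "background_log_intensity is not set on the TTD image; "
            "set it or use roi_volume with a background region"
        )
    h = (img.log_intensity() - img.background_log_intensity) / alpha
    return HeightMap(values=h, pixel_size=img.pixel_size)


def roi_volume(img: TTDImage, rois, dye: DyeSolution) -> pd.DataFrame:
    """Per-ROI volume from a TTD image, V = (A/alpha)*(mean ln I - mean ln I_bkg).

    The background log intensity is the mean of ln(I) over the background
    region (average logarithmic intensity, not log of the average).

    Returns
    -------
    DataFrame with columns ``label``, ``area_um2``, ``mean_ln_I``,
    ``bkg_ln_I``, ``volume_um3``.
    """
    alpha = dye.require_alpha()
    if rois.labels.shape != img.intensity.shape:
        raise ValueError(
            f"label image shape {rois.labels.shape} does not match "
            f"TTD image shape {img.intensity.shape}"
        )
    log_i = img.log_intensity()
    bkg_mask = rois.background_mask()
    if not bkg_mask.any():
        raise ValueError("background region is empty; cannot compute ROI volumes")
    bkg_ln = float(log_i[bkg_mask].mean())
    px_area = img.pixel_size**2
    rows = []
    for label in rois.roi_labels():
        mask = rois.labels == label
        npix = int(mask.sum())
        if npix == 0:
            warnings.warn(f"ROI {label} is empty; skipped", stacklevel=2)
            continue
        mean_ln = float(log_i[mask].mean())
        area = npix * px_area
        rows.append(
            {
                "label": label,
                "area_um2": area,
                "mean_ln_I": mean_ln,
                "bkg_ln_I": bkg_ln,
                "volume_um3": (area / alpha) * (mean_ln - bkg_ln),
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "area_um2", "mean_ln_I", "bkg_ln_I", "volume_um3"]
    )


def recommended_max_concentration(chamber_depth: float) -> float:
    """Upper bound on dye concentration (mg/ml) for a chamber of given depth (um).

    Rule of thumb C <= 300/h' keeping the background well above the dark
    level; e.g. 40-um tape allows up to 7.5 mg/ml, consistent with the 7 mg/ml
    routinely used for cultured eukaryotic cells.
    """
    if chamber_depth <= 0:
        raise ValueError("chamber depth must be positive")
    return 300.0 / chamber_depth


def dye_osmolality(concentration: float) -> float:
    """Osmolality increase (mosm/kg) caused by AB9 at the given mg/ml.

    Linear with slope 2.25 mosm*ml/(kg*mg) over 0-100 mg/ml; relevant mainly
    for bacteria, which need dye concentrations around 80 mg/ml.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return OSMOLALITY_SLOPE * concentration
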