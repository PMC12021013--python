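"""Phase retrieval from defocused brightfield pairs via the transport-of-intensity equation.

The TIE links the axial intensity derivative of a transmitted beam to the
transverse Laplacian of its phase,

    (2 pi n_imm / lambda) * dI/(I dz') = -laplacian(phi),

so two brightfield images collected symmetrically about best focus suffice to
reconstruct the phase up to an additive constant.  The numerical solution is
designated ``T`` (a *relative* phase map): inverting the Laplacian requires a
regularized spectral division whose damping makes absolute values
calibration-dependent, which is why a bead-based empirical coefficient ``s``
(see :mod:`tiettd.calibration`) replaces the ideal prefactor in downstream
quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.fft import dctn, idctn

__all__ = [
    "OpticalConfig",
    "DefocusPair",
    "PhaseMap",
    "RoiSet",
    "equalize_pair",
    "solve_tie",
    "roi_integrated_phase",
]

# Floor for the pixelwise mean intensity, as a fraction of the field mean.
_INTENSITY_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry and wavelength parameters.

    Parameters
    ----------
    wavelength:
        Illumination wavelength in vacuum, um.
    n_imm:
        Refractive index of the objective's immersion medium (1.0 for dry).
    n_medium:
        Refractive index of the mounting medium.  Recorded for provenance but
        unused by the solver: it cancels from the TIE once the difference
        between stage travel and focal-plane shift is accounted for.
    defocus_separation:
        FULL axial distance between the two imaged planes, um (e.g. planes at
        +/-0.5 um give 1.0).
    pixel_size:
        Lateral sampling, um per pixel.
    dark_level:
        Camera offset in counts, subtracted before any arithmetic.
    """

    wavelength: float
    n_imm: float = 1.0
    n_medium: float = 1.33
    defocus_separation: float = 1.0
    pixel_size: float = 0.3
    dark_level: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.n_imm < 1:
            raise ValueError("n_imm must be >= 1")
        if self.defocus_separation <= 0:
            raise ValueError("defocus_separation must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.dark_level < 0:
            raise ValueError("dark_level must be >= 0")


@dataclass(frozen=True)
class DefocusPair:
    """A pair of mutually defocused brightfield images.

    ``bf_over`` is the overfocused plane (BF1) and ``bf_under`` the
    underfocused plane (BF2); a positive-phase object appears brighter in BF1.
    """

    bf_over: np.ndarray
    bf_under: np.ndarray
    config: OpticalConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "bf_over", np.asarray(self.bf_over, dtype=float))
        object.__setattr__(self, "bf_under", np.asarray(self.bf_under, dtype=float))
        if self.bf_over.ndim != 2 or self.bf_under.ndim != 2:
            raise ValueError("brightfield images must be 2-D")
        if self.bf_over.shape != self.bf_under.shape:
            raise ValueError(
                f"defocus pair shapes differ: {self.bf_over.shape} vs {self.bf_under.shape}"
            )


@dataclass(frozen=True)
class PhaseMap:
    """2-D reconstructed phase field T(x, y) in relative phase units."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("phase map must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class RoiSet:
    """Integer label image defining cell ROIs and a background region.

    ``labels`` follows the usual label-image convention: 0 marks unassigned
    pixels, positive integers mark regions.  ``background_label`` selects
    which label is the background used for local correction; with the default
    of 0 every unassigned pixel is background.
    """

    labels: np.ndarray
    background_label: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(labels.dtype, np.integer):
            labels = labels.astype(np.int64)
        object.__setattr__(self, "labels", labels)

    def background_mask(self) -> np.ndarray:
        return self.labels == self.background_label

    def roi_labels(self) -> list[int]:
        labels = np.unique(self.labels)
        return [int(v) for v in labels if v != self.background_label and v != 0]

    def crop(self, sl: tuple[slice, slice]) -> "RoiSet":
        return RoiSet(self.labels[sl], self.background_label)


def equalize_pair(pair: DefocusPair) -> DefocusPair:
    """Equalize the mean intensities of the two defocused images.

    BF1' = BF1 + (mean(BF2) - mean(BF1))/2 and symmetrically for BF2', so both
    outputs share the average of the two input means while their pixelwise sum
    is unchanged.  This removes global exposure differences that the inverse
    Laplacian would otherwise amplify into large spurious phase gradients.
    """
    m1 = pair.bf_over.mean()
    m2 = pair.bf_under.mean()
    shift = 0.5 * (m2 - m1)
    return replace(pair, bf_over=pair.bf_over + shift, bf_under=pair.bf_under - shift)


def _laplacian_eigenvalues(n: int, spacing: float) -> np.ndarray:
    """Eigenvalues of the 1-D 5-point (second-difference) Laplacian under the
    half-sample symmetric (Neumann) extension diagonalized by DCT-II."""
    k = np.arange(n)
    return (2.0 - 2.0 * np.cos(np.pi * k / n)) / spacing**2


def discrete_laplacian(field: np.ndarray, spacing: float) -> np.ndarray:
    """5-point Laplacian with half-sample symmetric boundaries.

    This is the exact forward operator inverted by :func:`solve_tie`; the
    synthetic forward model uses it so that the forward/inverse pair is an
    identity (minus mean) at zero regularization.
    """
    return ndimage.laplace(np.asarray(field, dtype=float), mode="reflect") / spacing**2


def _inverse_laplacian(source: np.ndarray, spacing: float, eps: float) -> np.ndarray:
    """Solve -laplacian(T) = source spectrally with Tikhonov-style damping.

    The inverse transfer function 1/k^2 is damped to 1/(k^2 + eps*k^2_max);
    the DC mode is set to zero (gauge fixing happens later on the trimmed
    field).
    """
    ny, nx = source.shape
    k2 = (
        _laplacian_eigenvalues(ny, spacing)[:, None]
        + _laplacian_eigenvalues(nx, spacing)[None, :]
    )
    denom = k2 + eps * k2.max()
    denom[0, 0] = np.inf  # DC mode is gauge, removed below
    s_hat = dctn(source, type=2, norm="ortho")
    t_hat = s_hat / denom
    t_hat[0, 0] = 0.0
    return idctn(t_hat, type=2, norm="ortho")


def solve_tie(pair: DefocusPair, regularization: float = 1e-3) -> PhaseMap:
    """Reconstruct the relative phase map T from a defocus pair.

    Parameters
    ----------
    pair:
        Overfocused/underfocused brightfield images with their optical
        configuration.  The configured ``dark_level`` is subtracted first.
    regularization:
        Dimensionless damping ``eps`` applied to the squared spatial frequency
        during the spectral inversion.  ``eps = 0`` gives the exact inverse of
        :func:`discrete_laplacian` (the oracle mode); the default 1e-3 damps
        the low-frequency noise amplification typical of TIE inversion.

    Returns
    -------
    PhaseMap
        Zero-mean phase field, trimmed by 1 pixel on every side (output is 2
        pixels smaller than the inputs in each dimension).

    Notes
    -----
    The result is independent of ``config.n_medium``: the mounting-medium
    index cancels between the refraction of oblique rays and the axial
    foreshortening of the focal shift.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    cfg = pair.config
    dark = replace(
        pair,
        bf_over=pair.bf_over - cfg.dark_level,
        bf_under=pair.bf_under - cfg.dark_level,
    )
    eq = equalize_pair(dark)
    mean_image = 0.5 * (eq.bf_over + eq.bf_under)
    field_mean = mean_image.mean()
    if field_mean <= 0:
        raise ValueError(
            "degenerate input: mean intensity is non-positive after dark subtraction"
        )
    mean_image = np.maximum(mean_image, _INTENSITY_FLOOR_FRACTION * field_mean)
    source = (
        (2.0 * np.pi * cfg.n_imm / cfg.wavelength)
        * (eq.bf_over - eq.bf_under)
        / (mean_image * cfg.defocus_separation)
    )
    full = _inverse_laplacian(source, cfg.pixel_size, regularization)
    if full.shape[0] <= 2 or full.shape[1] <= 2:
        raise ValueError("input images too small to trim a 1-pixel border")
    trimmed = full[1:-1, 1:-1]
    trimmed = trimmed - trimmed.mean()
    return PhaseMap(values=trimmed, pixel_size=cfg.pixel_size)


def roi_integrated_phase(T: PhaseMap, rois: RoiSet) -> pd.DataFrame:
    """Background-corrected integrated phase per ROI.

    For each non-background label computes ``A * (mean(T in ROI) - mean(T in
    background))`` with the area ``A`` in um^2.  The background subtraction
    makes the integral invariant under a constant offset of the whole field,
    which resolves the additive (DC) ambiguity of the TIE solution.

    Returns
    -------
    DataFrame with columns ``label``, ``area_um2``, ``mean_T``, ``bkg_T``,
    ``integral_T``.
    """
    if rois.labels.shape != T.values.shape:
        raise ValueError(
            f"label image shape {rois.labels.shape} does not match "
            f"phase map shape {T.values.shape}"
        )
    bkg_mask = rois.background_mask()
    if not bkg_mask.any():
        raise ValueError("background region is empty; cannot correct ROI integrals")
    bkg = float(T.values[bkg_mask].mean())
    px_area = T.pixel_size**2
    rows = []
    for label in rois.roi_labels():
        mask = rois.labels == label
        npix = int(mask.sum())
        if npix == 0:
            warnings.warn(f"ROI {label} is empty; skipped", stacklevel=2)
            continue
        mean_t = float(T.values[mask].mean())
        area = npix * px_area
        rows.append(
            {
                "label": label,
                "area_um2": area,
                "mean_T": mean_t,
                "bkg_T": bkg,
                "integral_T": area * (mean_t - bkg),
            }
        )
    return pd.DataFrame(rows, columns=["label", "area_um2", "mean_T", "bkg_T", "integral_T"])
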