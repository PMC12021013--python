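"""Synthetic phantoms and forward models for the TIE/TTD pipeline.

Generates everything the pipeline consumes, with known ground truth:

* phase objects — spherical beads, spherical-cap "cells", Gaussian bumps;
* defocused brightfield pairs, by running the discrete TIE *forward*;
* dye-exclusion (TTD) images, by Beer-Lambert attenuation of a height map;
* half-ball-lens absorption images for alpha calibration.

The brightfield forward model is the discrete transport-of-intensity equation
itself (the same 5-point Laplacian the solver inverts), not a wave-optical
propagator: this makes the forward/inverse pair an exact identity (minus the
mean) at zero regularization, which is the central oracle for testing the
solver.  All stochastic output is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import LensGeometry, halfball_depth
from .phase_retrieval import DefocusPair, OpticalConfig, PhaseMap, discrete_laplacian
from .ttd_volumetry import HeightMap, TTDImage

__all__ = [
    "NoiseModel",
    "bead_phase_map",
    "cap_cell_height",
    "gaussian_phase",
    "phase_from_height",
    "forward_tie_pair",
    "ttd_image_from_height",
    "halfball_image",
]


@dataclass(frozen=True)
class NoiseModel:
    """Detection-noise model applied after image formation.

    ``gaussian`` adds multiplicative Gaussian noise with standard deviation
    ``sigma`` as a fraction of the local intensity (relative pixel noise
    dI/I); ``poisson`` draws shot noise with ``scale`` photoelectrons per
    count; ``none`` leaves the image untouched.
    """

    kind: str = "none"
    sigma: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0 or self.scale <= 0:
            raise ValueError("sigma must be >= 0 and scale positive")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "gaussian":
            return image * (1.0 + self.sigma * rng.standard_normal(image.shape))
        if self.kind == "poisson":
            return rng.poisson(np.maximum(image, 0.0) * self.scale) / self.scale
        return image


def _center_grid(shape: tuple[int, int], pixel_size: float, center=None):
    """Radial distance (um) of every pixel from the phantom center."""
    ny, nx = shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    yy, xx = np.indices(shape)
    return np.hypot(yy - center[0], xx - center[1]) * pixel_size


def bead_phase_map(
    diameter: float,
    delta_n: float,
    wavelength: float,
    pixel_size: float = 0.3,
    shape: tuple[int, int] = (256, 256),
    center: tuple[float, float] | None = None,
    edge_smooth_px: float = 0.0,
) -> PhaseMap:
    """Phase delay of a homogeneous sphere: phi = (2 pi/lambda) delta_n * chord.

    The chord thickness through a sphere of radius r at lateral distance rho
    is 2*sqrt(r^2 - rho^2); the phase peaks at (2 pi/lambda)*delta_n*d in the
    center and vanishes outside the bead.  The field integral equals
    (2 pi/lambda)*delta_n*(pi/6)*d^3 up to sampling error.

    ``edge_smooth_px`` optionally applies an integral-preserving Gaussian blur
    (in pixels) that models finite optical resolution and tames the sqrt-cusp
    at the rim, whose discrete Laplacian otherwise produces unphysically large
    defocus contrast.
    """
    radius = diameter / 2.0
    ny, nx = shape
    if diameter > min(ny, nx) * pixel_size:
        raise ValueError(
            f"bead diameter {diameter} um exceeds field extent "
            f"{min(ny, nx) * pixel_size} um"
        )
    rho = _center_grid(shape, pixel_size, center)
    chord = 2.0 * np.sqrt(np.maximum(radius**2 - rho**2, 0.0))
    phi = (2.0 * np.pi / wavelength) * delta_n * chord
    if edge_smooth_px > 0:
        phi = ndimage.gaussian_filter(phi, edge_smooth_px, mode="constant")
    return PhaseMap(values=phi, pixel_size=pixel_size)


def cap_cell_height(
    base_diameter: float,
    peak_height: float,
    pixel_size: float = 0.3,
    shape: tuple[int, int] = (256, 256),
    center: tuple[float, float] | None = None,
) -> HeightMap:
    """Height profile of a spherical-cap "cell" adherent to the substrate.

    A cap with footprint radius a = base_diameter/2 and apex height h0 is cut
    from a sphere of radius R = (a^2 + h0^2)/(2 h0); its analytic volume is
    pi*h0^2*(R - h0/3).
    """
    a = base_diameter / 2.0
    h0 = peak_height
    if a <= 0 or h0 <= 0:
        raise ValueError("base diameter and peak height must be positive")
    ny, nx = shape
    if base_diameter > min(ny, nx) * pixel_size:
        raise ValueError("cap footprint exceeds field extent")
    R = (a**2 + h0**2) / (2.0 * h0)
    rho = _center_grid(shape, pixel_size, center)
    h = np.sqrt(np.maximum(R**2 - rho**2, 0.0)) - (R - h0)
    h = np.where(rho <= a, np.maximum(h, 0.0), 0.0)
    return HeightMap(values=h, pixel_size=pixel_size)


def gaussian_phase(
    amplitude: float = 1.0,
    sigma_um: float = 6.0,
    pixel_size: float = 0.3,
    shape: tuple[int, int] = (256, 256),
    center: tuple[float, float] | None = None,
) -> PhaseMap:
    """Smooth Gaussian phase bump (default 1 rad peak, sigma 6 um)."""
    rho = _center_grid(shape, pixel_size, center)
    phi = amplitude * np.exp(-0.5 * (rho / sigma_um) ** 2)
    return PhaseMap(values=phi, pixel_size=pixel_size)


def phase_from_height(
    height: HeightMap, delta_n: float, wavelength: float
) -> PhaseMap:
    """Phase delay of a homogeneous object of known thickness: (2 pi/lambda) delta_n h."""
    phi = (2.0 * np.pi / wavelength) * delta_n * height.values
    return PhaseMap(values=phi, pixel_size=height.pixel_size)


def forward_tie_pair(
    phase: PhaseMap,
    base_intensity: float,
    config: OpticalConfig,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> DefocusPair:
    """Render a phase object into an over/under focused brightfield pair.

    Reads the TIE forward: the defocus contrast is

        c = -(lambda * dz' / (2 pi n_imm)) * laplacian(phi)

    and the planes are BF1 = I0*(1 + c/2), BF2 = I0*(1 - c/2), so their
    difference over mean reproduces the axial intensity derivative exactly on
    the discrete grid.  Any configured dark level is added back so the images
    behave like raw camera frames.
    """
    if base_intensity <= 0:
        raise ValueError("base_intensity must be positive")
    lap = discrete_laplacian(phase.values, phase.pixel_size)
    c = (
        -(config.wavelength * config.defocus_separation / (2.0 * np.pi * config.n_imm))
        * lap
    )
    cmax = float(np.abs(c).max())
    if cmax > 1.0:
        raise ValueError(
            f"unphysical defocus contrast |dI/I| = {cmax:.2f} > 1; reduce the "
            "defocus separation or smooth the phantom"
        )
    bf1 = base_intensity * (1.0 + 0.5 * c)
    bf2 = base_intensity * (1.0 - 0.5 * c)
    if noise is not None and noise.kind != "none":
        rng = np.random.default_rng(seed)
        bf1 = noise.apply(bf1, rng)
        bf2 = noise.apply(bf2, rng)
    return DefocusPair(
        bf_over=bf1 + config.dark_level,
        bf_under=bf2 + config.dark_level,
        config=config,
    )


def ttd_image_from_height(
    height: HeightMap,
    alpha: float,
    bkg_intensity: float,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> TTDImage:
    """Render a height field into a dye-exclusion image, I = I_bkg * exp(alpha h).

    The cell displaces the absorbing dye, so taller regions transmit more
    light and appear brighter; where h = 0 the intensity equals the
    background.  The true ln I_bkg is recorded on the returned image.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if bkg_intensity <= 0:
        raise ValueError("bkg_intensity must be positive")
    if (height.values < 0).any():
        raise ValueError("height field must be non-negative")
    img = bkg_intensity * np.exp(alpha * height.values)
    if noise is not None and noise.kind != "none":
        rng = np.random.default_rng(seed)
        img = noise.apply(img, rng)
    return TTDImage(
        intensity=img,
        pixel_size=height.pixel_size,
        background_log_intensity=float(np.log(bkg_intensity)),
        dark_level=0.0,
    )


def halfball_image(
    alpha: float,
    lens: LensGeometry,
    i0: float,
    pixel_size: float,
    shape: tuple[int, int] = (256, 256),
    center: tuple[float, float] | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Transmission image under a half-ball lens in dye, I(d) = i0 * exp(-alpha h(d)).

    Radially symmetric about the touch point; the center is brightest because
    the absorbing layer is thinnest there.  The whole image must lie within
    the lens footprint (d < R).
    """
    if alpha <= 0 or i0 <= 0:
        raise ValueError("alpha and i0 must be positive")
    d = _center_grid(shape, pixel_size, center)
    if d.max() >= lens.radius:
        raise ValueError(
            f"image extends to d = {d.max():.0f} um, beyond the lens radius "
            f"{lens.radius:.0f} um; use a smaller field or pixel size"
        )
    img = i0 * np.exp(-alpha * halfball_depth(d, lens))
    if noise is not None and noise.kind != "none":
        rng = np.random.default_rng(seed)
        img = noise.apply(img, rng)
    return img
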