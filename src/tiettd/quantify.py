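"""Fusion of TIE phase and TTD volume into protein concentration, water content and dry mass.

Protein mass concentration P relates linearly to the refractive index
elevation over water, delta_n = 0.185 * P (refractive increment 0.185 ml/g,
valid for most proteins and nucleic acids up to ~55% w/v), and to water
content as W = 1 - 0.7 * P.  Integrating the phase delay over the cell area
and dividing by the cell volume gives

    P = s * sum(delta_phi) / V,

where s is the calibrated TIE coefficient in um (ideally 0.86 * lambda).

Units are fixed to um / g/ml / pg throughout: 1 g/ml equals 1 pg/um^3, so
P [g/ml] times V [um^3] is directly the dry mass in pg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REFRACTIVE_INCREMENT",
    "SPECIFIC_VOLUME_COEFF",
    "PHASE_PREFACTOR",
    "CellQuantification",
    "protein_concentration",
    "water_content",
    "refractive_index_increment",
    "dry_mass",
    "quantify_rois",
]

#: Refractive increment of protein, ml/g.
REFRACTIVE_INCREMENT = 0.185
#: Partial specific volume coefficient relating W and P, ml/g.
SPECIFIC_VOLUME_COEFF = 0.7
#: Prefactor of the phase-to-concentration relation, 1/(2 pi * 0.185) = 0.86.
PHASE_PREFACTOR = 1.0 / (2.0 * np.pi * REFRACTIVE_INCREMENT)


@dataclass(frozen=True)
class CellQuantification:
    """Per-ROI quantification record."""

    roi_label: int
    area: float  # um^2
    volume: float  # um^3
    integrated_phase: float  # phase * um^2
    protein_concentration: float  # g/ml
    water_content: float  # fraction
    dry_mass: float  # pg
    delta_n: float  # dimensionless


def protein_concentration(integrated_phase: float, volume: float, s: float) -> float:
    """Protein concentration P = s * integrated_phase / V, in g/ml.

    ``integrated_phase`` is the background-corrected phase integral in
    phase*um^2, ``volume`` in um^3 and ``s`` the calibrated coefficient in um.
    Assumes negligible extracellular protein; otherwise the result is the
    concentration difference across the membrane.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if s <= 0:
        raise ValueError("calibration coefficient s must be positive")
    return s * integrated_phase / volume


def water_content(P: float) -> float:
    """Water volume fraction W = 1 - 0.7 * P.

    Warns (without clamping) when the result falls outside [0, 1], which
    signals an unphysical concentration estimate.
    """
    if P < 0:
        raise ValueError("protein concentration must be >= 0")
    W = 1.0 - SPECIFIC_VOLUME_COEFF * P
    if not (0.0 <= W <= 1.0):
        warnings.warn(f"water content {W:.3f} outside [0, 1]", stacklevel=2)
    return W


def refractive_index_increment(P: float) -> float:
    """Refractive index elevation over the solvent, delta_n = 0.185 * P."""
    if P < 0:
        raise ValueError("protein concentration must be >= 0")
    return REFRACTIVE_INCREMENT * P


def dry_mass(integrated_phase: float, wavelength: float) -> float:
    """Dry (protein) mass in pg from the integrated phase alone.

    mass = lambda/(2 pi 0.185) * integrated_phase; with matching s this
    equals protein_concentration * volume, but no volume measurement is
    needed — integrated phase is directly proportional to total protein mass.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return PHASE_PREFACTOR * wavelength * integrated_phase


def quantify_rois(
    phase_table: pd.DataFrame,
    volume_table: pd.DataFrame,
    s: float,
) -> pd.DataFrame:
    """Merge per-ROI phase integrals and volumes into full quantification rows.

    ``phase_table`` comes from :func:`tiettd.phase_retrieval.roi_integrated_phase`
    and ``volume_table`` from :func:`tiettd.ttd_volumetry.roi_volume`; rows are
    matched on ``label`` (identical label images on aligned crops).  Dry mass
    is computed as P*V so that it is consistent with the calibrated s.

    Returns
    -------
    DataFrame with columns ``roi_label``, ``area_um2``, ``volume_um3``,
    ``integral_T``, ``P_g_per_ml``, ``W``, ``dry_mass_pg``, ``delta_n``.
    """
    merged = phase_table.merge(volume_table, on="label", suffixes=("", "_ttd"))
    rows = []
    for rec in merged.itertuples(index=False):
        if rec.volume_um3 <= 0:
            warnings.warn(
                f"ROI {rec.label}: non-positive volume {rec.volume_um3:.3g} um^3; skipped",
                stacklevel=2,
            )
            continue
        P = protein_concentration(rec.integral_T, rec.volume_um3, s)
        rows.append(
            {
                "roi_label": int(rec.label),
                "area_um2": rec.area_um2,
                "volume_um3": rec.volume_um3,
                "integral_T": rec.integral_T,
                "P_g_per_ml": P,
                "W": water_content(max(P, 0.0)) if P >= 0 else 1.0 - SPECIFIC_VOLUME_COEFF * P,
                "dry_mass_pg": P * rec.volume_um3,
                "delta_n": REFRACTIVE_INCREMENT * P,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "roi_label",
            "area_um2",
            "volume_um3",
            "integral_T",
            "P_g_per_ml",
            "W",
            "dry_mass_pg",
            "delta_n",
        ],
    )
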