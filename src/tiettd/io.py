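"""Readers and writers: TIFF images, ROI label masks, configs, calibration JSON, CSV tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationFit
from .phase_retrieval import OpticalConfig, PhaseMap, RoiSet
from .ttd_volumetry import DyeSolution

__all__ = [
    "load_image",
    "save_image",
    "load_labels",
    "load_optical_config",
    "load_dye_config",
    "save_calibration",
    "load_calibration",
    "write_csv",
]

#: Fixed float format so repeated runs produce byte-identical CSVs.
CSV_FLOAT_FORMAT = "%.8g"


def load_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load a single-page grayscale TIFF (or PNG) as float64 without rescaling.

    Returns the image and a small metadata dict (dtype, shape, and pixel size
    if the TIFF resolution tags carry one).

    Raises
    ------
    ValueError
        For RGB or multi-page inputs; convert to single-channel grayscale
        (e.g. extract one channel) before processing.
    """
    path = Path(path)
    meta: dict = {}
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise ValueError(
                    f"{path.name}: multi-page TIFF not supported; "
                    "save each plane as its own file"
                )
            page = tif.pages[0]
            data = page.asarray()
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None and unit is not None and unit.value == 3:  # cm
                num, den = res.value
                if num:
                    meta["pixel_size_um"] = 1e4 * den / num
    else:
        data = iio.imread(path)
    if data.ndim == 3 and data.shape[-1] in (3, 4):
        raise ValueError(
            f"{path.name}: RGB image not supported; convert to grayscale first"
        )
    if data.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D grayscale image, got shape {data.shape}")
    meta["dtype"] = str(data.dtype)
    meta["shape"] = data.shape
    return data.astype(np.float64), meta


def save_image(path: str | Path, image: np.ndarray | PhaseMap) -> None:
    """Write an array or phase map as 32-bit float TIFF."""
    values = image.values if isinstance(image, PhaseMap) else np.asarray(image)
    tifffile.imwrite(Path(path), values.astype(np.float32))


def load_labels(path: str | Path, background_label: int = 0) -> RoiSet:
    """Load an integer label image (TIFF or PNG) as an ROI set."""
    data, _ = load_image(path)
    labels = np.rint(data).astype(np.int64)
    return RoiSet(labels=labels, background_label=background_label)


def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_optical_config(path: str | Path) -> OpticalConfig:
    """Load acquisition parameters from JSON/YAML.

    Expected keys: ``wavelength_um``, ``n_imm``, ``n_medium``, ``dz_um``,
    ``pixel_size_um``, ``dark_level`` (missing keys fall back to the
    OpticalConfig defaults).  An ``optical`` sub-mapping is honored so one
    file can hold the full run configuration.
    """
    cfg = _load_mapping(Path(path))
    if "optical" in cfg:
        cfg = cfg["optical"]
    return OpticalConfig(
        wavelength=float(cfg["wavelength_um"]),
        n_imm=float(cfg.get("n_imm", 1.0)),
        n_medium=float(cfg.get("n_medium", 1.33)),
        defocus_separation=float(cfg.get("dz_um", 1.0)),
        pixel_size=float(cfg.get("pixel_size_um", 0.3)),
        dark_level=float(cfg.get("dark_level", 0.0)),
    )


def load_dye_config(path: str | Path) -> DyeSolution:
    """Load dye parameters (``concentration_mg_ml``, ``alpha_um_inv``) from JSON/YAML."""
    cfg = _load_mapping(Path(path))
    if "dye" in cfg:
        cfg = cfg["dye"]
    return DyeSolution(
        concentration=float(cfg.get("concentration_mg_ml", 7.0)),
        absorption_coefficient=(
            float(cfg["alpha_um_inv"]) if cfg.get("alpha_um_inv") is not None else None
        ),
    )


def save_calibration(path: str | Path, fit: CalibrationFit) -> None:
    """Write a bead calibration to JSON (k/slope, g, s, r2, metadata)."""
    payload = asdict(fit)
    payload["k"] = fit.g  # Eq-14 style alias: response per unit (n_bead - n_oil)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_calibration(path: str | Path) -> CalibrationFit:
    payload = json.loads(Path(path).read_text())
    payload.pop("k", None)
    return CalibrationFit(**payload)


def write_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with a fixed float format (reproducible output)."""
    table.to_csv(Path(path), index=False, float_format=CSV_FLOAT_FORMAT)
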