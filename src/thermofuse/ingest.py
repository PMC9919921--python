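"""Thermal CSV ingestion and image intensification.

Infrared cameras export per-pixel surface temperatures (°C) as plain CSV,
one row per image row.  Structure-from-motion needs high-contrast grayscale
images, while raw thermograms of skin are nearly flat; this module converts
temperature grids to 8-bit intensity images and applies a configurable
"intensification" transform (percentile contrast stretch, gamma, optional
tile-based adaptive histogram equalization) that multiplies the number of
textured regions feature detectors can latch onto.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import exposure

logger = logging.getLogger(__name__)

__all__ = [
    "ThermalFrame",
    "IntensificationParams",
    "CsvDialect",
    "ThermalFormatError",
    "read_thermal_csv",
    "write_thermal_csv",
    "temperature_to_grayscale",
    "intensify",
    "write_intensity_png",
]


class ThermalFormatError(ValueError):
    """Raised when a thermal CSV export cannot be parsed."""


@dataclass(frozen=True)
class ThermalFrame:
    """A single thermogram: per-pixel surface temperature in °C."""

    temperatures: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
            raise ValueError(f"temperature grid must be 2D with shape >= (2, 2), got {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("temperature grid contains non-finite values")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        object.__setattr__(self, "temperatures", t)

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperatures.shape


@dataclass(frozen=True)
class CsvDialect:
    """Dialect of a per-pixel temperature CSV export.

    European exports commonly use ';' as delimiter and ',' as decimal mark;
    when the configured delimiter does not appear in the first data line and
    ';' does, the reader switches to the ';'/',' convention automatically.
    """

    delimiter: str = ","
    decimal_mark: str = "."
    skip_header_rows: int = 0


@dataclass(frozen=True)
class IntensificationParams:
    """Parameters of the contrast intensification transform.

    p_low/p_high are the stretch percentiles, gamma the exponent of the
    power-law mapping applied after the stretch, and ``local_equalize``
    enables CLAHE-style tile-based equalization with ``tile`` x ``tile``
    tiles across the image.
    """

    p_low: float = 2.0
    p_high: float = 98.0
    gamma: float = 1.0
    local_equalize: bool = True
    tile: int = 8

    def __post_init__(self) -> None:
        if not (0 <= self.p_low < self.p_high <= 100):
            raise ValueError(f"need 0 <= p_low < p_high <= 100, got ({self.p_low}, {self.p_high})")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.tile < 1:
            raise ValueError("tile must be a positive integer")


def read_thermal_csv(
    path: str | Path,
    dialect: CsvDialect | None = None,
    frame_index: int = 0,
) -> ThermalFrame:
    """Parse one per-pixel temperature CSV export into a ThermalFrame.

    Every data row must have the same number of cells; a ragged or
    unparseable file raises :class:`ThermalFormatError` naming the offending
    row/column.
    """
    path = Path(path)
    dialect = dialect or CsvDialect()
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    lines = lines[dialect.skip_header_rows :]
    if not lines:
        raise ThermalFormatError(f"{path}: no data rows")

    delim, decimal = dialect.delimiter, dialect.decimal_mark
    if delim == "," and decimal == "." and ";" in lines[0]:
        delim, decimal = ";", ","  # European export convention

    rows: list[list[float]] = []
    ncols: int | None = None
    for r, line in enumerate(lines):
        cells = line.split(delim)
        if ncols is None:
            ncols = len(cells)
        elif len(cells) != ncols:
            raise ThermalFormatError(
                f"{path}: ragged row {r}: expected {ncols} cells, got {len(cells)}"
            )
        parsed = []
        for c, cell in enumerate(cells):
            cell = cell.strip()
            if decimal != ".":
                cell = cell.replace(decimal, ".")
            try:
                parsed.append(float(cell))
            except ValueError as exc:
                raise ThermalFormatError(
                    f"{path}: cannot parse cell at row {r}, col {c}: {cell!r}"
                ) from exc
        rows.append(parsed)
    return ThermalFrame(np.array(rows, dtype=float), frame_index=frame_index)


def write_thermal_csv(frame: ThermalFrame, path: str | Path, dialect: CsvDialect | None = None) -> None:
    """Write a ThermalFrame in the same CSV convention the reader accepts."""
    dialect = dialect or CsvDialect()
    path = Path(path)
    with path.open("w") as fh:
        for row in frame.temperatures:
            cells = [format(v, ".17g") for v in row]  # bit-exact float round-trip
            if dialect.decimal_mark != ".":
                cells = [c.replace(".", dialect.decimal_mark) for c in cells]
            fh.write(dialect.delimiter.join(cells) + "\n")


def temperature_to_grayscale(
    frame: ThermalFrame, t_min: float | None = None, t_max: float | None = None
) -> np.ndarray:
    """Linearly map temperatures in [t_min, t_max] to 8-bit gray [0, 255].

    With t_min/t_max omitted the frame's own min/max are used (per-frame
    normalization); pass a fixed range for photometric consistency across a
    sequence.
    """
    t = frame.temperatures
    if t_min is None:
        t_min = float(t.min())
    if t_max is None:
        t_max = float(t.max())
    if t_min >= t_max:
        if t_min == t_max and t.min() == t.max():
            # constant frame: map to mid-gray
            return np.full(t.shape, 128, dtype=np.uint8)
        raise ValueError(f"t_min ({t_min}) must be < t_max ({t_max})")
    scaled = np.round(255.0 * (t - t_min) / (t_max - t_min))
    return np.clip(scaled, 0, 255).astype(np.uint8)


def intensify(image: np.ndarray, params: IntensificationParams | None = None) -> np.ndarray:
    """Contrast-intensify an 8-bit grayscale image.

    Percentile stretch to [p_low, p_high], power-law (gamma) mapping, then
    optional tile-based adaptive histogram equalization.  A degenerate image
    (single intensity) is returned unchanged with a warning: there is no
    contrast to stretch.
    """
    params = params or IntensificationParams()
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise TypeError("intensify expects an 8-bit grayscale image")
    lo = float(np.percentile(img, params.p_low))
    hi = float(np.percentile(img, params.p_high))
    if hi <= lo:
        lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        warnings.warn("degenerate (constant) image: intensification skipped", stacklevel=2)
        return img.copy()
    x = np.clip((img.astype(float) - lo) / (hi - lo), 0.0, 1.0)
    if params.gamma != 1.0:
        x = x**params.gamma
    if params.local_equalize:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x = exposure.equalize_adapthist(
                x, kernel_size=tuple(max(1, s // params.tile) for s in x.shape)
            )
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)


def write_intensity_png(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale image as lossless PNG (bit-exact round-trip)."""
    img = np.asarray(image)
    if img.dtype != np.uint8 or img.ndim != 2:
        raise ValueError("expected a 2D uint8 image")
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    iio.imwrite(path, img)
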