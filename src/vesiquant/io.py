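"""File I/O: multi-page 16-bit TIFF stacks and schema-checked CSV tables.

Image convention: page 0 = membrane dye, page 1 = reporter; a time-lapse is
one two-page block per time point.  Pixel size is stored in the TIFF
resolution tags (pixels per micrometre) and restored on read.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "write_image_stack",
    "read_image_stack",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def write_image_stack(path, planes, pixel_size_um: float) -> None:
    """Write planes (n, H, W) or (H, W) as multi-page 16-bit unsigned TIFF.

    Intensities are rounded and clipped to [0, 65535]; the pixel size is
    stored in the resolution tags with centimetre units.
    """
    arr = np.asarray(planes, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError("planes must be (H, W) or (n, H, W)")
    if pixel_size_um <= 0:
        raise FormatError("pixel_size_um must be positive")
    data = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    # exact rational so the pixel size survives the TIFF resolution tag
    px_per_cm = Fraction(10_000) / Fraction(pixel_size_um).limit_denominator(10**9)
    px_per_cm = (px_per_cm.numerator, px_per_cm.denominator)
    tifffile.imwrite(
        str(path),
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )


def read_image_stack(path) -> tuple[np.ndarray, float]:
    """Read a multi-page TIFF as float (n, H, W) plus the pixel size in um."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
    except tifffile.TiffFileError as exc:
        raise FormatError(f"malformed TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    pixel_size_um = float("nan")
    if res is not None:
        num, den = res.value
        px_per_unit = num / den
        if px_per_unit > 0:
            unit_val = getattr(unit, "value", None)
            unit_um = {2: 25_400.0, 3: 10_000.0}.get(
                int(unit_val) if unit_val is not None else 3, 10_000.0
            )
            pixel_size_um = unit_um / px_per_unit
    return data.astype(float), pixel_size_um


def write_table(path, frame: pd.DataFrame) -> None:
    """Write a DataFrame as a headered CSV without the index."""
    frame.to_csv(path, index=False)


def read_table(path, required_columns=None) -> pd.DataFrame:
    """Read a headered CSV, checking that required columns are present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"malformed CSV {path}: {exc}") from exc
    if required_columns:
        missing = [c for c in required_columns if c not in frame.columns]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
    return frame
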