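"""Membrane fluorescence quantification by radial rays and line profiles.

The automated readout casts rays from each vesicle centroid outward to
1.5x the vesicle radius along 63 equally spaced angles, samples the reporter
channel by bilinear interpolation at 0.5 px steps, records each ray's
maximum (the membrane crossing) and averages the per-ray maxima.  The
manual readout extracts a straight-line cross-section through a vesicle and
accepts it only if it shows exactly two membrane peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import VesicleDetection

__all__ = [
    "ImagePlane",
    "MembraneIntensityRecord",
    "LineProfile",
    "TwoPeakResult",
    "ProfilingError",
    "radial_membrane_intensity",
    "extract_line_profile",
    "two_peak_membrane_intensity",
]


class ProfilingError(RuntimeError):
    """Raised when a vesicle cannot be profiled (e.g. all rays leave the image)."""


@dataclass(frozen=True)
class ImagePlane:
    """A single-channel image: nonnegative finite intensities plus pixel size."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("ImagePlane.values must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite pixels")
        if np.any(v < 0):
            raise ValueError("image contains negative intensities")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class MembraneIntensityRecord:
    """Averaged membrane-crossing intensity for one vesicle."""

    vesicle_id: int
    mean_membrane_intensity: float
    n_rays_used: int
    per_ray_max: tuple[float, ...] | None = None


@dataclass(frozen=True)
class LineProfile:
    """Intensity samples along a straight segment; positions in um from p0."""

    positions: np.ndarray
    intensities: np.ndarray
    channel: str = "reporter"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.shape != inten.shape or pos.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1-D")
        if pos.size >= 2 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class TwoPeakResult:
    """Outcome of the two-peak cross-section readout.

    ``mean_peak_intensity`` is set only when exactly two peaks were found;
    otherwise the profile is discarded and ``peak_count`` says why.
    """

    mean_peak_intensity: float | None
    peak_count: int
    discarded: bool


def radial_membrane_intensity(
    reporter: ImagePlane,
    det: "VesicleDetection",
    n_angles: int = 63,
    extent_factor: float = 1.5,
    step_px: float = 0.5,
    use_interpolation: bool = True,
) -> MembraneIntensityRecord:
    """Mean of per-ray maximum reporter intensities around one vesicle.

    Rays start at the centroid and extend to ``extent_factor * radius_px``
    along ``n_angles`` equally spaced angles starting at 0 rad.  Rays with
    any sample outside the image are dropped (and reflected in
    ``n_rays_used``); if every ray exits, a :class:`ProfilingError` is
    raised.  With ``use_interpolation=False`` samples are nearest-pixel
    values instead of bilinear.
    """
    if n_angles < 3:
        raise ValueError("n_angles must be >= 3")
    if extent_factor <= 0 or step_px <= 0:
        raise ValueError("extent_factor and step_px must be positive")
    values = reporter.values
    h, w = values.shape
    cy, cx = det.centroid_row_px, det.centroid_col_px
    extent = extent_factor * det.radius_px
    radii = np.arange(0, extent + step_px, step_px)
    radii = radii[radii <= extent]
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)

    rows = cy + radii[None, :] * np.sin(angles)[:, None]
    cols = cx + radii[None, :] * np.cos(angles)[:, None]
    ray_ok = np.all(
        (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1), axis=1
    )
    if not np.any(ray_ok):
        raise ProfilingError(
            f"all {n_angles} rays exit the image for vesicle {det.id}"
        )
    order = 1 if use_interpolation else 0
    samples = ndimage.map_coordinates(
        values, [rows[ray_ok].ravel(), cols[ray_ok].ravel()], order=order
    ).reshape(int(ray_ok.sum()), radii.size)
    per_ray_max = samples.max(axis=1)
    return MembraneIntensityRecord(
        vesicle_id=det.id,
        mean_membrane_intensity=float(per_ray_max.mean()),
        n_rays_used=int(ray_ok.sum()),
        per_ray_max=tuple(float(x) for x in per_ray_max),
    )


def extract_line_profile(
    plane: ImagePlane,
    p0: tuple[float, float],
    p1: tuple[float, float],
    step_px: float = 0.5,
    channel: str = "reporter",
) -> LineProfile:
    """Bilinear-interpolated intensity profile along the segment p0 -> p1.

    Endpoints are (row, col) pixel coordinates and must lie inside the
    image; positions are reported in um from ``p0``.
    """
    if step_px <= 0:
        raise ValueError("step_px must be positive")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    h, w = plane.values.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError("profile endpoints must lie inside the image")
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("zero-length segment")
    n = int(np.floor(length / step_px)) + 1
    dist = np.arange(n) * step_px
    frac = dist / length
    rows = p0[0] + frac * (p1[0] - p0[0])
    cols = p0[1] + frac * (p1[1] - p0[1])
    samples = ndimage.map_coordinates(plane.values, [rows, cols], order=1)
    return LineProfile(
        positions=dist * plane.pixel_size_um,
        intensities=samples,
        channel=channel,
    )


def two_peak_membrane_intensity(
    profile: LineProfile,
    min_prominence: float,
    min_separation_um: float,
) -> TwoPeakResult:
    """Mean of the two membrane-crossing peaks of a cross-section profile.

    Local maxima with prominence >= ``min_prominence`` and pairwise
    separation >= ``min_separation_um`` are counted; a profile with any
    number of peaks other than two is discarded (a verdict, not an error).
    """
    if min_prominence < 0 or min_separation_um < 0:
        raise ValueError("prominence and separation must be >= 0")
    pos = profile.positions
    if pos.size < 3:
        return TwoPeakResult(None, 0, True)
    spacing = float(np.median(np.diff(pos)))
    distance = max(1, int(round(min_separation_um / spacing))) if spacing > 0 else 1
    peaks, _ = find_peaks(
        profile.intensities, prominence=min_prominence or None, distance=distance
    )
    if peaks.size != 2:
        return TwoPeakResult(None, int(peaks.size), True)
    mean = float(profile.intensities[peaks].mean())
    return TwoPeakResult(mean, 2, False)
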