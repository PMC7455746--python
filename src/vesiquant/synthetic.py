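"""Synthetic image, kinetic-trace and targeted-MS data generators.

Every downstream stage of the pipeline (segmentation, membrane profiling,
enrichment statistics, kinetics, MS quantification) can be exercised against
data generated here, with a ground-truth table alongside each artifact.  The
generators are pure functions of their spec (the seed is part of the spec),
so two calls with identical specs produce identical output.

The image model is an equatorially sectioned giant vesicle: the membrane dye
appears as a ring whose radial cross-section is Gaussian,

    I(d) = A * exp(-(d - r)^2 / (2 sigma^2)),

optionally convolved with a Gaussian PSF, with Poisson shot noise and
additive Gaussian read noise on top.  Reporter rings are the same geometry
scaled by a per-vesicle reporter intensity; a configurable fraction of
vesicles is "enriched" with lognormally distributed ring amplitudes (the
rest stay at background), emulating the wide, long-tailed single-vesicle
reporter distributions seen in heterogeneous lipid-synthesis populations.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImageSpec",
    "TraceSpec",
    "MSSpec",
    "PlacementError",
    "generate_vesicle_image",
    "generate_kinetic_traces",
    "generate_ms_tables",
    "logistic",
]

GROUND_TRUTH_COLUMNS = [
    "id",
    "centroid_row_px",
    "centroid_col_px",
    "radius_um",
    "true_membrane_reporter_intensity",
    "enriched",
]

TRACE_COLUMNS = ["liposome_id", "time_min", "intensity"]

TRACE_TRUTH_COLUMNS = [
    "liposome_id",
    "responder",
    "baseline",
    "amplitude",
    "rate_per_min",
    "midpoint_min",
    "max_rate_au_per_min",
    "plateau_time_h",
]

PEAK_TABLE_COLUMNS = [
    "sample_id",
    "transition_id",
    "injection",
    "counts",
    "block",
    "concentration_uM",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping vesicle placement cannot be satisfied."""


@dataclass(frozen=True)
class ImageSpec:
    """Parameters for one synthetic two-channel vesicle image.

    Defaults describe a confocal field of giant vesicles at 0.2 um/px with
    apparent diameters of 4-12 um, a diffraction-limited ring cross-section,
    and roughly half the population enriched in reporter signal.
    """

    height_px: int = 512
    width_px: int = 512
    pixel_size_um: float = 0.2
    n_vesicles: int = 10
    radius_range_um: tuple[float, float] = (2.0, 6.0)
    ring_sigma_um: float = 0.15
    membrane_peak_intensity: float = 2000.0
    reporter_enriched_fraction: float = 0.5
    reporter_lognormal_mu: float = math.log(800.0)
    reporter_lognormal_sigma: float = 0.8
    reporter_background_intensity: float = 100.0
    psf_sigma_um: float = 0.1
    read_noise_sigma: float = 5.0
    shot_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_vesicles < 0:
            raise ValueError("n_vesicles must be nonnegative")
        rmin, rmax = self.radius_range_um
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range_um must be positive with min <= max")
        if self.ring_sigma_um <= 0:
            raise ValueError("ring_sigma_um must be positive")
        if rmin < 2 * self.ring_sigma_um:
            raise ValueError("min radius must be >= 2x ring_sigma_um")
        if not 0 <= self.reporter_enriched_fraction <= 1:
            raise ValueError("reporter_enriched_fraction must be in [0, 1]")
        if self.membrane_peak_intensity <= 0:
            raise ValueError("membrane_peak_intensity must be positive")
        if self.reporter_background_intensity < 0:
            raise ValueError("reporter_background_intensity must be >= 0")
        if self.psf_sigma_um < 0 or self.read_noise_sigma < 0:
            raise ValueError("psf_sigma_um and read_noise_sigma must be >= 0")


@dataclass(frozen=True)
class TraceSpec:
    """Parameters for a cohort of single-liposome reporter-recruitment traces.

    Responder traces follow a four-parameter logistic in time; non-responders
    stay at baseline.  Amplitude, steepness and midpoint are drawn per
    liposome from lognormal distributions parameterised by mean and SD on
    the natural scale, so all draws are positive.  The defaults describe an
    overnight (16 h) time-lapse sampled every 15 min with plateaus around
    4-6 h and maximum recruitment rates of a few a.u. per minute.
    """

    n_liposomes: int = 50
    time_points_min: tuple[float, ...] = tuple(float(t) for t in range(0, 961, 15))
    baseline: float = 100.0
    amplitude_mean: float = 400.0
    amplitude_sd: float = 150.0
    rate_mean_per_min: float = 0.05
    rate_sd_per_min: float = 0.02
    midpoint_mean_min: float = 240.0
    midpoint_sd_min: float = 90.0
    trace_noise_sigma: float = 10.0
    nonresponder_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_liposomes <= 0:
            raise ValueError("n_liposomes must be positive")
        t = np.asarray(self.time_points_min, dtype=float)
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("time_points_min must be strictly increasing")
        if self.trace_noise_sigma < 0:
            raise ValueError("trace_noise_sigma must be >= 0")
        if not 0 <= self.nonresponder_fraction <= 1:
            raise ValueError("nonresponder_fraction must be in [0, 1]")
        for name in ("amplitude_mean", "rate_mean_per_min", "midpoint_mean_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("amplitude_sd", "rate_sd_per_min", "midpoint_sd_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MSSpec:
    """Parameters for synthetic targeted-MS peak tables.

    Detector response is linear in concentration (``counts = slope * conc +
    intercept``) with multiplicative lognormal noise of fixed coefficient of
    variation.  A calibration dilution series is emitted twice (``pre`` and
    ``post`` blocks, bracketing the sample acquisition) and every (sample,
    transition) pair is injected ``injections_per_sample`` times.
    """

    species: tuple[str, ...] = ("DOPE", "DOPG")
    true_concentrations_uM: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"reaction_1": {"DOPE": 12.0, "DOPG": 8.0}}
    )
    calibration_levels_uM: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    calibration_slope_counts_per_uM: float = 1000.0
    calibration_intercept_counts: float = 50.0
    injections_per_sample: int = 2
    count_noise_cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.calibration_levels_uM)) < 2:
            raise ValueError("need >= 2 distinct calibration levels")
        if any(l < 0 for l in self.calibration_levels_uM):
            raise ValueError("calibration levels must be >= 0")
        if self.injections_per_sample < 1:
            raise ValueError("injections_per_sample must be >= 1")
        if self.count_noise_cv < 0:
            raise ValueError("count_noise_cv must be >= 0")
        for sample, per_species in self.true_concentrations_uM.items():
            for sp, conc in per_species.items():
                if sp not in self.species:
                    raise ValueError(f"sample {sample!r} references unknown species {sp!r}")
                if conc < 0:
                    raise ValueError("concentrations must be >= 0")


def render_ring(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius_px: float,
    sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    """Render one Gaussian-cross-section ring into a fresh float image.

    The intensity at distance d from ``center`` is
    ``amplitude * exp(-(d - radius_px)^2 / (2 sigma_px^2))``.
    """
    out = np.zeros(shape, dtype=float)
    pad = int(math.ceil(radius_px + 5 * sigma_px))
    r0 = max(0, int(math.floor(center[0])) - pad)
    r1 = min(shape[0], int(math.ceil(center[0])) + pad + 1)
    c0 = max(0, int(math.floor(center[1])) - pad)
    c1 = min(shape[1], int(math.ceil(center[1])) + pad + 1)
    if r0 >= r1 or c0 >= c1:
        return out
    rows = np.arange(r0, r1, dtype=float)[:, None]
    cols = np.arange(c0, c1, dtype=float)[None, :]
    d = np.hypot(rows - center[0], cols - center[1])
    out[r0:r1, c0:c1] = amplitude * np.exp(-((d - radius_px) ** 2) / (2 * sigma_px**2))
    return out


def _place_centers(
    spec: ImageSpec, radii_px: np.ndarray, sigma_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample non-overlapping centers away from the image border."""
    centers = np.empty((len(radii_px), 2), dtype=float)
    max_attempts = 2000
    for i, r in enumerate(radii_px):
        margin = r + 3 * sigma_px
        lo_row, hi_row = margin, spec.height_px - 1 - margin
        lo_col, hi_col = margin, spec.width_px - 1 - margin
        if lo_row >= hi_row or lo_col >= hi_col:
            raise PlacementError(
                f"vesicle radius {r:.1f} px plus border margin {margin:.1f} px "
                f"does not fit in a {spec.height_px}x{spec.width_px} image"
            )
        for _ in range(max_attempts):
            cand = np.array(
                [rng.uniform(lo_row, hi_row), rng.uniform(lo_col, hi_col)]
            )
            prev = centers[:i]
            if i == 0:
                centers[i] = cand
                break
            dist = np.hypot(prev[:, 0] - cand[0], prev[:, 1] - cand[1])
            if np.all(dist >= radii_px[:i] + r + 6 * sigma_px):
                centers[i] = cand
                break
        else:
            raise PlacementError(
                f"could not place vesicle {i} without ring overlap after "
                f"{max_attempts} attempts (non-overlap constraint)"
            )
    return centers


def generate_vesicle_image(
    spec: ImageSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate a (membrane, reporter) image pair plus a ground-truth table.

    Returns
    -------
    membrane, reporter : float64 arrays of shape (height_px, width_px)
        Membrane-dye and reporter channels, nonnegative a.u.
    truth : DataFrame
        One row per vesicle with columns ``GROUND_TRUTH_COLUMNS``;
        ``true_membrane_reporter_intensity`` is the noise-free, unblurred
        reporter intensity at the ring peak (ring amplitude + uniform
        background).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)
    sigma_px = spec.ring_sigma_um / spec.pixel_size_um

    radii_um = rng.uniform(*spec.radius_range_um, size=spec.n_vesicles)
    radii_px = radii_um / spec.pixel_size_um
    enriched = rng.random(spec.n_vesicles) < spec.reporter_enriched_fraction
    ring_amplitudes = np.where(
        enriched,
        rng.lognormal(
            spec.reporter_lognormal_mu,
            spec.reporter_lognormal_sigma,
            size=spec.n_vesicles,
        ),
        0.0,
    )
    centers = (
        _place_centers(spec, radii_px, sigma_px, rng)
        if spec.n_vesicles
        else np.empty((0, 2))
    )

    membrane = np.zeros(shape, dtype=float)
    reporter = np.full(shape, spec.reporter_background_intensity, dtype=float)
    for i in range(spec.n_vesicles):
        ring = render_ring(shape, tuple(centers[i]), radii_px[i], sigma_px, 1.0)
        membrane += spec.membrane_peak_intensity * ring
        reporter += ring_amplitudes[i] * ring

    psf_px = spec.psf_sigma_um / spec.pixel_size_um
    if psf_px > 0:
        membrane = gaussian_filter(membrane, psf_px)
        reporter = gaussian_filter(reporter, psf_px)

    if spec.shot_noise:
        membrane = rng.poisson(np.clip(membrane, 0, None)).astype(float)
        reporter = rng.poisson(np.clip(reporter, 0, None)).astype(float)
    if spec.read_noise_sigma > 0:
        membrane = membrane + rng.normal(0, spec.read_noise_sigma, shape)
        reporter = reporter + rng.normal(0, spec.read_noise_sigma, shape)
    membrane = np.clip(membrane, 0, None)
    reporter = np.clip(reporter, 0, None)

    truth = pd.DataFrame(
        {
            "id": np.arange(spec.n_vesicles, dtype=int),
            "centroid_row_px": centers[:, 0],
            "centroid_col_px": centers[:, 1],
            "radius_um": radii_um,
            "true_membrane_reporter_intensity": ring_amplitudes
            + spec.reporter_background_intensity,
            "enriched": enriched,
        },
        columns=GROUND_TRUTH_COLUMNS,
    )
    return membrane, reporter, truth


def logistic(
    t: np.ndarray | float,
    baseline: float,
    amplitude: float,
    rate: float,
    midpoint: float,
) -> np.ndarray | float:
    """Four-parameter logistic: baseline + amplitude / (1 + exp(-rate*(t - midpoint)))."""
    from scipy.special import expit

    t = np.asarray(t, dtype=float)
    return baseline + amplitude * expit(rate * (t - midpoint))


def _lognormal_from_mean_sd(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draw lognormal values with the given natural-scale mean and SD."""
    if sd == 0:
        return np.full(size, mean)
    sigma2 = math.log(1 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def generate_kinetic_traces(spec: TraceSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate single-liposome recruitment traces and their true parameters.

    Returns a long-format trace table (``TRACE_COLUMNS``) and a truth table
    (``TRACE_TRUTH_COLUMNS``).  ``max_rate_au_per_min`` is the logistic's
    maximum slope amplitude*rate/4; ``plateau_time_h`` is the time at which
    the noise-free curve reaches 95% of its amplitude,
    midpoint + ln(19)/rate, in hours.  Non-responder rows carry NaN
    parameters apart from the baseline.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.time_points_min, dtype=float)
    n = spec.n_liposomes

    responder = rng.random(n) >= spec.nonresponder_fraction
    amplitude = _lognormal_from_mean_sd(rng, spec.amplitude_mean, spec.amplitude_sd, n)
    rate = _lognormal_from_mean_sd(rng, spec.rate_mean_per_min, spec.rate_sd_per_min, n)
    midpoint = _lognormal_from_mean_sd(
        rng, spec.midpoint_mean_min, spec.midpoint_sd_min, n
    )

    trace_rows = []
    truth_rows = []
    for i in range(n):
        if responder[i]:
            clean = logistic(t, spec.baseline, amplitude[i], rate[i], midpoint[i])
            truth_rows.append(
                {
                    "liposome_id": i,
                    "responder": True,
                    "baseline": spec.baseline,
                    "amplitude": amplitude[i],
                    "rate_per_min": rate[i],
                    "midpoint_min": midpoint[i],
                    "max_rate_au_per_min": amplitude[i] * rate[i] / 4.0,
                    "plateau_time_h": (midpoint[i] + math.log(19.0) / rate[i]) / 60.0,
                }
            )
        else:
            clean = np.full_like(t, spec.baseline)
            truth_rows.append(
                {
                    "liposome_id": i,
                    "responder": False,
                    "baseline": spec.baseline,
                    "amplitude": np.nan,
                    "rate_per_min": np.nan,
                    "midpoint_min": np.nan,
                    "max_rate_au_per_min": np.nan,
                    "plateau_time_h": np.nan,
                }
            )
        noisy = clean + rng.normal(0, spec.trace_noise_sigma, size=t.size)
        trace_rows.append(
            pd.DataFrame(
                {"liposome_id": i, "time_min": t, "intensity": noisy},
                columns=TRACE_COLUMNS,
            )
        )
    traces = pd.concat(trace_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=TRACE_TRUTH_COLUMNS)
    return traces, truth


def generate_ms_tables(
    spec: MSSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate calibration and sample peak tables plus truth concentrations.

    Returns
    -------
    calibration : DataFrame
        ``PEAK_TABLE_COLUMNS`` rows for the dilution series, one full series
        per block (``pre`` and ``post``), ``injections_per_sample``
        injections per level and species.
    samples : DataFrame
        Same schema for the unknown samples (``block = "sample"``, truth
        concentration column included for provenance only).
    truth : DataFrame
        (sample_id, transition_id, concentration_uM) tidy truth table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    cv = spec.count_noise_cv
    if cv > 0:
        sigma2 = math.log(1 + cv**2)
        noise_mu, noise_sigma = -sigma2 / 2, math.sqrt(sigma2)

    def noisy_counts(conc: float, size: int) -> np.ndarray:
        clean = (
            spec.calibration_slope_counts_per_uM * conc
            + spec.calibration_intercept_counts
        )
        if cv == 0:
            return np.full(size, float(clean))
        return clean * rng.lognormal(noise_mu, noise_sigma, size=size)

    cal_rows = []
    for block in ("pre", "post"):
        for level_idx, conc in enumerate(spec.calibration_levels_uM):
            for sp in spec.species:
                counts = noisy_counts(conc, spec.injections_per_sample)
                for inj in range(1, spec.injections_per_sample + 1):
                    cal_rows.append(
                        {
                            "sample_id": f"cal_{block}_L{level_idx}",
                            "transition_id": sp,
                            "injection": inj,
                            "counts": counts[inj - 1],
                            "block": block,
                            "concentration_uM": conc,
                        }
                    )
    calibration = pd.DataFrame(cal_rows, columns=PEAK_TABLE_COLUMNS)

    sample_rows = []
    truth_rows = []
    for sample_id, per_species in spec.true_concentrations_uM.items():
        for sp, conc in per_species.items():
            truth_rows.append(
                {"sample_id": sample_id, "transition_id": sp, "concentration_uM": conc}
            )
            counts = noisy_counts(conc, spec.injections_per_sample)
            for inj in range(1, spec.injections_per_sample + 1):
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "transition_id": sp,
                        "injection": inj,
                        "counts": counts[inj - 1],
                        "block": "sample",
                        "concentration_uM": conc,
                    }
                )
    samples = pd.DataFrame(sample_rows, columns=PEAK_TABLE_COLUMNS)
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "transition_id", "concentration_uM"]
    )
    return calibration, samples, truth


def spec_with(spec, **overrides):
    """Return a copy of a frozen spec dataclass with fields replaced."""
    return dataclasses.replace(spec, **overrides)
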