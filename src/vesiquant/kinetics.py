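"""Single-liposome recruitment kinetics and apparent-radius change.

Reporter recruitment to a synthesizing liposome's membrane follows a
sigmoidal time course; each trace is fitted with a four-parameter logistic

    I(t) = baseline + amplitude / (1 + exp(-k (t - t0))).

Two derived quantities summarise a fit: the maximum recruitment rate
amplitude*k/4 (the logistic's slope at its midpoint, in a.u. per minute)
and the plateau time t0 + ln(19)/k (when the fitted curve reaches 95% of
its amplitude), reported in hours.  A trace is a responder when the fit
converged and its amplitude exceeds three times the residual RMS.

Fitting uses deterministic multi-start least squares: 8 starting points on
a (k, t0) grid spanning the observation window, refined with
``scipy.optimize.least_squares``; no randomness is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .synthetic import logistic

__all__ = [
    "KineticTrace",
    "KineticFit",
    "fit_sigmoid",
    "fit_cohort",
    "radius_change",
    "link_timepoints",
]

FIT_COLUMNS = [
    "vesicle_id",
    "converged",
    "responder",
    "baseline",
    "amplitude",
    "rate_per_min",
    "midpoint_min",
    "max_rate_au_per_min",
    "plateau_time_h",
    "residual_rms",
]


@dataclass(frozen=True)
class KineticTrace:
    """Time series of membrane reporter intensity for one liposome."""

    vesicle_id: int
    times_min: np.ndarray
    intensities: np.ndarray
    apparent_radius_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "intensities", i)
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.apparent_radius_um is not None:
            r = np.asarray(self.apparent_radius_um, dtype=float)
            object.__setattr__(self, "apparent_radius_um", r)
            if r.shape != t.shape:
                raise ValueError("apparent_radius_um must match times in length")


@dataclass(frozen=True)
class KineticFit:
    """Logistic fit summary; parameters are None when the fit failed."""

    vesicle_id: int
    converged: bool
    responder: bool
    baseline: float | None
    amplitude: float | None
    rate_per_min: float | None
    midpoint_min: float | None
    max_rate_au_per_min: float | None
    plateau_time_h: float | None
    residual_rms: float | None


def _fit_once(
    t: np.ndarray, y: np.ndarray, x0: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    def resid(p):
        return logistic(t, *p) - y

    span = max(y.max() - y.min(), 1e-12)
    lb = [y.min() - 2 * span, 0.0, 1e-6, t[0] - (t[-1] - t[0])]
    ub = [y.max() + 2 * span, 10 * span + 1e-9, 10.0, t[-1] + (t[-1] - t[0])]
    x0 = np.clip(x0, lb, ub)
    try:
        res = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-12)
    except Exception:
        return x0, np.inf, False
    cost = float(np.sqrt(2 * res.cost / t.size))
    return res.x, cost, bool(res.success)


def fit_sigmoid(trace: KineticTrace) -> KineticFit:
    """Fit the four-parameter logistic to one trace.

    Non-convergence from every start yields ``converged=False`` with absent
    parameters, not an exception.
    """
    t, y = trace.times_min, trace.intensities
    if t.size < 5:
        raise ValueError("need >= 5 time points to fit")
    baseline0 = float(np.median(y[: max(2, t.size // 10)]))
    amp0 = max(float(y.max() - baseline0), 1e-9)
    t_span = t[-1] - t[0]
    # 8 deterministic starts: 4 midpoints x 2 steepnesses
    starts = [
        np.array([baseline0, amp0, k0, t0])
        for t0 in np.linspace(t[0] + 0.2 * t_span, t[0] + 0.8 * t_span, 4)
        for k0 in (2.0 / t_span * 4, 20.0 / t_span * 4)
    ]
    best = None
    for x0 in starts:
        params, rms, ok = _fit_once(t, y, x0)
        if ok and (best is None or rms < best[1]):
            best = (params, rms)
    if best is None:
        return KineticFit(trace.vesicle_id, False, False, *(None,) * 7)
    (b, a, k, t0), rms = best
    responder = a > 3 * rms
    return KineticFit(
        vesicle_id=trace.vesicle_id,
        converged=True,
        responder=bool(responder),
        baseline=float(b),
        amplitude=float(a),
        rate_per_min=float(k),
        midpoint_min=float(t0),
        max_rate_au_per_min=float(a * k / 4.0),
        plateau_time_h=float((t0 + math.log(19.0) / k) / 60.0),
        residual_rms=float(rms),
    )


def fit_cohort(traces: pd.DataFrame) -> pd.DataFrame:
    """Fit every liposome in a long-format trace table.

    Expects columns ``liposome_id``, ``time_min``, ``intensity``; returns
    one row per liposome with columns ``FIT_COLUMNS``.
    """
    rows = []
    for lid, grp in traces.groupby("liposome_id", sort=True):
        grp = grp.sort_values("time_min")
        fit = fit_sigmoid(
            KineticTrace(int(lid), grp["time_min"].to_numpy(), grp["intensity"].to_numpy())
        )
        rows.append(
            {
                "vesicle_id": fit.vesicle_id,
                "converged": fit.converged,
                "responder": fit.responder,
                "baseline": fit.baseline,
                "amplitude": fit.amplitude,
                "rate_per_min": fit.rate_per_min,
                "midpoint_min": fit.midpoint_min,
                "max_rate_au_per_min": fit.max_rate_au_per_min,
                "plateau_time_h": fit.plateau_time_h,
                "residual_rms": fit.residual_rms,
            }
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def radius_change(
    traces: list[KineticTrace], bin_width_um: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-vesicle apparent-radius change and its probability histogram.

    Delta r = r(last) - r(first) in um for every trace with radii at both
    endpoints; traces missing either endpoint are skipped (with the reason
    recorded).  The histogram uses ``bin_width_um`` bins centered on 0 and
    is normalized so the masses sum to 1.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    rows = []
    for tr in traces:
        r = tr.apparent_radius_um
        if r is None or not np.isfinite(r[0]) or not np.isfinite(r[-1]):
            rows.append(
                {"vesicle_id": tr.vesicle_id, "delta_r_um": np.nan,
                 "skipped": True, "reason": "missing endpoint radius"}
            )
            continue
        rows.append(
            {"vesicle_id": tr.vesicle_id, "delta_r_um": float(r[-1] - r[0]),
             "skipped": False, "reason": ""}
        )
    per_vesicle = pd.DataFrame(
        rows, columns=["vesicle_id", "delta_r_um", "skipped", "reason"]
    )
    dr = per_vesicle.loc[~per_vesicle["skipped"], "delta_r_um"].to_numpy()
    if dr.size:
        # bins centered on 0: edges at (k + 0.5) * width
        kmax = int(np.ceil((np.abs(dr).max() + bin_width_um) / bin_width_um))
        edges = (np.arange(-kmax, kmax + 1) + 0.5) * bin_width_um
        counts, _ = np.histogram(dr, bins=edges)
        mass = counts / counts.sum()
        hist = pd.DataFrame(
            {
                "bin_center_um": (edges[:-1] + edges[1:]) / 2,
                "probability": mass,
            }
        )
    else:
        hist = pd.DataFrame({"bin_center_um": [], "probability": []})
    return per_vesicle, hist


def link_timepoints(
    detections_a: pd.DataFrame,
    detections_b: pd.DataFrame,
    max_shift_um: float,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Match vesicles between two time points by mutual nearest centroid.

    Both inputs are detection tables (``id``, ``centroid_row_px``,
    ``centroid_col_px``) from the same immobilized field of view.  A pair is
    linked when each is the other's nearest neighbour and their separation
    is at most ``max_shift_um``.  Returns a table with ``id_a``, ``id_b``
    (nullable Int64; unmatched vesicles appear with the other id missing).
    """
    if max_shift_um < 0:
        raise ValueError("max_shift_um must be >= 0")
    pa = detections_a[["centroid_row_px", "centroid_col_px"]].to_numpy() * pixel_size_um
    pb = detections_b[["centroid_row_px", "centroid_col_px"]].to_numpy() * pixel_size_um
    ids_a = detections_a["id"].to_numpy()
    ids_b = detections_b["id"].to_numpy()
    links: list[tuple[object, object]] = []
    matched_a, matched_b = set(), set()
    if len(pa) and len(pb):
        tree_a, tree_b = cKDTree(pa), cKDTree(pb)
        d_ab, j_ab = tree_b.query(pa)
        d_ba, j_ba = tree_a.query(pb)
        for i in range(len(pa)):
            j = int(j_ab[i])
            if d_ab[i] <= max_shift_um and int(j_ba[j]) == i:
                links.append((ids_a[i], ids_b[j]))
                matched_a.add(i)
                matched_b.add(j)
    for i in range(len(pa)):
        if i not in matched_a:
            links.append((ids_a[i], None))
    for j in range(len(pb)):
        if j not in matched_b:
            links.append((None, ids_b[j]))
    return pd.DataFrame(links, columns=["id_a", "id_b"]).astype(
        {"id_a": "Int64", "id_b": "Int64"}
    )
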