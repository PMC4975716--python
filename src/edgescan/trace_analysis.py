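"""Knife-edge line-scan analysis: from a raw intensity trace to a 1/e^2 radius.

A line scan across the straight edge of a reflective grid bar records the
power transmitted past the edge as a function of scan position.  For a
Gaussian beam this is a Gauss error curve: the transmitted fraction past a
straight edge at the 1/e^2 radius scale is ``0.5 * erfc(sqrt(2) (x - x0)/w)``
for a falling edge.  Two estimators are provided:

* ``clip`` (default): locate the 10% and 90% transmission crossings and
  convert the 10-90 width to a 1/e^2 *diameter* with the clip factor 1.561
  (so radius = 1.561 * d_1090 / 2).  This makes no use of the curve shape
  beyond the two crossings.
* ``erf_fit``: least-squares fit of the full error-function model; serves as
  a shape-sensitive cross-check of the clip method.

Traces may arrive with a time abscissa (oscilloscope capture); the scan of a
grid hole of known width calibrates the time-to-distance scale from the
separation of the two 50% edge midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import optimize, special

__all__ = [
    "Trace",
    "AnalysisConfig",
    "EdgeEstimate",
    "GridCalibration",
    "TraceAnalysisError",
    "DegenerateTraceError",
    "AmbiguousEdgeError",
    "CalibrationError",
    "EdgeFitError",
    "ExtrapolationWarning",
    "knife_edge_transmission",
    "normalize_trace",
    "locate_clip_crossings",
    "radius_from_clip_width",
    "fit_edge_erf",
    "calibrate_scale",
    "radius_at_z",
    "clip_width_per_radius",
]

_SQRT2 = math.sqrt(2.0)


class TraceAnalysisError(ValueError):
    """Base class for trace-analysis failures."""


class DegenerateTraceError(TraceAnalysisError):
    """Trace has no usable edge contrast (constant, or buried in noise)."""


class AmbiguousEdgeError(TraceAnalysisError):
    """A clip level is never crossed, or crossed at several distinct places."""


class CalibrationError(TraceAnalysisError):
    """A calibration scene does not contain the two opposite edges of a hole."""


class EdgeFitError(TraceAnalysisError):
    """Error-function fit failed to converge; carries the initial estimate."""

    def __init__(self, message: str, initial: "EdgeEstimate | None" = None):
        super().__init__(message)
        self.initial = initial


class ExtrapolationWarning(UserWarning):
    """The data do not bracket the quantity being estimated."""


@dataclass(frozen=True)
class Trace:
    """One knife-edge line scan.

    ``abscissa`` is strictly increasing, in seconds (``abscissa_kind="time"``)
    or micrometres (``"distance"``).  ``scale`` [um/s] converts a time
    abscissa to distance once known.  ``z`` is the axial offset of the scan
    plane [um] and ``angle`` the scan direction [deg].
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    abscissa_kind: Literal["time", "distance"] = "distance"
    scale: float | None = None
    z: float = 0.0
    angle: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "abscissa", np.asarray(self.abscissa, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.intensity.shape:
            raise ValueError("abscissa and intensity must be 1-D arrays of equal length")
        if self.abscissa.size < 16:
            raise ValueError(f"trace needs >= 16 samples, got {self.abscissa.size}")
        if not np.all(np.diff(self.abscissa) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if not self.normalized and np.any(self.intensity < 0):
            raise ValueError("raw intensity must be non-negative")
        if self.abscissa_kind not in ("time", "distance"):
            raise ValueError(f"unknown abscissa_kind {self.abscissa_kind!r}")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def positions_um(self, scale: float | None = None) -> np.ndarray:
        """Abscissa converted to micrometres."""
        if self.abscissa_kind == "distance":
            return self.abscissa
        s = scale if scale is not None else self.scale
        if s is None:
            raise CalibrationError(
                "time-domain trace has no scale; run calibrate_scale first"
            )
        return self.abscissa * s


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the edge estimators.

    ``conversion_factor`` is the Gaussian 10/90 clip factor: the 1/e^2
    diameter equals 1.561 times the 10-90 knife-edge width.  Other clip
    levels (for non-Gaussian beams) may be set together with a matching
    factor.  Normalization uses robust quantiles rather than min/max so a
    few noise spikes cannot stretch the [0, 1] range.
    """

    clip_lo: float = 0.10
    clip_hi: float = 0.90
    conversion_factor: float = 1.561
    baseline_quantile: float = 0.02
    plateau_quantile: float = 0.98
    method: Literal["clip", "erf_fit"] = "clip"
    smooth_window: int = 5       # samples, crossing *detection* only
    rms_threshold: float = 0.01  # erf-fit residual above this flags the trace

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_lo < self.clip_hi < 1.0):
            raise ValueError("need 0 < clip_lo < clip_hi < 1")
        if self.conversion_factor <= 0:
            raise ValueError("conversion_factor must be positive")
        if not (0.0 <= self.baseline_quantile < self.plateau_quantile <= 1.0):
            raise ValueError("need 0 <= baseline_quantile < plateau_quantile <= 1")
        if self.method not in ("clip", "erf_fit"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class EdgeEstimate:
    """A localized edge: clip crossings, midpoint and derived 1/e^2 radius [um]."""

    x_lo: float
    x_hi: float
    d_1090: float
    x0: float
    direction: Literal["rising", "falling"]
    w: float | None = None
    rms_residual: float | None = None
    flagged: bool = False


@dataclass(frozen=True)
class GridCalibration:
    """Time-to-distance calibration from a scan across one full grid hole."""

    hole_width_ref: float = 40.0          # um
    scale: float | None = None            # um per s
    edge_separation_s: float | None = None

    def __post_init__(self) -> None:
        if self.hole_width_ref <= 0:
            raise ValueError("hole_width_ref must be positive")
        if self.scale is not None and not self.scale > 0:
            raise ValueError("scale must be positive")


def clip_width_per_radius(clip_lo: float = 0.10, clip_hi: float = 0.90) -> float:
    """Distance between the two clip crossings of a unit-radius Gaussian edge.

    For the defaults this is ``sqrt(2) * (erfinv(0.8) - erfinv(-0.8)) / 2
    = 1.2816``; its reciprocal times 2 is the familiar diameter conversion
    factor 1.561.
    """
    u_lo = special.erfinv(1.0 - 2.0 * clip_lo)
    u_hi = special.erfinv(1.0 - 2.0 * clip_hi)
    return abs(u_hi - u_lo) / _SQRT2


def knife_edge_transmission(
    x, x0: float, w: float, direction: str = "falling"
):
    """Transmitted power fraction of a Gaussian beam past a straight edge.

    ``0.5 * erfc(sqrt(2) (x - x0) / w)`` for a falling edge (opaque side at
    larger x); the complement for a rising edge.  ``w`` is the 1/e^2
    intensity radius; the value is 0.5 at ``x = x0``.
    """
    if not w > 0:
        raise ValueError(f"beam radius w must be positive, got {w}")
    u = _SQRT2 * (np.asarray(x, dtype=float) - x0) / w
    t = 0.5 * special.erfc(u)
    if direction == "rising":
        t = 1.0 - t
    elif direction != "falling":
        raise ValueError(f"unknown direction {direction!r}")
    return float(t) if np.isscalar(x) else t


def _noise_floor(y: np.ndarray) -> float:
    # robust sigma from first differences; flat regions dominate the median
    d = np.abs(np.diff(y))
    return 1.4826 * float(np.median(d)) / _SQRT2


def normalize_trace(trace: Trace, config: AnalysisConfig = AnalysisConfig()) -> Trace:
    """Affinely map the intensity so baseline -> 0 and plateau -> 1.

    The ``baseline_quantile`` / ``plateau_quantile`` quantiles bracket the
    intensity range robustly (spikes cannot stretch it); the baseline and
    plateau *levels* are then the medians of the samples within a quarter
    span of each bracket.  Medians of the flat clusters are unbiased under
    symmetric noise, whereas the tail quantiles themselves sit ~2 sigma
    into the noise and would inflate every edge width by a few percent.
    Values are clipped only to [-0.05, 1.05]: mild overshoot is retained so
    the error-function fit sees the true tails.
    """
    y = trace.intensity
    q_lo = float(np.quantile(y, config.baseline_quantile))
    q_hi = float(np.quantile(y, config.plateau_quantile))
    rough = q_hi - q_lo
    if rough > 0:
        lo = float(np.median(y[y <= q_lo + 0.25 * rough]))
        hi = float(np.median(y[y >= q_hi - 0.25 * rough]))
    else:
        lo, hi = q_lo, q_hi
    span = hi - lo
    floor = _noise_floor(y)
    if span <= 0 or (floor > 0 and span < 10.0 * floor):
        raise DegenerateTraceError(
            f"no usable edge contrast: plateau-baseline span {span:.3g} "
            f"vs noise floor {floor:.3g}"
        )
    norm = np.clip((y - lo) / span, -0.05, 1.05)
    return replace(trace, intensity=norm, normalized=True)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(ypad, kernel, mode="valid")[: y.size]


def _crossing_indices(y: np.ndarray, level: float) -> list[int]:
    """Indices i where the segment (i, i+1) crosses `level`, clustered."""
    s = y - level
    hits = np.nonzero((s[:-1] == 0) | (np.sign(s[:-1]) * np.sign(s[1:]) < 0))[0]
    clusters: list[int] = []
    for i in hits:
        if clusters and i - clusters[-1] <= 10:
            continue  # same edge, keep first crossing in scan direction
        clusters.append(int(i))
    return clusters


def _interp_crossing(x: np.ndarray, y: np.ndarray, level: float, i: int) -> float:
    # clamped to the bracket cell: the crossing was detected in (i, i+1), so
    # noise on the raw pair must not extrapolate the estimate outside it
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(0.5 * (x[i] + x[i + 1]))
    t = min(max((level - y0) / (y1 - y0), 0.0), 1.0)
    return float(x[i] + t * (x[i + 1] - x[i]))


def _refine_crossing(
    x: np.ndarray, y: np.ndarray, level: float, i: int, half_width: int
) -> float:
    """Crossing position from a local quadratic fit of the *raw* samples.

    A short least-squares quadratic around the bracketing pair removes the
    curvature bias of two-point interpolation and averages down sample
    noise; with fewer than 5 points in the window it degenerates to plain
    linear interpolation between the bracketing samples.
    """
    lo = max(0, i - half_width)
    hi = min(x.size, i + half_width + 2)
    xs, ys = x[lo:hi], y[lo:hi]
    if xs.size < 5:
        return _interp_crossing(x, y, level, i)
    xc = 0.5 * (x[i] + x[i + 1])
    coeffs = np.polynomial.polynomial.polyfit(xs - xc, ys - level, 2)
    c0, c1, c2 = coeffs
    if abs(c2) < 1e-12 * max(abs(c1), 1e-30):
        roots = [-c0 / c1] if c1 != 0 else []
    else:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc < 0:
            return _interp_crossing(x, y, level, i)
        sq = math.sqrt(disc)
        roots = [(-c1 + sq) / (2 * c2), (-c1 - sq) / (2 * c2)]
    span = xs[-1] - xs[0]
    roots = [r for r in roots if abs(r) <= span]
    if not roots:
        return _interp_crossing(x, y, level, i)
    return float(xc + min(roots, key=abs))


def _locate_level(
    x: np.ndarray,
    y_raw: np.ndarray,
    y_smooth: np.ndarray,
    level: float,
    half_width: int,
) -> float:
    idx = _crossing_indices(y_smooth, level)
    if not idx:
        raise AmbiguousEdgeError(f"level {level:.3g} is never crossed")
    if len(idx) > 1:
        raise AmbiguousEdgeError(
            f"level {level:.3g} crossed at {len(idx)} distinct places; "
            "trace does not contain a single monotone edge"
        )
    return _refine_crossing(x, y_raw, level, idx[0], half_width)


def _edge_direction(y_smooth: np.ndarray) -> str:
    k = max(3, y_smooth.size // 20)
    return "rising" if y_smooth[-k:].mean() >= y_smooth[:k].mean() else "falling"


def locate_clip_crossings(
    trace: Trace, config: AnalysisConfig = AnalysisConfig()
) -> EdgeEstimate:
    """Locate the clip-level and 50% crossings of a single normalized edge.

    The smoothed trace (moving mean over ``smooth_window`` samples) is used
    only to detect where each level is crossed and to reject traces where a
    level is crossed more than once; positions are then refined on the raw
    samples.  Returns positions only (``w`` is left unset).
    """
    if not trace.normalized:
        trace = normalize_trace(trace, config)
    x = trace.positions_um()
    y = trace.intensity
    ys = _smooth(y, config.smooth_window)
    direction = _edge_direction(ys)

    # first pass on the smoothed trace to size the refinement window
    step = float(np.median(np.diff(x)))
    try:
        rough = [
            _interp_crossing(x, ys, lvl, _crossing_indices(ys, lvl)[0])
            for lvl in (config.clip_lo, config.clip_hi)
        ]
        d_rough = abs(rough[1] - rough[0])
    except IndexError:
        d_rough = 0.0
    half_width = int(np.clip(round(0.1 * d_rough / step), 2, 25)) if d_rough else 2

    x_lo = _locate_level(x, y, ys, config.clip_lo, half_width)
    x_hi = _locate_level(x, y, ys, config.clip_hi, half_width)
    x0 = _locate_level(x, y, ys, 0.5, half_width)
    return EdgeEstimate(
        x_lo=x_lo,
        x_hi=x_hi,
        d_1090=abs(x_hi - x_lo),
        x0=x0,
        direction=direction,
    )


def radius_from_clip_width(
    d_1090: float, config: AnalysisConfig = AnalysisConfig()
) -> float:
    """1/e^2 radius from the 10-90 width: ``conversion_factor * d / 2``."""
    if d_1090 < 0:
        raise ValueError("d_1090 must be non-negative")
    return config.conversion_factor * d_1090 / 2.0


def _erf_model(x, baseline, amplitude, x0, w, sign):
    return baseline + amplitude * 0.5 * special.erfc(sign * _SQRT2 * (x - x0) / w)


def fit_edge_erf(
    trace: Trace, config: AnalysisConfig = AnalysisConfig()
) -> EdgeEstimate:
    """Least-squares error-function fit of one edge.

    Model: ``B + A * 0.5 * erfc(+-sqrt(2)(x - x0)/w)``, sign fixed by the
    detected edge direction.  Initialized from the clip-method estimate
    (falling back to coarse guesses if the clip pass fails).  The residual
    is reported rms-normalized by the fitted amplitude and the estimate is
    flagged when it exceeds ``rms_threshold`` — a Gaussian beam across a
    sharp edge should fit to within the noise — or when the fitted 10-90
    width is not contained in the scanned window (a straight ramp is fit
    deceptively well by the linear core of a much wider erf, so the
    residual alone cannot reject it).
    """
    norm = trace if trace.normalized else normalize_trace(trace, config)
    x = norm.positions_um()
    y = norm.intensity

    initial = None
    try:
        initial = locate_clip_crossings(norm, config)
        x0_guess = initial.x0
        w_guess = radius_from_clip_width(initial.d_1090, config)
        direction = initial.direction
    except TraceAnalysisError:
        direction = _edge_direction(_smooth(y, config.smooth_window))
        x0_guess = float(x[y.size // 2])
        w_guess = 0.25 * float(x[-1] - x[0])
    sign = -1.0 if direction == "rising" else 1.0
    w_guess = max(w_guess, 2.0 * float(np.median(np.diff(x))))

    try:
        popt, _ = optimize.curve_fit(
            lambda xx, b, a, x0, w: _erf_model(xx, b, a, x0, w, sign),
            x, y,
            p0=[0.0, 1.0, x0_guess, w_guess],
            bounds=([-0.5, 0.1, x[0] - (x[-1] - x[0]), 1e-6],
                    [0.5, 2.0, x[-1] + (x[-1] - x[0]), 10.0 * (x[-1] - x[0])]),
            maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise EdgeFitError(f"error-function fit did not converge: {exc}", initial)
    baseline, amplitude, x0, w = popt
    resid = y - _erf_model(x, *popt, sign)
    rms = float(np.sqrt(np.mean(resid**2))) / amplitude
    half = clip_width_per_radius(config.clip_lo, config.clip_hi) * w / 2.0
    if direction == "rising":
        x_lo, x_hi = x0 - half, x0 + half
    else:
        x_lo, x_hi = x0 + half, x0 - half
    return EdgeEstimate(
        x_lo=x_lo,
        x_hi=x_hi,
        d_1090=2.0 * half,
        x0=float(x0),
        direction=direction,
        w=float(w),
        rms_residual=rms,
        flagged=rms > config.rms_threshold or 2.0 * half > 0.5 * float(x[-1] - x[0]),
    )


def _find_hole_midpoints(
    x: np.ndarray, y: np.ndarray, window: int
) -> tuple[float, float] | None:
    """(rising, falling) 50% midpoints of a full-hole trace, or None."""
    ys = _smooth(y, window)
    idx = _crossing_indices(ys, 0.5)
    if len(idx) != 2:
        return None
    i_up, i_dn = idx
    if not (ys[i_up] < 0.5 <= ys[i_up + 1] or ys[i_up] <= 0.5 < ys[i_up + 1]):
        return None  # first crossing must be rising
    t_up = _refine_crossing(x, y, 0.5, i_up, max(2, window))
    t_dn = _refine_crossing(x, y, 0.5, i_dn, max(2, window))
    return (t_up, t_dn)


def calibrate_scale(
    full_hole_trace: Trace, grid: GridCalibration = GridCalibration()
) -> GridCalibration:
    """Time-to-distance scale from a scan across one full grid hole.

    The separation of the two 50% edge midpoints in seconds corresponds to
    the known hole width, so ``scale = hole_width_ref / dt`` [um/s].  The
    50% midpoint (not the 10/90 midpoint) defines the edge position: it is
    symmetric and noise-robust.
    """
    if full_hole_trace.abscissa_kind != "time":
        raise CalibrationError("calibration expects a time-domain trace")
    config = AnalysisConfig()
    norm = normalize_trace(full_hole_trace, config)
    mids = _find_hole_midpoints(norm.abscissa, norm.intensity, config.smooth_window)
    if mids is None:
        raise CalibrationError(
            "calibration trace must cross 50% exactly twice "
            "(rising then falling edge of one hole)"
        )
    t_up, t_dn = mids
    dt = t_dn - t_up
    if dt <= 0:
        raise CalibrationError("edges found in the wrong order")
    return GridCalibration(
        hole_width_ref=grid.hole_width_ref,
        scale=grid.hole_width_ref / dt,
        edge_separation_s=dt,
    )


def _split_hole(
    trace: Trace, config: AnalysisConfig
) -> list[Trace]:
    """Split a normalized full-hole trace into its two single-edge halves.

    If only one 50% crossing is present the trace is returned unchanged.
    """
    x = trace.abscissa
    y = trace.intensity
    mids = _find_hole_midpoints(x, y, config.smooth_window)
    if mids is None:
        return [trace]
    cut = float(0.5 * (mids[0] + mids[1]))
    i_cut = int(np.searchsorted(x, cut))
    if i_cut < 16 or trace.abscissa.size - i_cut < 16:
        return [trace]
    left = replace(trace, abscissa=x[:i_cut], intensity=y[:i_cut])
    right = replace(trace, abscissa=x[i_cut:], intensity=y[i_cut:])
    return [left, right]


def radius_at_z(
    trace: Trace,
    config: AnalysisConfig = AnalysisConfig(),
    calibration: GridCalibration | None = None,
) -> tuple[float, float]:
    """Full single-trace pipeline: normalize, locate/fit, convert to radius.

    Time-domain traces are converted to distance with the trace's own scale
    or the supplied calibration.  A trace spanning a whole hole contributes
    both of its edges; their radii are averaged.  Returns ``(z, w)`` in um.
    """
    scale = trace.scale
    if scale is None and calibration is not None:
        scale = calibration.scale
    x_um = trace.positions_um(scale)
    dist = replace(trace, abscissa=x_um, abscissa_kind="distance", scale=None)
    norm = normalize_trace(dist, config)

    radii = []
    for segment in _split_hole(norm, config):
        if config.method == "clip":
            est = locate_clip_crossings(segment, config)
            radii.append(radius_from_clip_width(est.d_1090, config))
        else:
            est = fit_edge_erf(segment, config)
            radii.append(est.w)
    return (trace.z, float(np.mean(radii)))
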