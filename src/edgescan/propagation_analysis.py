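"""From per-plane radii to waist, divergence, effective NA and astigmatism.

Given the beam radius measured at several axial offsets z (one series per
scan angle), this module estimates the waist ``w0``, waist position ``z0``
and far-field half-angle ``theta`` of the propagation hyperbola
``w(z)^2 = w0^2 + theta^2 (z - z0)^2``, and derives the effective numerical
aperture ``n sin(theta)``.  Two estimators:

* ``trig`` — the instrument-bench recipe: waist from the smallest measured
  radii near focus, divergence from far-field points (>= 5 Rayleigh ranges
  out) as ``arctan(w / |z - z0|)``.
* ``hyperbola`` — weighted least squares of the full hyperbola; uses every
  plane and needs no far-field qualification.

Comparing the two scan angles (0 and 90 degrees) yields the ellipticity
(ratio of the smaller to the larger waist) and the astigmatism (axial
separation of the two line foci).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .beam_optics import (
    ObjectiveSpec,
    TheoryReport,
    effective_na,
    paraxial_metric,
    theoretical_waist,
)
from .trace_analysis import ExtrapolationWarning

__all__ = [
    "RadiusSeries",
    "PropagationFit",
    "AxialCharacterization",
    "FocusReport",
    "InsufficientRangeError",
    "waist_from_series",
    "divergence_trig",
    "fit_trig",
    "fit_hyperbola",
    "ideal_reference_series",
    "characterize_axes",
    "focus_report",
]


class InsufficientRangeError(ValueError):
    """No measurement lies far enough from the waist to read the divergence."""


@dataclass(frozen=True)
class RadiusSeries:
    """Measured beam radii w(z) for one scan angle.

    ``z`` and ``w`` are in micrometres, ``wavelength`` in nanometres.
    Points are stored sorted by z.  Fitting operations require at least
    three points; an empty series is permitted only as a container (e.g.
    an ideal reference over an empty grid).
    """

    z: np.ndarray
    w: np.ndarray
    angle: float = 0.0
    wavelength: float = 488.0
    n: float = 1.0
    objective: ObjectiveSpec | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if z.shape != w.shape or z.ndim != 1:
            raise ValueError("z and w must be 1-D arrays of equal length")
        if np.unique(z).size != z.size:
            raise ValueError("z values must be distinct")
        if np.any(w <= 0):
            raise ValueError("all radii must be positive")
        order = np.argsort(z)
        object.__setattr__(self, "z", z[order])
        object.__setattr__(self, "w", w[order])
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")

    def __len__(self) -> int:
        return int(self.z.size)

    @classmethod
    def from_points(
        cls, points: Sequence[tuple[float, float]], **kwargs
    ) -> "RadiusSeries":
        pts = np.asarray(list(points), dtype=float).reshape(-1, 2)
        return cls(z=pts[:, 0], w=pts[:, 1], **kwargs)

    @property
    def wavelength_um(self) -> float:
        return self.wavelength * 1e-3


@dataclass(frozen=True)
class PropagationFit:
    """Hyperbola parameters for one axis: waist, focus position, divergence."""

    w0: float                 # um
    z0: float                 # um
    theta: float              # rad
    effective_na: float
    method: Literal["trig", "hyperbola"]
    rmse: float               # um, on w
    w0_se: float              # um, scatter of the near-focus radii
    n: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < math.pi / 2):
            raise ValueError(f"theta must be in (0, pi/2), got {self.theta}")


@dataclass(frozen=True)
class AxialCharacterization:
    """Joint x/y picture of the focus: per-axis fits, ellipticity, astigmatism."""

    fit_0: PropagationFit
    fit_90: PropagationFit
    ellipticity: float        # min(w0) / max(w0), in (0, 1]
    astigmatism: float        # |z0(0 deg) - z0(90 deg)| [um]


def _require_points(series: RadiusSeries, n_min: int, what: str) -> None:
    if len(series) < n_min:
        raise ValueError(f"{what} needs >= {n_min} points, got {len(series)}")


def waist_from_series(
    series: RadiusSeries, n_near: int = 3
) -> tuple[float, float, float]:
    """Waist estimate from the near-focus planes.

    ``w0`` is the mean of the ``n_near`` smallest radii, ``z0`` their
    w-weighted z centroid and ``w0_se`` their standard deviation — the
    repeatability of the near-focus measurement.  Warns when the minimum
    sits at the end of the scanned range (the waist was probably not
    bracketed, so ``z0`` is an extrapolation).
    """
    _require_points(series, n_near, "waist_from_series")
    idx = np.argsort(series.w)[:n_near]
    w_near = series.w[idx]
    z_near = series.z[idx]
    w0 = float(np.mean(w_near))
    z0 = float(np.sum(z_near * w_near) / np.sum(w_near))
    w0_se = float(np.std(w_near, ddof=1)) if n_near > 1 else 0.0
    i_min = int(np.argmin(series.w))
    if i_min in (0, len(series) - 1):
        warnings.warn(
            "smallest radius is at the edge of the z range; the waist is "
            "extrapolated, not bracketed",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return w0, z0, w0_se


def _rayleigh_um(series: RadiusSeries, w0: float) -> float:
    return series.n * math.pi * w0**2 / series.wavelength_um


def divergence_trig(series: RadiusSeries, w0: float, z0: float) -> float:
    """Far-field divergence by trigonometry: mean ``arctan(w / |z - z0|)``.

    Only planes at least five Rayleigh ranges from the waist qualify, where
    the hyperbola is within ~2% of its asymptote; anchoring the triangle at
    the waist position keeps the small residual bias positive and bounded,
    unlike the finite-difference slope which undershoots.
    """
    z_r = _rayleigh_um(series, w0)
    dz = np.abs(series.z - z0)
    far = dz >= 5.0 * z_r
    if not np.any(far):
        raise InsufficientRangeError(
            f"no plane lies >= {5.0 * z_r:.3g} um (5 Rayleigh ranges) from "
            f"the waist at z0 = {z0:.3g} um; farthest is {dz.max():.3g} um"
        )
    return float(np.mean(np.arctan(series.w[far] / dz[far])))


def fit_trig(series: RadiusSeries, n_near: int = 3) -> PropagationFit:
    """Bench-style estimate: near-focus waist + far-field trigonometry."""
    _require_points(series, 3, "fit_trig")
    w0, z0, w0_se = waist_from_series(series, n_near)
    theta = divergence_trig(series, w0, z0)
    model = np.sqrt(w0**2 + theta**2 * (series.z - z0) ** 2)
    return PropagationFit(
        w0=w0,
        z0=z0,
        theta=theta,
        effective_na=effective_na(series.n, theta),
        method="trig",
        rmse=float(np.sqrt(np.mean((model - series.w) ** 2))),
        w0_se=w0_se,
        n=series.n,
    )


def fit_hyperbola(series: RadiusSeries, n_near: int = 3) -> PropagationFit:
    """Least-squares fit of ``w^2 = w0^2 + theta^2 (z - z0)^2``.

    The squared-radius residuals are weighted by 1/(2w), which to first
    order equals fitting the radii themselves: without the weight the
    far-field planes (largest w^2) dominate and the waist is poorly
    constrained.  Initialized from the near-focus waist and (when far-field
    planes exist) the trigonometric divergence; three exact points are
    interpolated exactly.
    """
    _require_points(series, 3, "fit_hyperbola")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        w0_i, z0_i, w0_se = waist_from_series(series, min(n_near, len(series)))
    try:
        theta_i = divergence_trig(series, w0_i, z0_i)
    except InsufficientRangeError:
        dz = np.abs(series.z - z0_i)
        spread = float(dz.max())
        theta_i = max((series.w.max() - w0_i) / spread, 1e-4) if spread > 0 else 1e-3

    def resid(p):
        w0, z0, theta = p
        return (w0**2 + theta**2 * (series.z - z0) ** 2 - series.w**2) / (
            2.0 * series.w
        )

    w_min = float(series.w.min())
    sol = optimize.least_squares(
        resid,
        x0=[min(w0_i, w_min), z0_i, min(theta_i, 1.5)],
        bounds=([1e-9, -np.inf, 1e-9], [1.001 * w_min, np.inf, math.pi / 2 - 1e-9]),
    )
    if not sol.success:
        raise RuntimeError(
            f"hyperbola fit failed: {sol.message}; initial estimates "
            f"w0={w0_i:.4g} um, z0={z0_i:.4g} um, theta={theta_i:.4g} rad"
        )
    w0, z0, theta = sol.x
    model = np.sqrt(w0**2 + theta**2 * (series.z - z0) ** 2)
    return PropagationFit(
        w0=float(w0),
        z0=float(z0),
        theta=float(theta),
        effective_na=effective_na(series.n, float(theta)),
        method="hyperbola",
        rmse=float(np.sqrt(np.mean((model - series.w) ** 2))),
        w0_se=w0_se,
        n=series.n,
    )


def ideal_reference_series(
    objective: ObjectiveSpec,
    wavelength: float,
    z_grid: Sequence[float],
    angle: float = 0.0,
) -> RadiusSeries:
    """Diffraction-limited caustic of the objective, for overlay plots.

    Uses the theoretical waist at full NA and the marginal-ray half-angle
    ``arcsin(NA/n)``; the waist sits at z = 0.
    """
    z = np.asarray(list(z_grid), dtype=float)
    w0 = theoretical_waist(wavelength, objective.immersion_n, objective.na) * 1e-3
    theta = objective.half_angle
    w = np.sqrt(w0**2 + theta**2 * z**2)
    return RadiusSeries(
        z=z, w=w, angle=angle, wavelength=wavelength,
        n=objective.immersion_n, objective=objective,
    )


def characterize_axes(
    series_0: RadiusSeries,
    series_90: RadiusSeries,
    method: Literal["trig", "hyperbola"] = "hyperbola",
    n_near: int = 3,
) -> AxialCharacterization:
    """Fit both scan axes and derive ellipticity and astigmatism.

    Ellipticity is the smaller waist over the larger (<= 1 and invariant
    under relabeling the axes); astigmatism is the axial separation of the
    two waist positions.
    """
    if series_0.wavelength != series_90.wavelength or series_0.n != series_90.n:
        raise ValueError("both axes must share wavelength and medium index")
    fitter = fit_trig if method == "trig" else fit_hyperbola
    fit_0 = fitter(series_0, n_near)
    fit_90 = fitter(series_90, n_near)
    w_pair = (fit_0.w0, fit_90.w0)
    return AxialCharacterization(
        fit_0=fit_0,
        fit_90=fit_90,
        ellipticity=min(w_pair) / max(w_pair),
        astigmatism=abs(fit_0.z0 - fit_90.z0),
    )


@dataclass(frozen=True)
class FocusReport:
    """Measured vs diffraction-limited focus for one objective/wavelength.

    Waists are reported in nanometres to match the usual tabulation;
    ``w0_ratio`` > 1 quantifies how much larger the real focus is than the
    full-NA diffraction limit, and ``na_ratio`` how much of the nominal NA
    the beam actually uses.
    """

    objective_label: str
    wavelength: float                    # nm
    theory: TheoryReport
    w0_nm: dict[str, float]              # per-axis measured waists
    w0_se_nm: dict[str, float]
    effective_na: dict[str, float]
    w0_ratio: dict[str, float]           # measured / theoretical waist
    na_ratio: dict[str, float]           # effective / nominal NA
    paraxial_metric_measured: dict[str, float]
    ellipticity: float | None
    astigmatism_um: float | None
    method: str

    def to_dict(self) -> dict:
        return {
            "objective": self.objective_label,
            "wavelength_nm": self.wavelength,
            "theoretical_waist_nm": self.theory.w0_theory,
            "lateral_resolution_nm": self.theory.r_lat,
            "axial_resolution_nm": self.theory.r_ax,
            "paraxial_metric_theory": self.theory.paraxial_metric,
            "measured_waist_nm": self.w0_nm,
            "measured_waist_se_nm": self.w0_se_nm,
            "effective_na": self.effective_na,
            "waist_ratio_measured_over_theory": self.w0_ratio,
            "na_ratio_effective_over_nominal": self.na_ratio,
            "paraxial_metric_measured": self.paraxial_metric_measured,
            "ellipticity": self.ellipticity,
            "astigmatism_um": self.astigmatism_um,
            "fit_method": self.method,
        }


def focus_report(
    char: AxialCharacterization | PropagationFit,
    objective: ObjectiveSpec,
    wavelength: float,
) -> FocusReport:
    """Tabulate measured waists and effective NA against diffraction theory.

    Accepts a two-axis characterization or a single-axis fit (in which case
    ellipticity and astigmatism are omitted).
    """
    theory = TheoryReport.for_objective(objective, wavelength)
    if isinstance(char, PropagationFit):
        fits = {"0": char}
        ellipticity = None
        astigmatism = None
        method = char.method
    else:
        fits = {"0": char.fit_0, "90": char.fit_90}
        ellipticity = char.ellipticity
        astigmatism = char.astigmatism
        method = char.fit_0.method
    w0_nm = {a: f.w0 * 1e3 for a, f in fits.items()}
    return FocusReport(
        objective_label=objective.label or f"{objective.magnification:g}x/{objective.na:g}",
        wavelength=wavelength,
        theory=theory,
        w0_nm=w0_nm,
        w0_se_nm={a: f.w0_se * 1e3 for a, f in fits.items()},
        effective_na={a: f.effective_na for a, f in fits.items()},
        w0_ratio={a: w / theory.w0_theory for a, w in w0_nm.items()},
        na_ratio={a: f.effective_na / objective.na for a, f in fits.items()},
        paraxial_metric_measured={
            a: paraxial_metric(wavelength, objective.immersion_n, w)
            for a, w in w0_nm.items()
        },
        ellipticity=ellipticity,
        astigmatism_um=astigmatism,
        method=method,
    )
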