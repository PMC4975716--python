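"""Synthetic knife-edge line scans of an astigmatic elliptical Gaussian beam.

The simulated scene is the one used for focus metrology on a scanning
microscope: a reflective metal grid (square holes, opaque bars) in the
specimen plane, a focused Gaussian beam scanned across the centre of one
hole, and a detector below integrating the transmitted power.  The beam may
be elliptical (different waists along the two scan axes) and astigmatic
(different waist positions), each axis propagating as an independent
hyperbola.  For a beam of radius w the transmitted power across the hole
``[x_L, x_R]`` is

    T(x) = 0.5 * [erf(sqrt(2)(x - x_L)/w) - erf(sqrt(2)(x - x_R)/w)]

which rises through 0.5 exactly at the left edge and falls through 0.5 at
the right edge.  A non-ideal ("graded") edge is modelled by convolving the
profile with a box of width ``edge_grade`` (done in closed form), and laser
intensity noise as multiplicative Gaussian noise on each sample.  Traces
are emitted in the time domain, as an oscilloscope would capture them, with
the true time-to-distance scale recorded alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .beam_optics import ideal_divergence
from .trace_analysis import Trace

__all__ = [
    "TrueBeam",
    "GridModel",
    "AcquisitionModel",
    "CalibrationScene",
    "SimulatedSeries",
    "beam_radius_at",
    "simulate_line_scan",
    "simulate_z_series",
    "make_calibration_scene",
]

_SQRT2 = math.sqrt(2.0)
_SQRT_PI = math.sqrt(math.pi)


@dataclass(frozen=True)
class TrueBeam:
    """Ground-truth elliptical astigmatic beam (per-axis hyperbolas).

    Lengths in micrometres except ``wavelength`` [nm]; angles in radians.
    Axis x is scanned at 0 degrees, axis y at 90 degrees.
    """

    w0x: float
    w0y: float
    z0x: float = 0.0
    z0y: float = 0.0
    theta_x: float = 0.0
    theta_y: float = 0.0
    wavelength: float = 488.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.w0x <= 0 or self.w0y <= 0:
            raise ValueError("waists must be positive")
        if self.wavelength <= 0 or self.n < 1:
            raise ValueError("need wavelength > 0 and n >= 1")
        for name in ("theta_x", "theta_y"):
            th = getattr(self, name)
            if not (0.0 <= th < math.pi / 2):
                raise ValueError(f"{name} must be in [0, pi/2), got {th}")

    @classmethod
    def ideal(
        cls,
        w0x: float,
        w0y: float | None = None,
        z0x: float = 0.0,
        z0y: float = 0.0,
        wavelength: float = 488.0,
        n: float = 1.0,
    ) -> "TrueBeam":
        """Diffraction-limited divergence on each axis."""
        w0y = w0x if w0y is None else w0y
        lam_um = wavelength * 1e-3
        return cls(
            w0x=w0x, w0y=w0y, z0x=z0x, z0y=z0y,
            theta_x=ideal_divergence(lam_um, n, w0x),
            theta_y=ideal_divergence(lam_um, n, w0y),
            wavelength=wavelength, n=n,
        )

    def rayleigh_um(self, axis: str = "min") -> float:
        """Rayleigh range [um]; axis 'x', 'y' or 'min' (smaller-waist axis)."""
        lam_um = self.wavelength * 1e-3
        zx = self.n * math.pi * self.w0x**2 / lam_um
        zy = self.n * math.pi * self.w0y**2 / lam_um
        return {"x": zx, "y": zy, "min": min(zx, zy)}[axis]

    def to_dict(self) -> dict:
        return {
            "w0x_um": self.w0x, "w0y_um": self.w0y,
            "z0x_um": self.z0x, "z0y_um": self.z0y,
            "theta_x_rad": self.theta_x, "theta_y_rad": self.theta_y,
            "wavelength_nm": self.wavelength, "n": self.n,
        }


@dataclass(frozen=True)
class GridModel:
    """Reflective grid: hole width, bar width, optional graded edge [um]."""

    hole_width: float = 40.0
    bar_width: float = 20.0
    edge_grade: float = 0.0

    def __post_init__(self) -> None:
        if self.hole_width <= 0 or self.bar_width <= 0:
            raise ValueError("hole_width and bar_width must be positive")
        if not (0.0 <= self.edge_grade < self.hole_width / 4):
            raise ValueError("edge_grade must be in [0, hole_width/4)")


@dataclass(frozen=True)
class AcquisitionModel:
    """Line-scan acquisition: sampling, geometry, signal levels, noise.

    ``scan_span`` is the distance covered by one scan line [um]; one line
    takes ``1/line_rate`` seconds, so the implied time-to-distance scale is
    ``scan_span * line_rate`` um/s.  ``noise_frac`` is the s.d. of the
    multiplicative laser intensity noise (default 1%).
    """

    n_samples: int = 2048
    line_rate: float = 10.0
    scan_span: float = 80.0
    amplitude: float = 1.0
    baseline: float = 0.05
    noise_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 64:
            raise ValueError("n_samples must be >= 64")
        if self.line_rate <= 0 or self.scan_span <= 0 or self.amplitude <= 0:
            raise ValueError("line_rate, scan_span and amplitude must be positive")
        if self.noise_frac < 0 or self.baseline < 0:
            raise ValueError("noise_frac and baseline must be non-negative")

    @property
    def scale_um_per_s(self) -> float:
        return self.scan_span * self.line_rate


def beam_radius_at(beam: TrueBeam, z: float, angle: float) -> float:
    """Radius [um] of the scanned axis at plane z; angle must be 0 or 90."""
    if angle == 0:
        w0, z0, th = beam.w0x, beam.z0x, beam.theta_x
    elif angle == 90:
        w0, z0, th = beam.w0y, beam.z0y, beam.theta_y
    else:
        raise ValueError(f"scan angle must be 0 or 90 degrees, got {angle}")
    return math.sqrt(w0**2 + (th * (z - z0)) ** 2)


def _rising_edge(x: np.ndarray, edge: float, w: float, grade: float) -> np.ndarray:
    """Transmission of one rising edge, optionally box-blurred (closed form)."""
    if grade <= 0:
        return 0.5 * (1.0 + special.erf(_SQRT2 * (x - edge) / w))

    # box convolution of the erf step: antiderivative of 0.5*(1+erf(a u))
    # is u/2 + (u erf(a u) + exp(-(a u)^2)/(a sqrt(pi)))/2 with a = sqrt2/w
    a = _SQRT2 / w

    def antider(u: np.ndarray) -> np.ndarray:
        au = a * u
        return 0.5 * u + 0.5 * (u * special.erf(au) + np.exp(-(au**2)) / (a * _SQRT_PI))

    u = x - edge
    return (antider(u + grade / 2) - antider(u - grade / 2)) / grade


def hole_transmission(
    x: np.ndarray, w: float, hole_width: float, edge_grade: float = 0.0
) -> np.ndarray:
    """Fraction of a beam of radius w transmitted by a hole centred at 0."""
    if w <= 0:
        raise ValueError("beam radius must be positive")
    x_l, x_r = -hole_width / 2, hole_width / 2
    return _rising_edge(x, x_l, w, edge_grade) - _rising_edge(x, x_r, w, edge_grade)


def _scan_trace(
    w: float,
    grid: GridModel,
    acq: AcquisitionModel,
    z: float,
    angle: float,
    rng: np.random.Generator,
) -> Trace:
    t = np.arange(acq.n_samples) / (acq.n_samples * acq.line_rate)
    x = (t * acq.scale_um_per_s) - acq.scan_span / 2.0  # hole centred at 0
    signal = acq.baseline + acq.amplitude * hole_transmission(
        x, w, grid.hole_width, grid.edge_grade
    )
    if acq.noise_frac > 0:
        signal = signal * (1.0 + acq.noise_frac * rng.standard_normal(signal.size))
    signal = np.maximum(signal, 0.0)
    return Trace(
        abscissa=t,
        intensity=signal,
        abscissa_kind="time",
        scale=acq.scale_um_per_s,
        z=z,
        angle=angle,
    )


def simulate_line_scan(
    beam: TrueBeam,
    grid: GridModel,
    acq: AcquisitionModel,
    z: float,
    angle: float,
    rng: np.random.Generator | None = None,
) -> Trace:
    """One line scan across the hole centre at plane z and the given angle.

    The trace abscissa is in seconds with the true scale attached.  Warns
    when the beam is so wide relative to the hole that the transmission
    plateau is never reached (edges overlap; the clip method degrades).
    """
    w = beam_radius_at(beam, z, angle)
    if w > grid.hole_width / 4:
        warnings.warn(
            f"beam radius {w:.3g} um exceeds a quarter of the hole width; "
            "the two edges overlap and the plateau is depressed",
            UserWarning,
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(acq.seed)
    return _scan_trace(w, grid, acq, z, angle, rng)


@dataclass(frozen=True)
class SimulatedSeries:
    """A z-series of traces with its acquisition manifest and ground truth."""

    traces: list[Trace]
    manifest: pd.DataFrame
    truth: dict


def default_z_list(beam: TrueBeam, n_planes: int = 9, span_zr: float = 5.0) -> np.ndarray:
    """Planes spanning +-``span_zr`` Rayleigh ranges of the smaller-waist axis."""
    z_r = beam.rayleigh_um("min")
    z0 = beam.z0x if beam.w0x <= beam.w0y else beam.z0y
    return z0 + np.linspace(-span_zr * z_r, span_zr * z_r, n_planes)


def simulate_z_series(
    beam: TrueBeam,
    grid: GridModel = GridModel(),
    acq: AcquisitionModel = AcquisitionModel(),
    z_list: np.ndarray | list[float] | None = None,
    angles: tuple[float, ...] = (0.0, 90.0),
) -> SimulatedSeries:
    """Simulate one trace per (z, angle) with independent, reproducible noise.

    Per-trace RNG streams are spawned from ``acq.seed`` so the same seed
    reproduces the whole series bit for bit; the manifest records z, angle
    and the per-trace seed.  The default z list covers +-5 Rayleigh ranges
    of the smaller-waist axis in 9 planes.
    """
    if z_list is None:
        z_list = default_z_list(beam)
    z_list = np.asarray(list(z_list), dtype=float)
    traces: list[Trace] = []
    rows = []
    seed_seq = np.random.SeedSequence(acq.seed)
    children = seed_seq.spawn(max(1, z_list.size * len(angles)))
    k = 0
    for angle in angles:
        for z in z_list:
            child = children[k]
            trace = simulate_line_scan(
                beam, grid, acq, float(z), float(angle),
                rng=np.random.default_rng(child),
            )
            traces.append(trace)
            rows.append(
                {
                    "z_um": float(z),
                    "angle_deg": float(angle),
                    "abscissa_kind": "time",
                    "scale_um_per_s": acq.scale_um_per_s,
                    "seed": int(child.entropy) if isinstance(child.entropy, int) else acq.seed,
                    "spawn_key": "/".join(str(s) for s in child.spawn_key),
                }
            )
            k += 1
    manifest = pd.DataFrame(
        rows,
        columns=["z_um", "angle_deg", "abscissa_kind", "scale_um_per_s", "seed", "spawn_key"],
    )
    truth = beam.to_dict()
    truth["grid"] = {
        "hole_width_um": grid.hole_width,
        "bar_width_um": grid.bar_width,
        "edge_grade_um": grid.edge_grade,
    }
    truth["scale_um_per_s"] = acq.scale_um_per_s
    return SimulatedSeries(traces=traces, manifest=manifest, truth=truth)


@dataclass(frozen=True)
class CalibrationScene:
    """A full-hole time-domain trace plus the scale that generated it."""

    trace: Trace
    true_scale: float  # um per s


def make_calibration_scene(
    grid: GridModel = GridModel(),
    acq: AcquisitionModel = AcquisitionModel(),
    w: float = 1.0,
) -> CalibrationScene:
    """A scan across one full hole, for exercising the scale calibration.

    The returned trace carries no scale of its own (it is what the
    calibration is supposed to recover); the true value is reported
    separately.
    """
    if w <= 0:
        raise ValueError("beam radius must be positive")
    if acq.scan_span <= grid.hole_width + 4 * w:
        raise ValueError(
            "scan_span must exceed hole_width + 4w so both bars are visible"
        )
    rng = np.random.default_rng(acq.seed)
    trace = _scan_trace(w, grid, acq, z=0.0, angle=0.0, rng=rng)
    bare = Trace(
        abscissa=trace.abscissa,
        intensity=trace.intensity,
        abscissa_kind="time",
        scale=None,
        z=0.0,
        angle=0.0,
    )
    return CalibrationScene(trace=bare, true_scale=acq.scale_um_per_s)
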