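"""Closed-form Gaussian-beam and diffraction-resolution theory.

All lengths in this module are in **nanometres**, all angles in **radians**;
unit conversion happens at I/O boundaries, never here.

The model is the standard TEM00 Gaussian beam: a focused beam with 1/e^2
intensity radius ``w0`` at the waist spreads along the optical axis as a
hyperbola ``w(z)^2 = w0^2 + theta^2 (z - z0)^2`` with far-field half-angle
``theta``.  A diffraction-limited ("ideal") beam satisfies
``theta = lambda / (n pi w0)``, in which case the hyperbola is the familiar
``w(z) = w0 sqrt(1 + (lambda z / (n pi w0^2))^2)``.  The half-angle a lens
can support at full numerical aperture is ``theta = arcsin(NA / n)``, and
conversely a measured divergence maps to an *effective* numerical aperture
``NA_eff = n sin(theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "BeamModel",
    "TheoryReport",
    "lateral_resolution",
    "axial_resolution",
    "ideal_divergence",
    "beam_radius",
    "effective_na",
    "theoretical_waist",
    "paraxial_metric",
    "rayleigh_range",
]

_SQRT2 = math.sqrt(2.0)


def _check_positive(**values: float) -> None:
    for name, value in values.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class ObjectiveSpec:
    """A microscope objective: magnification, NA and immersion medium.

    The immersion refractive index ``immersion_n`` is 1.0 for dry lenses and
    1.518 for standard immersion oil.  ``na < immersion_n`` is required so
    that the marginal-ray half-angle ``arcsin(na / immersion_n)`` exists.
    """

    magnification: float
    na: float
    immersion_n: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        _check_positive(magnification=self.magnification, na=self.na)
        if self.immersion_n < 1.0:
            raise ValueError(f"immersion_n must be >= 1, got {self.immersion_n}")
        if self.na >= self.immersion_n:
            raise ValueError(
                f"na ({self.na}) must be smaller than immersion_n "
                f"({self.immersion_n}) for the marginal-ray angle to exist"
            )

    @property
    def half_angle(self) -> float:
        """Marginal-ray half-angle at full NA, ``arcsin(na / n)`` [rad]."""
        return math.asin(self.na / self.immersion_n)


@dataclass(frozen=True)
class BeamModel:
    """A (possibly non-ideal) Gaussian beam along one transverse axis.

    Parameters
    ----------
    w0 : float
        1/e^2 intensity waist radius [nm].
    z0 : float
        Axial position of the waist [nm].
    wavelength : float
        Vacuum wavelength [nm].
    n : float
        Refractive index of the propagation medium.
    theta : float
        Far-field divergence half-angle [rad].  Independent of ``w0`` so
        that aberrated beams (larger waist than diffraction allows) can be
        represented; an ideal beam has ``theta = wavelength / (n pi w0)``.
    """

    w0: float
    z0: float
    wavelength: float
    n: float
    theta: float

    def __post_init__(self) -> None:
        _check_positive(w0=self.w0, wavelength=self.wavelength, n=self.n)
        if not (0.0 < self.theta < math.pi / 2):
            raise ValueError(f"theta must be in (0, pi/2), got {self.theta}")

    @classmethod
    def ideal(
        cls, w0: float, wavelength: float, n: float = 1.0, z0: float = 0.0
    ) -> "BeamModel":
        """Diffraction-limited beam: divergence tied to the waist."""
        return cls(
            w0=w0, z0=z0, wavelength=wavelength, n=n,
            theta=ideal_divergence(wavelength, n, w0),
        )

    @property
    def is_ideal(self) -> bool:
        """True when theta matches the diffraction limit to 1e-9 relative."""
        theta_ideal = ideal_divergence(self.wavelength, self.n, self.w0)
        return abs(self.theta - theta_ideal) <= 1e-9 * theta_ideal

    @property
    def rayleigh_range(self) -> float:
        """``z_R = n pi w0^2 / lambda`` [nm] (of the ideal beam with this w0)."""
        return rayleigh_range(self.wavelength, self.n, self.w0)


def lateral_resolution(wavelength: float, na: float) -> float:
    """Rayleigh lateral resolution ``0.61 lambda / NA`` [nm]."""
    _check_positive(wavelength=wavelength, na=na)
    return 0.61 * wavelength / na


def axial_resolution(wavelength: float, na: float, n: float = 1.0) -> float:
    """Axial resolution ``2 n lambda / NA^2`` [nm]."""
    _check_positive(wavelength=wavelength, na=na)
    if n < 1.0:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    return 2.0 * n * wavelength / na**2


def ideal_divergence(wavelength: float, n: float, w0: float) -> float:
    """Diffraction-limited far-field half-angle ``lambda / (n pi w0)`` [rad]."""
    _check_positive(wavelength=wavelength, n=n, w0=w0)
    return wavelength / (n * math.pi * w0)


def rayleigh_range(wavelength: float, n: float, w0: float) -> float:
    """Rayleigh range ``n pi w0^2 / lambda`` [nm] of an ideal beam."""
    _check_positive(wavelength=wavelength, n=n, w0=w0)
    return n * math.pi * w0**2 / wavelength


def beam_radius(z, beam: BeamModel):
    """Beam radius ``sqrt(w0^2 + theta^2 (z - z0)^2)`` [nm] at position z [nm].

    Accepts a scalar or array ``z``.  Even in ``z - z0`` with minimum ``w0``
    at ``z = z0``; for an ideal beam this is exactly the diffraction
    hyperbola ``w0 sqrt(1 + ((z - z0)/z_R)^2)``.
    """
    dz = np.asarray(z, dtype=float) - beam.z0
    w = np.sqrt(beam.w0**2 + (beam.theta * dz) ** 2)
    return float(w) if np.isscalar(z) else w


def effective_na(n: float, theta: float) -> float:
    """Effective numerical aperture ``n sin(theta)`` of a measured divergence."""
    _check_positive(n=n)
    if not (0.0 <= theta < math.pi / 2):
        raise ValueError(f"theta must be in [0, pi/2), got {theta}")
    return n * math.sin(theta)


def theoretical_waist(wavelength: float, n: float, na: float) -> float:
    """Diffraction-limited waist at full NA, ``lambda / (n pi arcsin(NA/n))`` [nm].

    This is the smallest waist the objective can produce: the inverse of
    :func:`ideal_divergence` evaluated at the marginal-ray half-angle
    ``arcsin(NA/n)`` (not the paraxial NA/n, which matters at high NA).
    """
    _check_positive(wavelength=wavelength, n=n, na=na)
    if na >= n:
        raise ValueError(f"na ({na}) must be < n ({n})")
    return wavelength / (n * math.pi * math.asin(na / n))


def paraxial_metric(wavelength: float, n: float, w0: float) -> float:
    """Paraxial-validity figure ``k w0 / sqrt(2)`` with in-medium ``k = 2 pi n / lambda``.

    Values above ~4 mean the paraxial Gaussian-beam treatment is safe;
    below ~1 it fails outright.  Dimensionless.
    """
    _check_positive(wavelength=wavelength, n=n, w0=w0)
    return (2.0 * math.pi * n / wavelength) * w0 / _SQRT2


@dataclass(frozen=True)
class TheoryReport:
    """Diffraction-theory figures of merit for one objective/wavelength pair."""

    r_lat: float            # lateral resolution [nm]
    r_ax: float             # axial resolution [nm]
    w0_theory: float        # diffraction-limited waist [nm]
    theta_full_na: float    # half-angle at full NA [rad]
    paraxial_metric: float  # k w0 / sqrt(2) at the theoretical waist

    @classmethod
    def for_objective(cls, objective: ObjectiveSpec, wavelength: float) -> "TheoryReport":
        n = objective.immersion_n
        w0 = theoretical_waist(wavelength, n, objective.na)
        return cls(
            r_lat=lateral_resolution(wavelength, objective.na),
            r_ax=axial_resolution(wavelength, objective.na, n),
            w0_theory=w0,
            theta_full_na=objective.half_angle,
            paraxial_metric=paraxial_metric(wavelength, n, w0),
        )
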