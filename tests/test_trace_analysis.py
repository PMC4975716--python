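"""Edge localisation: error-function model, clip method, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special

from edgescan.trace_analysis import (
    AmbiguousEdgeError,
    AnalysisConfig,
    CalibrationError,
    DegenerateTraceError,
    GridCalibration,
    Trace,
    calibrate_scale,
    clip_width_per_radius,
    fit_edge_erf,
    knife_edge_transmission,
    locate_clip_crossings,
    normalize_trace,
    radius_from_clip_width,
)

SQRT2 = math.sqrt(2.0)


def erfc_edge_trace(
    w: float = 1.0,
    x0: float = 0.0,
    step_frac: float = 0.01,
    span_w: float = 6.0,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    rising: bool = False,
    noise: float = 0.0,
    seed: int = 0,
) -> Trace:
    """Synthetic single-edge trace sampled at ``step_frac * w``."""
    x = x0 + np.arange(-span_w * w, span_w * w, step_frac * w)
    t = 0.5 * special.erfc(SQRT2 * (x - x0) / w)
    if rising:
        t = 1.0 - t
    y = baseline + amplitude * t
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise * rng.standard_normal(y.size))
    return Trace(abscissa=x, intensity=np.maximum(y, 0.0))


def half_plane_transmission(x_beam: float, x_edge: float, w: float) -> float:
    """Brute-force oracle: 2-D Gaussian intensity integrated over the open half-plane."""

    def intensity(y, x):
        return math.exp(-2.0 * ((x - x_beam) ** 2 + y**2) / w**2)

    total = math.pi * w**2 / 2.0
    val, _ = integrate.dblquad(
        intensity,
        x_beam - 8 * w,
        x_edge,
        lambda _: -8 * w,
        lambda _: 8 * w,
        epsabs=1e-12,
        epsrel=1e-10,
    )
    return val / total


@pytest.mark.parametrize("w", [0.1, 1.0, 10.0])
def test_transmission_matches_half_plane_integral(w):
    """erfc closed form agrees with numerical half-plane integration to 1e-6."""
    for u in np.linspace(-2.0, 2.0, 21):
        x_beam = u * w
        expected = half_plane_transmission(x_beam, 0.0, w)
        got = knife_edge_transmission(x_beam, 0.0, w, direction="falling")
        assert got == pytest.approx(expected, abs=1e-6)


def test_transmission_midpoint_limits_and_clip_point():
    assert knife_edge_transmission(0.0, 0.0, 1.0) == pytest.approx(0.5)
    assert knife_edge_transmission(50.0, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)
    assert knife_edge_transmission(-50.0, 0.0, 1.0) == pytest.approx(1.0, abs=1e-12)
    # 10% transmission of a unit-radius beam occurs 0.6408 w past the midpoint
    assert knife_edge_transmission(0.6408, 0.0, 1.0) == pytest.approx(0.100, abs=2e-4)
    with pytest.raises(ValueError):
        knife_edge_transmission(0.0, 0.0, -1.0)


def test_clip_factor_relation():
    """10-90 width is 1.2816 w, i.e. diameter = 1.561 x width."""
    width = clip_width_per_radius(0.10, 0.90)
    assert width == pytest.approx(SQRT2 * special.erfinv(0.8), rel=1e-12)
    assert 2.0 / width == pytest.approx(1.561, abs=5e-4)


class TestNormalize:
    def test_identity_for_unit_trace(self):
        trace = erfc_edge_trace()
        norm = normalize_trace(trace)
        assert np.allclose(norm.intensity, trace.intensity, atol=1e-9)
        assert norm.normalized

    def test_inverts_affine_scaling(self):
        ref = erfc_edge_trace().intensity
        scaled = erfc_edge_trace(amplitude=3.7, baseline=0.4)
        norm = normalize_trace(scaled)
        assert np.allclose(norm.intensity, ref, atol=1e-9)

    def test_constant_trace_rejected(self):
        flat = Trace(abscissa=np.arange(64.0), intensity=np.full(64, 2.0))
        with pytest.raises(DegenerateTraceError):
            normalize_trace(flat)

    def test_edge_buried_in_noise_rejected(self):
        rng = np.random.default_rng(1)
        x = np.arange(256.0)
        y = 1.0 + 0.05 * rng.standard_normal(256) + 0.01 * (x > 128)
        with pytest.raises(DegenerateTraceError):
            normalize_trace(Trace(abscissa=x, intensity=np.maximum(y, 0)))


class TestClipCrossings:
    def test_linear_ramp_exact(self):
        x = np.linspace(0.0, 1.0, 101)
        trace = Trace(abscissa=x, intensity=x.copy(), normalized=True)
        est = locate_clip_crossings(trace)
        assert est.direction == "rising"
        assert est.x_lo == pytest.approx(0.1, abs=1e-9)
        assert est.x_hi == pytest.approx(0.9, abs=1e-9)
        assert est.x0 == pytest.approx(0.5, abs=1e-9)

    def test_erfc_edge_width_noiseless(self):
        trace = normalize_trace(erfc_edge_trace(w=1.0, step_frac=0.01))
        est = locate_clip_crossings(trace)
        assert est.direction == "falling"
        assert est.d_1090 == pytest.approx(1.2816, abs=0.005)

    def test_erfc_edge_width_with_noise(self):
        """1% multiplicative noise, 2048-sample edges: width within 0.02 w (median)."""
        errors = []
        for seed in range(11):
            trace = normalize_trace(
                erfc_edge_trace(w=1.0, step_frac=0.00586, span_w=6.0, noise=0.01, seed=seed)
            )
            est = locate_clip_crossings(trace)
            errors.append(abs(est.d_1090 - 1.28155))
        assert np.median(errors) < 0.02

    def test_level_never_crossed(self):
        x = np.linspace(0.0, 1.0, 64)
        trace = Trace(abscissa=x, intensity=0.5 + 0.2 * x, normalized=True)
        with pytest.raises(AmbiguousEdgeError):
            locate_clip_crossings(trace)

    def test_multiple_edges_rejected(self):
        x = np.linspace(0.0, 4.0, 512)
        y = 0.5 * (1 + np.sin(2 * np.pi * x / 2.0))  # crosses every level twice
        trace = Trace(abscissa=x, intensity=y, normalized=True)
        with pytest.raises(AmbiguousEdgeError):
            locate_clip_crossings(trace)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    w=st.floats(0.1, 10.0),
    x0=st.floats(-100.0, 100.0),
    amplitude=st.floats(0.5, 5.0),
    baseline=st.floats(0.0, 2.0),
    rising=st.booleans(),
)
def test_clip_method_identity_under_affine_maps(w, x0, amplitude, baseline, rising):
    """Exact erfc edges of any scale: recovered w within 0.5% at step 0.015 w,
    invariant under abscissa translation and intensity gain/offset."""
    trace = erfc_edge_trace(
        w=w, x0=x0, step_frac=0.015, amplitude=amplitude, baseline=baseline, rising=rising
    )
    est = locate_clip_crossings(normalize_trace(trace))
    recovered = radius_from_clip_width(est.d_1090)
    assert recovered == pytest.approx(w, rel=5e-3)
    assert est.direction == ("rising" if rising else "falling")
    assert est.x0 == pytest.approx(x0, abs=0.02 * w)


def test_radius_from_clip_width():
    assert radius_from_clip_width(0.0) == 0.0
    # unit-waist round trip: exact width maps back to radius 1 within the
    # rounding of the 4-significant-figure conversion factor
    assert radius_from_clip_width(1.2816) == pytest.approx(1.0003, abs=2e-4)
    with pytest.raises(ValueError):
        radius_from_clip_width(-1.0)


class TestErfFit:
    def test_noiseless_recovery(self):
        trace = erfc_edge_trace(w=2.5, x0=3.0)
        est = fit_edge_erf(trace)
        assert est.w == pytest.approx(2.5, rel=1e-6)
        assert est.x0 == pytest.approx(3.0, abs=1e-6)
        assert not est.flagged

    def test_noisy_recovery_within_two_percent(self):
        trace = erfc_edge_trace(w=1.0, step_frac=0.00586, noise=0.01, seed=7)
        est = fit_edge_erf(trace)
        assert est.w == pytest.approx(1.0, rel=0.02)

    def test_linear_ramp_is_flagged(self):
        x = np.linspace(0.0, 1.0, 256)
        est = fit_edge_erf(Trace(abscissa=x, intensity=x.copy(), normalized=True))
        assert est.flagged  # fitted edge wider than the scanned window

    def test_agrees_with_clip_method(self):
        trace = normalize_trace(erfc_edge_trace(w=0.8, step_frac=0.01))
        clip_w = radius_from_clip_width(locate_clip_crossings(trace).d_1090)
        fit_w = fit_edge_erf(trace).w
        assert fit_w == pytest.approx(clip_w, rel=0.01)


def hole_trace_seconds(dt_mid: float = 4e-3, scale: float = 10_000.0) -> Trace:
    """Time-domain full-hole trace whose 50% midpoints are dt_mid apart."""
    t = np.linspace(0.0, 0.1, 2048)
    w_s = 5e-4  # edge width in seconds (~10 samples, well resolved)
    left, right = 0.05 - dt_mid / 2, 0.05 + dt_mid / 2
    y = 0.5 * (special.erf(SQRT2 * (t - left) / w_s) - special.erf(SQRT2 * (t - right) / w_s))
    return Trace(abscissa=t, intensity=np.maximum(y, 0.0), abscissa_kind="time")


class TestCalibration:
    def test_scale_from_midpoint_separation(self):
        cal = calibrate_scale(hole_trace_seconds(), GridCalibration(hole_width_ref=40.0))
        assert cal.edge_separation_s == pytest.approx(4e-3, rel=1e-3)
        assert cal.scale == pytest.approx(10_000.0, rel=1e-3)

    def test_single_edge_rejected(self):
        t = np.linspace(0.0, 0.1, 1024)
        y = 0.5 * (1 + special.erf(SQRT2 * (t - 0.05) / 5e-4))
        trace = Trace(abscissa=t, intensity=y, abscissa_kind="time")
        with pytest.raises(CalibrationError):
            calibrate_scale(trace)

    def test_distance_trace_rejected(self):
        trace = erfc_edge_trace()
        with pytest.raises(CalibrationError):
            calibrate_scale(trace)


def test_trace_validation():
    with pytest.raises(ValueError):
        Trace(abscissa=np.arange(8.0), intensity=np.ones(8))  # too short
    with pytest.raises(ValueError):
        Trace(abscissa=np.zeros(32), intensity=np.ones(32))  # not increasing
    with pytest.raises(ValueError):
        Trace(abscissa=np.arange(32.0), intensity=-np.ones(32))  # negative raw


def test_analysis_config_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(clip_lo=0.9, clip_hi=0.1)
    with pytest.raises(ValueError):
        AnalysisConfig(conversion_factor=-1.0)
    with pytest.raises(ValueError):
        AnalysisConfig(method="bogus")
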