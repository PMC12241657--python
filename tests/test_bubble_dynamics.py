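"""Shelled-bubble radial dynamics: equilibrium, linearity, damping, scattering."""

import numpy as np
import pytest

from sonocell.acoustics import PCD_CONTEXT
from sonocell.bubble_dynamics import (
    BubbleParams,
    DrivingPulse,
    OscillationMetrics,
    RadiusTimeSeries,
    drive_for_mi,
    oscillation_metrics,
    scattered_pressure,
    simulate_radial_dynamics,
)

DRIVE_021 = drive_for_mi(0.21, 0.5e6, n_cycles=20)


def phago(mult: float) -> BubbleParams:
    return BubbleParams(compartment="phagocytosed", intracellular_viscosity_multiplier=mult)


def test_zero_drive_stays_at_rest(pcd_context):
    """With no acoustic forcing the bubble sits at its rest radius."""
    drive = DrivingPulse(frequency=0.5e6, pnp=0.0, n_cycles=20)
    series = simulate_radial_dynamics(BubbleParams(), drive, pcd_context)
    assert np.allclose(series.radius, BubbleParams().rest_radius, rtol=1e-9)


def test_linear_regime_amplitude_proportional_to_pressure(pcd_context):
    """At tiny drive the response is a drive-frequency sinusoid scaling
    linearly with pressure (harmonic-oscillator limit)."""
    # mid-elastic-branch bubble: smooth restoring force around R0
    bubble = BubbleParams(buckling_radius_ratio=0.97)
    amps = []
    for mi in (0.005, 0.01):
        series = simulate_radial_dynamics(
            bubble, drive_for_mi(mi, 0.5e6, n_cycles=20), pcd_context
        )
        driven = series.time <= 40e-6
        x = series.radius[driven] - bubble.rest_radius
        amps.append(0.5 * (x.max() - x.min()))
        # dominant spectral component at the drive frequency
        spec = np.abs(np.fft.rfft(x - x.mean()))
        freqs = np.fft.rfftfreq(x.size, 1.0 / pcd_context.sampling_rate)
        assert freqs[np.argmax(spec)] == pytest.approx(0.5e6, rel=0.05)
    assert amps[1] / amps[0] == pytest.approx(2.0, rel=0.02)


def test_free_bubble_compression_dominant(pcd_context):
    """A free buckled-shell bubble at MI 0.21 compresses more than it expands."""
    m = oscillation_metrics(simulate_radial_dynamics(BubbleParams(), DRIVE_021, pcd_context))
    assert abs(m.compression_pct) > m.expansion_pct


def test_solver_tolerance_convergence(pcd_context):
    """Halving the solver tolerance changes max |R| by < 0.1%."""
    a = simulate_radial_dynamics(BubbleParams(), DRIVE_021, pcd_context, rtol=1e-8)
    b = simulate_radial_dynamics(BubbleParams(), DRIVE_021, pcd_context, rtol=5e-9)
    assert abs(a.radius.max() - b.radius.max()) / b.radius.max() < 1e-3


def test_metrics_closed_forms(pcd_context):
    """Constant radius gives (0, 0); a 10% sinusoid gives (+10, -10)."""
    drive = DrivingPulse(frequency=0.5e6, pnp=0.0, n_cycles=20)
    t = np.arange(0, 50e-6, 1.0 / pcd_context.sampling_rate)
    r0 = 1.1e-6
    flat = RadiusTimeSeries(
        time=t, radius=np.full_like(t, r0), velocity=np.zeros_like(t),
        params=BubbleParams(), drive=drive, context=pcd_context,
    )
    m = oscillation_metrics(flat)
    assert m.expansion_pct == 0.0 and m.compression_pct == 0.0

    r = r0 * (1 + 0.1 * np.sin(2 * np.pi * 0.5e6 * t))
    wavy = RadiusTimeSeries(
        time=t, radius=r, velocity=np.zeros_like(t),
        params=BubbleParams(), drive=drive, context=pcd_context,
    )
    m = oscillation_metrics(wavy)
    assert m.expansion_pct == pytest.approx(10.0, abs=0.05)
    assert m.compression_pct == pytest.approx(-10.0, abs=0.05)


def test_metrics_reject_short_series(pcd_context):
    t = np.arange(8) / pcd_context.sampling_rate  # well under one period
    series = RadiusTimeSeries(
        time=t, radius=np.full_like(t, 1.1e-6), velocity=np.zeros_like(t),
        params=BubbleParams(), drive=DRIVE_021, context=pcd_context,
    )
    with pytest.raises(ValueError):
        oscillation_metrics(series)


def test_metrics_invariant_validation():
    with pytest.raises(ValueError):
        OscillationMetrics(expansion_pct=-5.0, compression_pct=-1.0)
    with pytest.raises(ValueError):
        OscillationMetrics(expansion_pct=1.0, compression_pct=-120.0)


def test_monotone_damping(pcd_context):
    """More intracellular damping never increases the expansion amplitude."""
    expansions = [
        oscillation_metrics(simulate_radial_dynamics(phago(m), DRIVE_021, pcd_context)).expansion_pct
        for m in (1.0, 5.0, 25.0, 100.0)
    ]
    assert np.all(np.diff(expansions) <= 1e-6)


def test_compression_only_regime_exists(pcd_context):
    """Some damping multiplier yields expansion < 3% with |compression| > 10%."""
    found = False
    for mult in (60.0, 70.0, 78.0, 85.0):
        m = oscillation_metrics(simulate_radial_dynamics(phago(mult), DRIVE_021, pcd_context))
        if m.expansion_pct < 3.0 and abs(m.compression_pct) > 10.0:
            found = True
            break
    assert found


def test_scattered_pressure_laws(pcd_context):
    """Constant R radiates nothing; amplitude follows 1/r; nonlinear
    oscillation radiates a second harmonic above the floor."""
    drive = DrivingPulse(frequency=0.5e6, pnp=0.0, n_cycles=20)
    t = np.arange(0, 50e-6, 1.0 / pcd_context.sampling_rate)
    flat = RadiusTimeSeries(
        time=t, radius=np.full_like(t, 1.1e-6), velocity=np.zeros_like(t),
        params=BubbleParams(), drive=drive, context=pcd_context,
    )
    assert np.allclose(scattered_pressure(flat, 1e-2, pcd_context), 0.0, atol=1e-12)

    series = simulate_radial_dynamics(BubbleParams(), DRIVE_021, pcd_context)
    p1 = scattered_pressure(series, 1e-2, pcd_context)
    p2 = scattered_pressure(series, 2e-2, pcd_context)
    assert np.allclose(p2, p1 / 2, rtol=1e-12)

    spec = np.abs(np.fft.rfft(p1))
    freqs = np.fft.rfftfreq(p1.size, 1.0 / pcd_context.sampling_rate)
    def band(f):
        return spec[(freqs > f - 0.05e6) & (freqs < f + 0.05e6)].max()
    floor = spec[(freqs > 4.2e6) & (freqs < 4.4e6)].max()
    assert band(1.0e6) > 10 * floor  # second harmonic well above floor

    with pytest.raises(ValueError):
        scattered_pressure(series, 5e-6, pcd_context)  # violates far field


def test_harmonic_ratio_vanishes_in_linear_limit(pcd_context):
    """Scattered harmonic-to-fundamental ratio goes to zero as pnp -> 0."""
    bubble = BubbleParams(buckling_radius_ratio=0.97)
    ratios = []
    for mi in (0.1, 0.02, 0.004):
        series = simulate_radial_dynamics(
            bubble, drive_for_mi(mi, 0.5e6, n_cycles=20), pcd_context
        )
        p = scattered_pressure(series, 1e-2, pcd_context)
        spec = np.abs(np.fft.rfft(p))
        freqs = np.fft.rfftfreq(p.size, 1.0 / pcd_context.sampling_rate)
        fund = spec[np.argmin(np.abs(freqs - 0.5e6))]
        harm = spec[np.argmin(np.abs(freqs - 1.0e6))]
        ratios.append(harm / fund)
    assert ratios[0] > ratios[1] > ratios[2]
    assert ratios[2] < 0.05


def test_free_bubble_requires_unit_multiplier():
    with pytest.raises(ValueError):
        BubbleParams(compartment="free", intracellular_viscosity_multiplier=2.0)
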