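"""Shared acoustic quantities: mechanical index, wavelength, diffraction limits.

All library-internal quantities are SI (metres, seconds, hertz, pascals).
The field's customary mixed units (MPa, MHz, µm, mm) appear only in
reporting dataclasses (:class:`MIValue`, :class:`ResolutionSpec`) and in
their constructors, so unit conversions happen exactly once, at the
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "AcousticContext",
    "MIValue",
    "ResolutionSpec",
    "wavelength",
    "mechanical_index",
    "pnp_for_mi",
    "diffraction_limits",
    "IMAGING_CONTEXT",
    "PCD_CONTEXT",
]


@dataclass(frozen=True)
class AcousticContext:
    """Medium and acquisition constants shared across the imaging chain.

    Parameters
    ----------
    sound_speed : float
        Speed of sound in the medium, m/s.
    center_frequency : float
        Transmit/drive center frequency, Hz.
    sampling_rate : float
        Receive sampling rate, Hz.  Must be at least 4x the center
        frequency so that the second harmonic remains representable.
    ambient_pressure : float
        Static ambient pressure, Pa.
    density : float
        Medium density, kg/m^3.
    """

    center_frequency: float
    sampling_rate: float
    sound_speed: float = 1540.0
    ambient_pressure: float = 101_325.0
    density: float = 1000.0

    def __post_init__(self) -> None:
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if self.sampling_rate < 4.0 * self.center_frequency:
            raise ValueError(
                "sampling_rate must be >= 4 x center_frequency "
                f"(got fs={self.sampling_rate:.3g} Hz for f0="
                f"{self.center_frequency:.3g} Hz)"
            )

    @property
    def wavelength(self) -> float:
        """Wavelength c/f0 in metres."""
        return self.sound_speed / self.center_frequency


def wavelength(context: AcousticContext) -> float:
    """Wavelength c/f0 of the context's center frequency, in metres."""
    return context.wavelength


@dataclass(frozen=True)
class MIValue:
    """Mechanical index with the pressure and frequency it was computed from.

    ``mi = pnp_mpa / sqrt(frequency_mhz)`` -- the regulatory proxy for
    cavitation likelihood.  Stored in the units the definition is written
    in (MPa, MHz).
    """

    mi: float
    pnp_mpa: float
    frequency_mhz: float

    def __post_init__(self) -> None:
        expected = self.pnp_mpa / math.sqrt(self.frequency_mhz)
        if abs(self.mi - expected) > 1e-12 * max(1.0, abs(expected)):
            raise ValueError(
                f"inconsistent MIValue: mi={self.mi!r} but "
                f"pnp/sqrt(f) = {expected!r}"
            )


def mechanical_index(pnp: float, frequency: float) -> MIValue:
    """Mechanical index from peak negative pressure and center frequency.

    Parameters
    ----------
    pnp : float
        Peak negative pressure in Pa (>= 0).
    frequency : float
        Center frequency in Hz (> 0).

    Returns
    -------
    MIValue
        ``mi = (pnp / 1e6) / sqrt(frequency / 1e6)``.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if pnp < 0:
        raise ValueError("peak negative pressure must be non-negative")
    pnp_mpa = pnp / 1e6
    f_mhz = frequency / 1e6
    return MIValue(mi=pnp_mpa / math.sqrt(f_mhz), pnp_mpa=pnp_mpa, frequency_mhz=f_mhz)


def pnp_for_mi(mi: float, frequency: float) -> float:
    """Peak negative pressure in Pa that yields ``mi`` at ``frequency`` (Hz).

    Exact inverse of :func:`mechanical_index`.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if mi < 0:
        raise ValueError("mi must be non-negative")
    return mi * math.sqrt(frequency / 1e6) * 1e6


@dataclass(frozen=True)
class ResolutionSpec:
    """Diffraction-limited resolution of a linear-array system.

    lateral = 1.44 * lambda * z / (2 alpha), axial = lambda * n_cycles / 2.
    Reported in the customary units (µm for resolutions and wavelength,
    mm for aperture and depth).
    """

    wavelength_um: float
    aperture_mm: float
    depth_mm: float
    n_cycles: float
    lateral_um: float
    axial_um: float

    def __post_init__(self) -> None:
        lat = 1.44 * self.wavelength_um * (self.depth_mm / self.aperture_mm)
        axi = self.wavelength_um * self.n_cycles / 2.0
        for name, got, want in (("lateral", self.lateral_um, lat), ("axial", self.axial_um, axi)):
            if abs(got - want) > 1e-9 * max(1.0, abs(want)):
                raise ValueError(f"inconsistent ResolutionSpec {name} limit")


def diffraction_limits(
    context: AcousticContext, aperture: float, depth: float, n_cycles: float
) -> ResolutionSpec:
    """Diffraction-limited lateral/axial resolution of a focused system.

    Parameters
    ----------
    context : AcousticContext
        Supplies sound speed and center frequency (lambda = c / f0).
    aperture : float
        Full aperture 2*alpha of the array, metres.
    depth : float
        Imaging depth z, metres.
    n_cycles : float
        Number of full cycles in the transmit pulse (a 4-half-cycle pulse
        counts as 2).

    Returns
    -------
    ResolutionSpec
        lateral = 1.44 * lambda * z / (2 alpha) and axial =
        lambda * n_cycles / 2, reported in µm.
    """
    if aperture <= 0:
        raise ValueError("aperture must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if n_cycles <= 0:
        raise ValueError("n_cycles must be positive")
    lam = context.wavelength
    lateral = 1.44 * lam * depth / aperture
    axial = lam * n_cycles / 2.0
    return ResolutionSpec(
        wavelength_um=lam * 1e6,
        aperture_mm=aperture * 1e3,
        depth_mm=depth * 1e3,
        n_cycles=n_cycles,
        lateral_um=lateral * 1e6,
        axial_um=axial * 1e6,
    )


#: Default context for the 15.625 MHz linear-array imaging experiments.
#: Sampling at 4x f0 keeps the second harmonic below Nyquist.
IMAGING_CONTEXT = AcousticContext(center_frequency=15.625e6, sampling_rate=62.5e6)

#: Default context for the 0.5 MHz passive-cavitation-detection experiments.
#: 20 MHz sampling leaves ample margin for the broadband band near 2.9 MHz.
PCD_CONTEXT = AcousticContext(center_frequency=0.5e6, sampling_rate=20e6)
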