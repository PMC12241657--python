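"""Passive cavitation detector (PCD) spectral dosimetry.

Acoustic emissions received during sonication are high-pass filtered
(default cut-off 0.6 MHz, protecting the receiver from the fundamental),
Fourier transformed, and summarised as three band doses defined relative
to the drive frequency f0:

* harmonic dose  -- mean magnitude over 2 f0    +/- 5 FFT bins,
* ultraharmonic  -- mean magnitude over 1.5 f0  +/- 5 FFT bins,
* broadband dose -- mean magnitude over 5.72 f0 +/- 5 FFT bins.

Elevated harmonics with quiet broadband indicate stable cavitation;
elevated broadband indicates inertial cavitation.  "Bin" means an FFT bin
of the record zero-padded to the next power of two, so the +/-5-bin rule
is reproducible for a fixed record length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal as sps

from .acoustics import AcousticContext, PCD_CONTEXT
from .bubble_dynamics import (
    BubbleParams,
    DrivingPulse,
    drive_for_mi,
    scattered_pressure,
    simulate_radial_dynamics,
)

__all__ = [
    "SpectralDose",
    "CavitationVerdict",
    "emission_spectrum",
    "band_doses",
    "classify_cavitation",
    "synthesize_pcd_record",
    "mi_sweep",
    "BAND_MULTIPLES",
]

#: Band centers as multiples of the drive frequency.
BAND_MULTIPLES = {"harmonic": 2.0, "ultraharmonic": 1.5, "broadband": 5.72}

#: Half-width of every dose band, in FFT bins.
BAND_HALF_WIDTH_BINS = 5


@dataclass
class SpectralDose:
    """FFT magnitude spectrum plus the three band doses.

    ``magnitude_db`` is referenced to the spectral maximum (display
    convention).  The band doses are referenced to 1 Pa so that doses
    from different records (e.g. bubble vs. no-bubble baseline) compare
    on a common absolute scale.  Doses are ``None`` until
    :func:`band_doses` fills them.
    """

    freqs: np.ndarray
    magnitude: np.ndarray
    magnitude_db: np.ndarray
    f0: float
    bin_width: float
    harmonic_dose: float | None = None
    ultraharmonic_dose: float | None = None
    broadband_dose: float | None = None

    def band_bins(self, multiple: float) -> np.ndarray:
        """Indices of the 11 bins centered on the bin nearest multiple*f0."""
        center = int(round(multiple * self.f0 / self.bin_width))
        idx = np.arange(center - BAND_HALF_WIDTH_BINS, center + BAND_HALF_WIDTH_BINS + 1)
        if idx[0] < 0 or idx[-1] >= self.freqs.size:
            raise ValueError(
                f"band at {multiple:g} f0 exceeds the spectrum "
                f"(bins {idx[0]}..{idx[-1]} of {self.freqs.size})"
            )
        return idx


@dataclass(frozen=True)
class CavitationVerdict:
    """Stable/inertial cavitation classification against a baseline."""

    state: Literal["none", "stable", "inertial"]
    harmonic_excess_db: float
    broadband_excess_db: float


def emission_spectrum(
    record: np.ndarray,
    context: AcousticContext,
    highpass_cutoff: float | None = 0.6e6,
    window: Literal["hann", "rect"] = "hann",
) -> SpectralDose:
    """Spectrum of a PCD record: zero-phase high-pass, window, FFT.

    Parameters
    ----------
    record : ndarray
        Received pressure record, >= 1024 samples at
        ``context.sampling_rate``.
    highpass_cutoff : float or None
        Zero-phase 4th-order Butterworth high-pass cut-off, Hz.  ``None``
        disables filtering.
    window : {"hann", "rect"}
        Taper applied before the FFT.

    Returns
    -------
    SpectralDose
        With magnitudes filled and doses unfilled; dB is referenced to
        the spectral maximum.
    """
    record = np.asarray(record, dtype=float)
    if record.ndim != 1 or record.size < 1024:
        raise ValueError("record must be a 1-D array of at least 1024 samples")
    fs = context.sampling_rate
    if context.center_frequency >= fs / 2:
        raise ValueError("f0 not representable at the sampling rate")
    x = record
    if highpass_cutoff is not None:
        sos = sps.butter(4, highpass_cutoff, btype="highpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    if window == "hann":
        x = x * sps.windows.hann(x.size, sym=False)
    n_fft = 1 << (x.size - 1).bit_length()
    spec = np.abs(np.fft.rfft(x, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    ref = spec.max()
    if ref == 0.0:
        ref = 1.0
    mag_db = 20.0 * np.log10(np.maximum(spec / ref, 1e-300))
    return SpectralDose(
        freqs=freqs,
        magnitude=spec,
        magnitude_db=mag_db,
        f0=context.center_frequency,
        bin_width=fs / n_fft,
    )


def band_doses(
    spectrum: SpectralDose,
    f0: float | None = None,
    dose_domain: Literal["db", "linear"] = "db",
) -> SpectralDose:
    """Fill harmonic / ultraharmonic / broadband doses of a spectrum.

    Each dose is the mean over the 11 bins centered on the nearest bin to
    the stated multiple of f0.  Averaging is on dB magnitudes by default
    (``dose_domain="linear"`` averages linear magnitudes, then converts).
    """
    out = replace(spectrum)
    if f0 is not None:
        out.f0 = f0
    nyquist = out.freqs[-1]
    doses = {}
    for name, mult in BAND_MULTIPLES.items():
        try:
            idx = out.band_bins(mult)
        except ValueError as exc:
            raise ValueError(f"{name} band exceeds Nyquist ({nyquist:.3g} Hz)") from exc
        if dose_domain == "db":
            mag_db_abs = 20.0 * np.log10(np.maximum(out.magnitude[idx], 1e-300))
            doses[name] = float(mag_db_abs.mean())
        else:
            doses[name] = float(20.0 * math.log10(max(out.magnitude[idx].mean(), 1e-300)))
    out.harmonic_dose = doses["harmonic"]
    out.ultraharmonic_dose = doses["ultraharmonic"]
    out.broadband_dose = doses["broadband"]
    return out


def classify_cavitation(
    dose: SpectralDose,
    baseline: SpectralDose,
    harmonic_threshold_db: float = 6.0,
    broadband_threshold_db: float = 6.0,
) -> CavitationVerdict:
    """Classify a dosed spectrum against a no-bubble baseline.

    Stable cavitation: harmonic excess above threshold with broadband at
    baseline.  Inertial cavitation: broadband excess above threshold.
    """
    if abs(dose.bin_width - baseline.bin_width) > 1e-9 * baseline.bin_width:
        raise ValueError("dose and baseline have different bin widths")
    for s in (dose, baseline):
        if s.harmonic_dose is None or s.broadband_dose is None:
            raise ValueError("doses must be filled (call band_doses first)")
    h_excess = dose.harmonic_dose - baseline.harmonic_dose
    b_excess = dose.broadband_dose - baseline.broadband_dose
    if b_excess > broadband_threshold_db:
        state = "inertial"
    elif h_excess > harmonic_threshold_db:
        state = "stable"
    else:
        state = "none"
    return CavitationVerdict(
        state=state, harmonic_excess_db=float(h_excess), broadband_excess_db=float(b_excess)
    )


def synthesize_pcd_record(
    bubble: BubbleParams | None,
    mi: float,
    context: AcousticContext = PCD_CONTEXT,
    n_cycles: int = 20,
    detector_distance: float = 10e-3,
    fundamental_leak: float = 1e-7,
    noise_floor: float = 0.07,
    broadband_noise: float = 0.0,
    record_duration: float = 80e-6,
    seed: int = 0,
) -> np.ndarray:
    """Simulated PCD receive record for one sonication.

    The record is the sum of a fundamental leak (the drive scaled by
    ``fundamental_leak``, as picked up by the detector), the bubble's
    far-field scattered pressure delayed by the detector distance (absent
    for a no-bubble control), white detector noise at ``noise_floor``
    (Pa RMS), and optionally extra broadband noise emulating inertial
    emissions.  Seeded and deterministic.
    """
    fs = context.sampling_rate
    n = int(round(record_duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    drive = drive_for_mi(
        mi, context.center_frequency, n_cycles=n_cycles, envelope="tapered"
    )
    drive = replace(drive, taper_cycles=3.0)
    record = fundamental_leak * drive.waveform(t)
    if bubble is not None and mi > 0:
        series = simulate_radial_dynamics(bubble, drive, context)
        p = scattered_pressure(series, detector_distance, context)
        delay = int(round(detector_distance / context.sound_speed * fs))
        stop = min(n, delay + p.size)
        record[delay:stop] += p[: stop - delay]
    record += rng.normal(0.0, noise_floor, n)
    if broadband_noise > 0.0:
        record += rng.normal(0.0, broadband_noise, n)
    return record


def mi_sweep(
    bubble: BubbleParams | None,
    mi_grid: np.ndarray,
    context: AcousticContext = PCD_CONTEXT,
    n_cycles: int = 20,
    n_reps: int = 4,
    seed: int = 0,
    **record_kwargs,
) -> pd.DataFrame:
    """Band doses versus mechanical index for one bubble parameterization.

    For each MI on the (ascending) grid, ``n_reps`` independent
    20-cycle sonication records are synthesized with and without the
    bubble (``bubble=None`` sweeps a no-bubble control against itself).
    Doses are averaged over the repeats -- the simulated analogue of
    repeating the acquisition over several dishes -- and the excesses
    over the no-bubble baseline are tabulated.
    """
    mi_grid = np.asarray(mi_grid, dtype=float)
    if np.any(np.diff(mi_grid) <= 0):
        raise ValueError("mi_grid must be strictly ascending")
    rows = []
    for i, mi in enumerate(mi_grid):
        doses = {"harmonic": [], "ultraharmonic": [], "broadband": []}
        bases = {"harmonic": [], "ultraharmonic": [], "broadband": []}
        last_dose = last_base = None
        for rep in range(n_reps):
            s = seed + 1000 * i + 2 * rep
            rec = synthesize_pcd_record(
                bubble, mi, context, n_cycles=n_cycles, seed=s, **record_kwargs
            )
            base = synthesize_pcd_record(
                None, mi, context, n_cycles=n_cycles, seed=s + 1, **record_kwargs
            )
            last_dose = band_doses(emission_spectrum(rec, context))
            last_base = band_doses(emission_spectrum(base, context))
            for name in doses:
                doses[name].append(getattr(last_dose, f"{name}_dose"))
                bases[name].append(getattr(last_base, f"{name}_dose"))
        mean_dose = replace(
            last_dose,
            harmonic_dose=float(np.mean(doses["harmonic"])),
            ultraharmonic_dose=float(np.mean(doses["ultraharmonic"])),
            broadband_dose=float(np.mean(doses["broadband"])),
        )
        mean_base = replace(
            last_base,
            harmonic_dose=float(np.mean(bases["harmonic"])),
            ultraharmonic_dose=float(np.mean(bases["ultraharmonic"])),
            broadband_dose=float(np.mean(bases["broadband"])),
        )
        verdict = classify_cavitation(mean_dose, mean_base)
        rows.append(
            {
                "mi": mi,
                "harmonic_db": mean_dose.harmonic_dose,
                "ultraharmonic_db": mean_dose.ultraharmonic_dose,
                "broadband_db": mean_dose.broadband_dose,
                "baseline_harmonic_db": mean_base.harmonic_dose,
                "baseline_broadband_db": mean_base.broadband_dose,
                "harmonic_excess_db": verdict.harmonic_excess_db,
                "broadband_excess_db": verdict.broadband_excess_db,
                "state": verdict.state,
            }
        )
    return pd.DataFrame(rows)
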