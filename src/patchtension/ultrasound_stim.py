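"""Hydrophone calibration, acoustic intensity, and ultrasound dose-response.

A calibrated hydrophone converts voltage to acoustic pressure through a
frequency-specific Pa-per-volt factor. Acoustic intensity at the patch is
computed from the peak pressure of the waveform as

    I = (p_peak * 0.707)^2 / Z * (1 / 100^2)   [W/cm^2]

i.e. RMS pressure squared over the characteristic acoustic impedance of water
(Z = 1.48e6 kg m^-2 s^-1), converted from W/m^2 to W/cm^2. The 0.707 literal
is the sinusoid peak-to-RMS factor and is kept as the literal constant so
outputs match the published arithmetic exactly. The reported value is the
intensity at the peak pressure of the burst and is labelled as such.

Ultrasound dose-response midpoints reuse the same Boltzmann machinery as the
tension analysis, in the acoustic-power domain; no channel energetics are
derivable from a power-domain fit (the coupling from power to membrane tension
is not part of the measurement), and the fit is flagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .gating_analysis import BoltzmannParams, fit_boltzmann

__all__ = [
    "RMS_FACTOR",
    "WATER_IMPEDANCE",
    "HydrophoneCalibration",
    "AcousticWaveform",
    "voltage_to_pressure",
    "intensity_from_pressure",
    "power_response_midpoint",
    "paired_radius_comparison",
]

#: Peak -> RMS factor for a sinusoidal waveform (kept as the literal 0.707).
RMS_FACTOR = 0.707

#: Characteristic acoustic impedance of water, kg m^-2 s^-1.
WATER_IMPEDANCE = 1.48e6

_M2_PER_CM2 = 1.0 / 100.0**2

POWER_UNITS = "W/cm^2"


@dataclass(frozen=True)
class HydrophoneCalibration:
    """Frequency-specific hydrophone sensitivity (Pa per volt)."""

    pa_per_volt: float
    frequency_mhz: float | None = None

    def __post_init__(self):
        if self.pa_per_volt <= 0:
            raise InvalidArgumentError("calibration must be positive Pa/V")


@dataclass(frozen=True)
class AcousticWaveform:
    """An acoustic-pressure time series with its derived intensity."""

    samples_pa: np.ndarray
    sample_rate_hz: float
    p_peak_pa: float
    intensity_w_cm2: float


def intensity_from_pressure(p_peak_pa: float, impedance: float = WATER_IMPEDANCE) -> float:
    """Acoustic intensity (W/cm^2) from peak pressure (Pa).

    ``I = (p * 0.707)^2 / Z / 100^2``; scales quadratically with pressure.
    """
    if p_peak_pa < 0:
        raise InvalidArgumentError("peak pressure must be >= 0")
    return (p_peak_pa * RMS_FACTOR) ** 2 / impedance * _M2_PER_CM2


def voltage_to_pressure(
    volts, sample_rate_hz: float, cal: HydrophoneCalibration
) -> AcousticWaveform:
    """Transform a hydrophone voltage trace into an acoustic-pressure waveform."""
    v = np.asarray(volts, dtype=float)
    samples = v * cal.pa_per_volt
    p_peak = float(np.max(np.abs(samples))) if samples.size else 0.0
    return AcousticWaveform(
        samples_pa=samples,
        sample_rate_hz=float(sample_rate_hz),
        p_peak_pa=p_peak,
        intensity_w_cm2=intensity_from_pressure(p_peak),
    )


def read_hydrophone_csv(path, cal: HydrophoneCalibration) -> AcousticWaveform:
    """Load a ``time_s, volts`` CSV and convert it to pressure."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 0.0
    return voltage_to_pressure(df["volts"].to_numpy(dtype=float), rate, cal)


def power_response_midpoint(points, seed: int = 0) -> BoltzmannParams:
    """Boltzmann midpoint of an acoustic-power dose-response.

    ``points`` is ``(power W/cm^2, I/Imax)`` pairs (array or DataFrame, as in
    :func:`patchtension.gating_analysis.fit_boltzmann`). The returned fit is in
    the power domain: midpoint and slope are in W/cm^2 and no energetics can
    be derived from them.
    """
    return fit_boltzmann(points, mode="global", stimulus_units=POWER_UNITS, seed=seed)


def paired_radius_comparison(records) -> pd.DataFrame:
    """Tidy table comparing patch radii across matched stimulation modes.

    ``records`` is an iterable of dicts with keys ``patch_id``, ``fraction``
    (the matched I/Imax), ``r_pressure_um`` and ``r_ultrasound_um``. When both
    stimuli act purely through membrane tension, matched activation implies
    matched tension and hence matched radius, so ``diff_um`` centers on zero.
    """
    df = pd.DataFrame(list(records))
    required = {"patch_id", "fraction", "r_pressure_um", "r_ultrasound_um"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"records lack columns: {sorted(missing)}")
    df["diff_um"] = df["r_ultrasound_um"] - df["r_pressure_um"]
    return df
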