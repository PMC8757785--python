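"""Pulsatile inlet flow waveforms.

A single-peak systolic pulse stands in for the patient's ECHO-derived inlet
velocity profile: a raised-cosine systole occupying one third of the cardiac
period followed by zero-flow diastole, rescaled exactly to the prescribed
cardiac output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: fraction of the period occupied by systole
SYSTOLE_FRACTION = 1.0 / 3.0


@dataclass
class FlowWaveform:
    """Periodic volumetric inlet flow rate.

    times : s, covering exactly one period (first sample 0, last ``period``)
    flow : m^3/s, with flow[0] == flow[-1] (periodicity)
    """

    times: np.ndarray
    flow: np.ndarray
    period: float
    heart_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.flow = np.asarray(self.flow, dtype=np.float64)
        if self.times.shape != self.flow.shape:
            raise ValueError("times and flow must have identical shape")
        if abs(self.period - 60.0 / self.heart_rate) > 1e-9:
            raise ValueError("period must equal 60 / heart_rate")
        if abs(self.times[0]) > 1e-12 or abs(self.times[-1] - self.period) > 1e-9:
            raise ValueError("samples must cover exactly one period")
        if abs(self.flow[0] - self.flow[-1]) > 1e-12:
            raise ValueError("waveform must be periodic (first == last sample)")

    def stroke_volume(self) -> float:
        """Trapezoidal volume per beat, m^3."""
        return float(np.trapezoid(self.flow, self.times))

    def cardiac_output(self) -> float:
        """Implied cardiac output, m^3/s (stroke volume x beat frequency)."""
        return self.stroke_volume() * self.heart_rate / 60.0

    def at(self, t) -> np.ndarray:
        """Flow at arbitrary times (periodic linear interpolation)."""
        tt = np.mod(np.asarray(t, dtype=np.float64), self.period)
        return np.interp(tt, self.times, self.flow)

    def derivative(self) -> np.ndarray:
        """dQ/dt at the sample times by periodic central differences."""
        n = len(self.times) - 1  # last sample repeats the first
        q = self.flow[:n]
        dt = self.times[1] - self.times[0]
        dq = (np.roll(q, -1) - np.roll(q, 1)) / (2.0 * dt)
        return np.append(dq, dq[0])

    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.flow))])


def generate_inlet_waveform(cardiac_output_l_min: float,
                            heart_rate_bpm: float,
                            n_samples: int = 200) -> FlowWaveform:
    """Generate a single-systolic-peak inlet waveform.

    The pulse is a raised cosine over the first third of the period and zero
    elsewhere, rescaled so the trapezoidal cycle integral times the heart
    rate reproduces ``cardiac_output_l_min`` (within 0.1%, exactly up to
    float rounding).

    Parameters
    ----------
    cardiac_output_l_min : cardiac output in litres per minute (> 0).
    heart_rate_bpm : heart rate in beats per minute (> 0).
    n_samples : samples over one period, >= 8.
    """
    if cardiac_output_l_min <= 0 or heart_rate_bpm <= 0:
        raise ValueError("cardiac output and heart rate must be positive")
    if n_samples < 8:
        raise ValueError("need at least 8 samples per period")
    period = 60.0 / heart_rate_bpm
    t = np.linspace(0.0, period, n_samples)
    t_sys = SYSTOLE_FRACTION * period
    shape = np.where(t < t_sys, 0.5 * (1.0 - np.cos(2.0 * np.pi * t / t_sys)), 0.0)
    shape[-1] = shape[0]
    target_per_beat = (cardiac_output_l_min * 1e-3 / 60.0) * period  # m^3/beat
    integral = np.trapezoid(shape, t)
    flow = shape * (target_per_beat / integral)
    return FlowWaveform(times=t, flow=flow, period=period,
                        heart_rate=heart_rate_bpm)
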