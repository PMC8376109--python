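"""Breath flow-rate traces and MRI trigger synchronization.

During imaging the subject inhales through a pneumotachograph while the
scanner emits a 5 V trigger pulse at the start of every dynamic image
acquisition; both channels are recorded on a common time base.  This module
parses such recordings, detects the trigger rising edges, and summarizes the
flow over each dynamic window (flagging windows where the subject has begun to
exhale, which are excluded from downstream comparison).

CSV dialect: header ``time_s,flow_mls,trigger_v``, comma-separated, UTF-8.
Flow is volumetric in mL·s⁻¹ with inhalation positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BreathTrace",
    "detect_triggers",
    "per_dynamic_flow",
    "DynamicFlowSummary",
    "synthetic_inhalation_trace",
]

CSV_COLUMNS = ("time_s", "flow_mls", "trigger_v")


@dataclass(frozen=True)
class BreathTrace:
    """Uniformly sampled flow-rate + trigger recording.

    time in s (strictly increasing, uniform step), flow_rate in mL·s⁻¹
    (positive = inhalation), trigger_voltage in V.
    """

    time: np.ndarray
    flow_rate: np.ndarray
    trigger_voltage: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.flow_rate, dtype=float)
        v = np.asarray(self.trigger_voltage, dtype=float)
        if not (t.ndim == f.ndim == v.ndim == 1 and len(t) == len(f) == len(v)):
            raise ValueError("all channels must be 1-D and the same length")
        if len(t) < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time must be uniformly sampled")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "flow_rate", f)
        object.__setattr__(self, "trigger_voltage", v)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def support(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def flow_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Linearly interpolated flow rate, mL·s⁻¹ (constant beyond the ends)."""
        return np.interp(t, self.time, self.flow_rate)

    def flow_m3s_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Interpolated flow rate in m³·s⁻¹ for use by the flow physics."""
        return np.asarray(self.flow_at(t)) * 1e-6

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "flow_mls": self.flow_rate,
                "trigger_v": self.trigger_voltage,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BreathTrace":
        df = pd.read_csv(path)
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"breath-trace CSV missing columns: {sorted(missing)}")
        return cls(
            time=df["time_s"].to_numpy(),
            flow_rate=df["flow_mls"].to_numpy(),
            trigger_voltage=df["trigger_v"].to_numpy(),
        )


def detect_triggers(trace: BreathTrace, threshold: float = 2.5) -> np.ndarray:
    """Times of rising edges where the trigger voltage crosses ``threshold`` upward.

    A crossing requires the previous sample strictly below and the current
    sample at or above the threshold, so a flat channel sitting exactly at the
    threshold produces no triggers.
    """
    v = trace.trigger_voltage
    rising = (v[:-1] < threshold) & (v[1:] >= threshold)
    return trace.time[1:][rising]


@dataclass(frozen=True)
class DynamicFlowSummary:
    """Per-dynamic mean flow and exhalation flag."""

    trigger_times: np.ndarray  # s
    mean_flow: np.ndarray  # mL/s over [trigger, trigger+duration]
    is_exhalation: np.ndarray  # mean flow < 0
    duration: float

    @property
    def retained(self) -> np.ndarray:
        """Indices of dynamics kept for comparison (inhalation only)."""
        return np.flatnonzero(~self.is_exhalation)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dynamic": np.arange(len(self.trigger_times)),
                "trigger_time_s": self.trigger_times,
                "mean_flow_mls": self.mean_flow,
                "exhalation": self.is_exhalation,
            }
        )


def per_dynamic_flow(
    trace: BreathTrace, triggers: np.ndarray, duration: float
) -> DynamicFlowSummary:
    """Mean flow over each dynamic acquisition window.

    A dynamic whose mean flow is negative is flagged as exhalation; such
    dynamics are excluded from the velocity comparison by default because the
    gas composition on exhalation is unknown.  Windows running past the end of
    the recording are truncated with a warning.
    """
    triggers = np.asarray(triggers, dtype=float)
    if duration <= 0:
        raise ValueError("duration must be positive")
    t0, t1 = trace.support
    if triggers.size and (triggers.min() < t0 or triggers.max() > t1):
        raise ValueError("trigger outside trace support")
    means = np.empty(len(triggers))
    for i, trig in enumerate(triggers):
        end = trig + duration
        if end > t1:
            warnings.warn(
                f"dynamic {i} window truncated at trace end ({end:.2f}s > {t1:.2f}s)",
                stacklevel=2,
            )
            end = t1
        sel = (trace.time >= trig) & (trace.time <= end)
        # ensure the interval ends contribute even between samples
        tt = np.unique(np.concatenate([[trig], trace.time[sel], [end]]))
        means[i] = np.trapezoid(trace.flow_at(tt), tt) / (end - trig)
    return DynamicFlowSummary(
        trigger_times=triggers,
        mean_flow=means,
        is_exhalation=means < 0,
        duration=duration,
    )


def synthetic_inhalation_trace(
    total_duration: float = 20.0,
    inhale_duration: float = 13.0,
    peak_flow: float = 80.0,
    ramp: float = 1.5,
    n_dynamics: int = 5,
    dynamic_duration: float = 3.1,
    first_trigger: float = 0.5,
    sample_rate: float = 200.0,
    exhale_flow: float = -150.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> BreathTrace:
    """Emulate a slow 1 L ¹²⁹Xe inhalation with scanner trigger pulses.

    The profile ramps up over ``ramp`` seconds, holds a plateau near
    ``peak_flow`` (default 80 mL·s⁻¹, the mean inhalation rate of the
    experiments), ramps down at the end of the inhalation, then reverses into
    exhalation.  Trigger pulses (0→5 V, 100 ms wide) mark dynamic starts.
    """
    t = np.arange(0.0, total_duration, 1.0 / sample_rate)
    flow = np.zeros_like(t)
    up = t < ramp
    flow[up] = peak_flow * t[up] / ramp
    plateau = (t >= ramp) & (t <= inhale_duration - ramp)
    flow[plateau] = peak_flow
    down = (t > inhale_duration - ramp) & (t <= inhale_duration)
    flow[down] = peak_flow * (inhale_duration - t[down]) / ramp
    ex = t > inhale_duration
    flow[ex] = exhale_flow * np.minimum(1.0, (t[ex] - inhale_duration) / ramp)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        flow = flow + rng.normal(0.0, noise_sigma, size=flow.shape)
    trig = np.zeros_like(t)
    for k in range(n_dynamics):
        start = first_trigger + k * dynamic_duration
        trig[(t >= start) & (t < start + 0.1)] = 5.0
    return BreathTrace(time=t, flow_rate=flow, trigger_voltage=trig)
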