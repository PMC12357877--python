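"""Step-ramp voltage command used by all laboratories.

The waveform mimics a ventricular action potential: from a −80 mV holding
potential the cell is stepped to −90 mV for 100 ms (the −10 mV test step used
to track input resistance), depolarized to +40 mV for 500 ms, then ramped
back down to −80 mV over 100 ms (−1.2 V/s).  Drug inhibition is measured at
the peak of the outward current elicited by the repolarizing ramp.  Sweeps
are delivered at 0.2 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SegmentationError


@dataclass(frozen=True)
class StepRampProtocol:
    """Segment durations (ms) and levels (mV) of the step-ramp command."""

    hold_mV: float = -80.0
    test_step_mV: float = -90.0
    depol_mV: float = 40.0
    pre_hold_ms: float = 100.0
    test_step_ms: float = 100.0
    inter_hold_ms: float = 100.0  # back at hold between step and depolarization
    depol_ms: float = 500.0
    ramp_ms: float = 100.0
    post_hold_ms: float = 100.0
    sampling_interval_s: float = 1e-4
    inter_sweep_interval_s: float = 5.0  # 0.2 Hz pacing

    def __post_init__(self) -> None:
        for name in ("pre_hold_ms", "test_step_ms", "inter_hold_ms",
                     "depol_ms", "ramp_ms", "post_hold_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")

    # --- segment boundaries in seconds from sweep start -------------------
    @property
    def step_window(self) -> tuple[float, float]:
        t0 = self.pre_hold_ms / 1e3
        return (t0, t0 + self.test_step_ms / 1e3)

    @property
    def depol_window(self) -> tuple[float, float]:
        t0 = (self.pre_hold_ms + self.test_step_ms + self.inter_hold_ms) / 1e3
        return (t0, t0 + self.depol_ms / 1e3)

    @property
    def ramp_window(self) -> tuple[float, float]:
        t0 = self.depol_window[1]
        return (t0, t0 + self.ramp_ms / 1e3)

    @property
    def holding_window(self) -> tuple[float, float]:
        return (0.0, self.pre_hold_ms / 1e3)

    @property
    def duration_s(self) -> float:
        return self.ramp_window[1] + self.post_hold_ms / 1e3

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration_s / self.sampling_interval_s)) + 1
        return np.arange(n) * self.sampling_interval_s

    def command_voltage(self, time_s: np.ndarray) -> np.ndarray:
        """Command voltage (mV) at each time point."""
        t = np.asarray(time_s, dtype=float)
        v = np.full(t.shape, self.hold_mV)
        s0, s1 = self.step_window
        d0, d1 = self.depol_window
        r0, r1 = self.ramp_window
        v[(t >= s0) & (t < s1)] = self.test_step_mV
        v[(t >= d0) & (t < d1)] = self.depol_mV
        ramp = (t >= r0) & (t < r1)
        v[ramp] = self.depol_mV + (self.hold_mV - self.depol_mV) * (t[ramp] - r0) / (r1 - r0)
        return v

    def window_slice(self, time_s: np.ndarray, window: tuple[float, float]) -> slice:
        """Index slice covering ``window``; raises if the sweep is too short."""
        lo, hi = window
        if time_s[0] > lo + 1e-12 or time_s[-1] < hi - 1e-12 - self.sampling_interval_s:
            raise SegmentationError(
                f"sweep [{time_s[0]:g}, {time_s[-1]:g}] s does not cover window "
                f"[{lo:g}, {hi:g}] s")
        i0 = int(np.searchsorted(time_s, lo - 1e-12))
        i1 = int(np.searchsorted(time_s, hi - 1e-12))
        if i1 <= i0:
            raise SegmentationError(f"empty window [{lo:g}, {hi:g}] s")
        return slice(i0, i1)


DEFAULT_PROTOCOL = StepRampProtocol()
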