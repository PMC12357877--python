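"""Per-sweep measurements, E-4031 subtraction and QC stability metrics.

Drug inhibition is measured at the outward peak of the current elicited by
the repolarizing voltage ramp.  The hERG-mediated (E-4031-sensitive)
component is isolated by subtracting the current recorded under a saturating
dose of the blocker E-4031 at the end of each recording, either trace-wise
(pointwise subtraction of the averaged E-4031 sweep, then peak extraction)
or peak-wise (subtraction of the mean E-4031 ramp peak); cells recorded
without an E-4031 phase use the absolute ramp amplitude.

Sign convention: outward current positive; the ramp peak is the maximum
(not the absolute maximum) in the ramp window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DegenerateCellError,
                     InsufficientDataError)
from .protocol import DEFAULT_PROTOCOL, StepRampProtocol
from .ted import CellExperiment, SweepRecord

#: number of final E-4031 sweeps averaged into the subtraction reference
E4031_REFERENCE_SWEEPS = 3
#: number of final in-phase sweeps averaged into a phase's reported amplitude
PHASE_SUMMARY_SWEEPS = 5


@dataclass
class SweepMeasurement:
    ramp_peak_pA: float
    peak_voltage_mV: float
    I_minus80_pA: float
    R_input_MOhm: float
    sweep_index: int = -1
    phase: str = ""


def measure_sweep(sweep: SweepRecord,
                  protocol: StepRampProtocol = DEFAULT_PROTOCOL,
                  sweep_index: int = -1, phase: str = "") -> SweepMeasurement:
    """Extract the per-sweep QC and amplitude measurements.

    * ramp peak: maximum current in the ramp window, with the command
      voltage at the argmax;
    * I(-80 mV): mean current over the pre-step holding window;
    * R_input: |test step| / |steady-state step deflection|, using the mean
      current over the second half of the -90 mV step (MOhm; infinite when
      the deflection is zero).
    """
    t = sweep.time_s
    hold = protocol.window_slice(t, protocol.holding_window)
    step = protocol.window_slice(t, protocol.step_window)
    ramp = protocol.window_slice(t, protocol.ramp_window)
    i_hold = float(sweep.current_pA[hold].mean())
    # steady state of the test step: second half of the step window
    half = (step.start + step.stop) // 2
    i_step = float(sweep.current_pA[half:step.stop].mean())
    dv = abs(protocol.hold_mV - protocol.test_step_mV)  # mV
    di = abs(i_step - i_hold)                           # pA
    r_input = float("inf") if di == 0 else 1e3 * dv / di  # mV/pA = GOhm
    k = int(np.argmax(sweep.current_pA[ramp]))
    return SweepMeasurement(
        ramp_peak_pA=float(sweep.current_pA[ramp][k]),
        peak_voltage_mV=float(sweep.voltage_mV[ramp][k]),
        I_minus80_pA=i_hold, R_input_MOhm=r_input,
        sweep_index=sweep_index, phase=phase)


def subtract_e4031(cell: CellExperiment, mode: str = "trace",
                   n_reference: int = E4031_REFERENCE_SWEEPS) -> pd.DataFrame:
    """hERG amplitude per non-e4031 sweep after E-4031 subtraction.

    mode "peak": ramp peak minus the mean E-4031 ramp peak; mode "trace":
    pointwise subtraction of the averaged E-4031 sweep before peak
    extraction; mode "none": absolute ramp peak (for cells recorded without
    an E-4031 phase).  The reference is the mean of the last ``n_reference``
    E-4031 sweeps.
    """
    if mode not in ("trace", "peak", "none"):
        raise ConfigurationError(f"unknown subtraction mode {mode!r}")
    proto = cell.protocol
    idx = [i for i, p in enumerate(cell.phase_per_sweep) if p != "e4031"]
    e4 = [i for i, p in enumerate(cell.phase_per_sweep) if p == "e4031"]
    if mode != "none" and not e4:
        raise ConfigurationError(
            f"cell {cell.cell_id}: subtraction mode {mode!r} requires an "
            "e4031 phase")
    ref_idx = e4[-n_reference:] if e4 else []
    rows = []
    if mode == "trace" and ref_idx:
        ref_trace = np.mean([cell.sweeps[i].current_pA for i in ref_idx], axis=0)
    for i in idx:
        sweep = cell.sweeps[i]
        ramp = proto.window_slice(sweep.time_s, proto.ramp_window)
        if mode == "trace":
            herg = float((sweep.current_pA - ref_trace)[ramp].max())
        elif mode == "peak":
            ref_peak = float(np.mean([
                measure_sweep(cell.sweeps[j], proto).ramp_peak_pA
                for j in ref_idx]))
            herg = measure_sweep(sweep, proto).ramp_peak_pA - ref_peak
        else:
            herg = measure_sweep(sweep, proto).ramp_peak_pA
        rows.append({"sweep_index": i, "phase": cell.phase_per_sweep[i],
                     "concentration_molar": cell.conc_per_sweep[i],
                     "herg_pA": herg})
    return pd.DataFrame(rows)


def fractional_inhibition(baseline_amp: float, drug_amp: float) -> float:
    """``1 - drug/baseline``; negative values (current increase) retained."""
    if baseline_amp <= 0:
        raise DegenerateCellError(
            f"baseline hERG amplitude {baseline_amp:g} pA is not positive")
    return 1.0 - drug_amp / baseline_amp


def phase_inhibition(cell: CellExperiment, mode: str = "trace",
                     last_n: int = PHASE_SUMMARY_SWEEPS) -> pd.DataFrame:
    """Fractional inhibition per drug phase of a cell.

    Baseline and per-phase drug amplitudes are the means of the last
    ``last_n`` in-phase hERG amplitudes after E-4031 subtraction.
    """
    herg = subtract_e4031(cell, mode=mode)
    veh = herg[herg.phase == "vehicle"]["herg_pA"].to_numpy()
    if veh.size == 0:
        raise DegenerateCellError(f"cell {cell.cell_id}: no vehicle phase")
    baseline = float(veh[-last_n:].mean())
    rows = []
    drug_part = herg[herg.phase == "drug"]
    for conc, grp in drug_part.groupby("concentration_molar", sort=True):
        amp = float(grp["herg_pA"].to_numpy()[-last_n:].mean())
        rows.append({"drug": cell.drug, "lab_id": cell.lab_id,
                     "cell_id": cell.cell_id, "concentration_molar": conc,
                     "inhibition": fractional_inhibition(baseline, amp)})
    return pd.DataFrame(rows)


def stability_percent_change(amplitudes) -> float:
    """Percent change between the first and fifth of the last five values.

    The QC stability metric: ``100 * (a_last - a_last-4) / a_last-4`` on the
    final five in-phase amplitudes (traces 20 s apart at 0.2 Hz pacing).
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 5:
        raise InsufficientDataError(
            f"stability metric needs >= 5 amplitudes, got {a.size}")
    first, fifth = a[-5], a[-1]
    return 100.0 * (fifth - first) / first


def cell_time_course(cell: CellExperiment, mode: str = "trace") -> pd.DataFrame:
    """Per-sweep time-course table for reporting.

    Columns: sweep_index, phase, ramp_peak_pA, herg_pA (NaN for e4031
    sweeps), I_minus80_pA, R_input_MOhm, peak_voltage_mV.
    """
    herg = subtract_e4031(cell, mode=mode)
    herg_map = dict(zip(herg["sweep_index"], herg["herg_pA"]))
    rows = []
    for i, sweep in enumerate(cell.sweeps):
        m = measure_sweep(sweep, cell.protocol, sweep_index=i,
                          phase=cell.phase_per_sweep[i])
        rows.append({
            "sweep_index": i, "phase": m.phase,
            "ramp_peak_pA": m.ramp_peak_pA,
            "herg_pA": herg_map.get(i, float("nan")),
            "I_minus80_pA": m.I_minus80_pA,
            "R_input_MOhm": m.R_input_MOhm,
            "peak_voltage_mV": m.peak_voltage_mV,
        })
    return pd.DataFrame(rows)


def cell_qc_summary(cell: CellExperiment, mode: str = "trace") -> dict:
    """Stability metrics for vehicle and each drug phase of a cell."""
    herg = subtract_e4031(cell, mode=mode)
    out: dict[str, float] = {}
    veh = herg[herg.phase == "vehicle"]["herg_pA"].to_numpy()
    out["n_control_traces"] = int(veh.size)
    out["control_stability_pct"] = (
        stability_percent_change(veh) if veh.size >= 5 else float("nan"))
    for conc, grp in herg[herg.phase == "drug"].groupby(
            "concentration_molar", sort=True):
        amps = grp["herg_pA"].to_numpy()
        out[f"drug_stability_pct@{conc:.3e}"] = (
            stability_percent_change(amps) if amps.size >= 5 else float("nan"))
    return out
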