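#!/usr/bin/env python
"""Sweep-level processing demo: TED-lite export, QC and inhibition.

Simulates whole-cell step-ramp recordings for one drug at four
concentrations (vehicle -> drug -> E-4031 phases, with leak, rundown and
noise), writes them as a TED-lite dataset, validates it, and runs the
trace-processing pipeline: per-sweep measurements, E-4031 subtraction,
per-cell fractional inhibition and stability QC.
"""

from pathlib import Path

import pandas as pd

from hergvar import pipeline, ted
from hergvar.protocol import StepRampProtocol
from hergvar.synthetic import PhaseSpec, SweepSimConfig, simulate_cell_recording

OUT = Path("results/trace_qc")
SEED = 42
IC50, NH = 1e-8, 1.0


def main() -> None:
    protocol = StepRampProtocol(sampling_interval_s=1e-3)
    cells = []
    for j, mult in enumerate((0.3, 1.0, 3.0, 10.0)):
        cfg = SweepSimConfig(
            phases=(PhaseSpec("vehicle", float("nan"), 8),
                    PhaseSpec("drug", IC50 * mult, 8),
                    PhaseSpec("e4031", float("nan"), 4)),
            protocol=protocol, herg_amplitude_pA=1200.0,
            leak_conductance_nS=1.5, rundown_per_sweep=0.002,
            noise_sd_pA=4.0, drug_ic50_molar=IC50, drug_nH=NH)
        cell = simulate_cell_recording(cfg, seed=SEED + j,
                                       cell_id=f"cell{j}", lab_id="LabDemo",
                                       drug="drugA")
        cell.experiment_id = "LabDemo:drugA"
        cells.append(cell)

    root = OUT / "ted"
    ted.write_dataset(ted.dataset_from_cells(cells), root)
    findings = ted.validate_dataset(root)
    print(f"TED-lite dataset at {root}: "
          f"{'valid' if not findings else findings}")

    cfg = pipeline.PipelineConfig(mode="ted", input_path=str(root),
                                  out_dir=str(OUT / "analysis"))
    report = pipeline.run_pipeline(cfg)
    print(f"processed {report.summary['n_cells']} cells")
    pts = pd.read_csv(OUT / "analysis" / "inhibition_points.csv")
    print(pts.to_string(index=False))
    print(f"per-cell time courses and QC -> {OUT / 'analysis'}")


if __name__ == "__main__":
    main()
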