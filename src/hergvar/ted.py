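"""TED-lite dataset IO: a manifest of experimental conditions plus one CSV
waveform file per sweep.

The dialect implemented here is deliberately small and fully documented
rather than a bit-exact copy of any deposited schema:

* ``manifest.csv`` — one row per sweep with columns
  ``experiment_id, lab_id, cell_id, drug_name, phase, nominal_concentration_molar,
  sweep_file, sweep_index, time_offset_s, temperature_C``.
  ``phase`` is one of ``vehicle``, ``drug``, ``e4031``; the concentration may be
  empty for vehicle sweeps.  Within a cell, ``sweep_index`` is strictly
  increasing and phases appear in the order vehicle → drug → e4031.
* one CSV per sweep with header ``time_s,voltage_mV,current_pA``; the time
  base starts at 0 s and sampling must be uniform (1 ns tolerance).
* ``metadata.json`` — format version and the protocol constants.

Comma separator, ``.`` decimal, UTF-8, mandatory header rows; concentrations
stored in molar using decimal scientific notation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MissingSweepError, SchemaError
from .protocol import DEFAULT_PROTOCOL, StepRampProtocol

FORMAT_VERSION = "ted-lite-1"

MANIFEST_COLUMNS = [
    "experiment_id", "lab_id", "cell_id", "drug_name", "phase",
    "nominal_concentration_molar", "sweep_file", "sweep_index",
    "time_offset_s", "temperature_C",
]

PHASES = ("vehicle", "drug", "e4031")
_PHASE_RANK = {"vehicle": 0, "drug": 1, "e4031": 2}

UNIFORMITY_TOL_S = 1e-9


@dataclass
class SweepRecord:
    """One stimulus repetition: time (s), command voltage (mV), current (pA)."""

    time_s: np.ndarray
    voltage_mV: np.ndarray
    current_pA: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        n = len(self.time_s)
        if len(self.voltage_mV) != n or len(self.current_pA) != n:
            raise FormatError("time, voltage and current columns differ in length")
        if n < 2:
            raise FormatError("a sweep needs at least two samples")
        dt = np.diff(self.time_s)
        if np.any(np.abs(dt - dt[0]) > UNIFORMITY_TOL_S):
            raise FormatError("non-uniform sampling interval")

    @property
    def sampling_interval_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def n_samples(self) -> int:
        return len(self.time_s)


@dataclass
class CellExperiment:
    """All sweeps recorded from one cell, in stimulation order.

    ``phase_per_sweep`` / ``conc_per_sweep`` run parallel to ``sweeps``;
    the concentration is NaN for vehicle and e4031 sweeps.
    """

    cell_id: str
    lab_id: str
    drug: str
    sweeps: list[SweepRecord]
    phase_per_sweep: list[str]
    conc_per_sweep: list[float]
    protocol: StepRampProtocol = field(default_factory=lambda: DEFAULT_PROTOCOL)
    experiment_id: str = ""
    temperature_C: float = 37.0

    def phases(self) -> list[str]:
        out: list[str] = []
        for p in self.phase_per_sweep:
            if p not in out:
                out.append(p)
        return out


@dataclass
class TedDataset:
    manifest: pd.DataFrame
    sweeps: dict[tuple[str, int], SweepRecord]
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str


# ---------------------------------------------------------------------------
# writing

def dataset_from_cells(cells: list[CellExperiment]) -> TedDataset:
    """Assemble a TED-lite dataset from in-memory cell experiments."""
    rows = []
    sweeps: dict[tuple[str, int], SweepRecord] = {}
    for cell in cells:
        for i, (sweep, phase, conc) in enumerate(
                zip(cell.sweeps, cell.phase_per_sweep, cell.conc_per_sweep)):
            fname = f"sweeps/{cell.cell_id}_{i:04d}.csv"
            rows.append({
                "experiment_id": cell.experiment_id or f"{cell.lab_id}:{cell.drug}",
                "lab_id": cell.lab_id,
                "cell_id": cell.cell_id,
                "drug_name": cell.drug,
                "phase": phase,
                "nominal_concentration_molar": conc,
                "sweep_file": fname,
                "sweep_index": i,
                "time_offset_s": i * cell.protocol.inter_sweep_interval_s,
                "temperature_C": cell.temperature_C,
            })
            sweeps[(cell.cell_id, i)] = sweep
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    proto = cells[0].protocol if cells else DEFAULT_PROTOCOL
    metadata = {"format_version": FORMAT_VERSION,
                "protocol": dataclasses.asdict(proto)}
    return TedDataset(manifest=manifest, sweeps=sweeps, metadata=metadata)


def write_dataset(dataset: TedDataset, root_path: str | Path) -> Path:
    """Write a dataset in the TED-lite dialect; returns the manifest path.

    All invariants are checked before any file is written.
    """
    findings = _validate_in_memory(dataset)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise SchemaError("; ".join(f"{f.code}: {f.message}" for f in errors))
    root = Path(root_path)
    (root / "sweeps").mkdir(parents=True, exist_ok=True)
    man = dataset.manifest.copy()
    man["nominal_concentration_molar"] = [
        "" if (isinstance(c, float) and math.isnan(c)) else f"{float(c):.9e}"
        for c in man["nominal_concentration_molar"]
    ]
    manifest_path = root / "manifest.csv"
    man.to_csv(manifest_path, index=False)
    with open(root / "metadata.json", "w") as fh:
        json.dump(dataset.metadata or {"format_version": FORMAT_VERSION}, fh, indent=1)
    for (_cell, idx), rec in dataset.sweeps.items():
        row = dataset.manifest[(dataset.manifest.cell_id == _cell)
                               & (dataset.manifest.sweep_index == idx)]
        fname = row.iloc[0]["sweep_file"]
        path = root / fname
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "time_s": rec.time_s,
            "voltage_mV": rec.voltage_mV,
            "current_pA": rec.current_pA,
        }).to_csv(path, index=False, float_format="%.17g")
    return manifest_path


# ---------------------------------------------------------------------------
# reading / validation

def _read_manifest(root: Path) -> pd.DataFrame:
    mpath = root / "manifest.csv"
    if not mpath.exists():
        raise MissingSweepError(f"no manifest file at {mpath}")
    man = pd.read_csv(mpath, dtype={"cell_id": str, "lab_id": str,
                                    "experiment_id": str, "drug_name": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise SchemaError(f"manifest is missing column(s): {', '.join(missing)}")
    man["nominal_concentration_molar"] = pd.to_numeric(
        man["nominal_concentration_molar"], errors="coerce")
    return man


def _manifest_findings(man: pd.DataFrame) -> list[Finding]:
    findings: list[Finding] = []
    bad_phase = sorted(set(man["phase"]) - set(PHASES))
    if bad_phase:
        findings.append(Finding("error", "bad-phase",
                                f"unknown phase label(s): {', '.join(map(str, bad_phase))}"))
        return findings
    dup = man.duplicated(subset=["cell_id", "sweep_index"])
    if dup.any():
        keys = man.loc[dup, ["cell_id", "sweep_index"]].itertuples(index=False)
        for cell, idx in sorted(set(map(tuple, keys))):
            findings.append(Finding("error", "duplicate-sweep",
                                    f"(cell {cell}, sweep {idx}) appears more than once"))
    for cell, grp in man.groupby("cell_id", sort=True):
        idx = grp["sweep_index"].to_numpy()
        if not np.all(np.diff(idx) > 0):
            findings.append(Finding("error", "sweep-order",
                                    f"cell {cell}: sweep_index not strictly increasing"))
        ranks = [_PHASE_RANK[p] for p in grp.sort_values("sweep_index")["phase"]]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            findings.append(Finding("error", "phase-order",
                                    f"cell {cell}: phases out of vehicle→drug→e4031 order"))
    return findings


def _read_sweep_file(path: Path) -> SweepRecord:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "voltage_mV", "current_pA"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing waveform column {col}")
    return SweepRecord(df["time_s"].to_numpy(),
                       df["voltage_mV"].to_numpy(),
                       df["current_pA"].to_numpy())


def read_dataset(root_path: str | Path) -> TedDataset:
    """Read and fully validate a TED-lite dataset.

    Raises :class:`SchemaError` for manifest problems,
    :class:`MissingSweepError` for dangling sweep references and
    :class:`FormatError` for malformed waveform files.
    """
    root = Path(root_path)
    man = _read_manifest(root)
    findings = _manifest_findings(man)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise SchemaError("; ".join(f"{f.code}: {f.message}" for f in errors))
    metadata: dict = {}
    meta_path = root / "metadata.json"
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
    sweeps: dict[tuple[str, int], SweepRecord] = {}
    for row in man.itertuples(index=False):
        path = root / row.sweep_file
        if not path.exists():
            raise MissingSweepError(f"manifest references missing sweep file: {path}")
        sweeps[(row.cell_id, int(row.sweep_index))] = _read_sweep_file(path)
    return TedDataset(manifest=man, sweeps=sweeps, metadata=metadata)


def _validate_in_memory(dataset: TedDataset) -> list[Finding]:
    findings = _manifest_findings(dataset.manifest)
    n_expected = {}
    for row in dataset.manifest.itertuples(index=False):
        key = (row.cell_id, int(row.sweep_index))
        if key not in dataset.sweeps:
            findings.append(Finding("error", "missing-sweep",
                                    f"no waveform for cell {key[0]} sweep {key[1]}"))
        else:
            n_expected[key] = dataset.sweeps[key].n_samples
    lengths = set(n_expected.values())
    if len(lengths) > 1:
        findings.append(Finding("warning", "ragged-lengths",
                                f"sweeps differ in length: {sorted(lengths)}"))
    return findings


def validate_dataset(root_path: str | Path) -> list[Finding]:
    """Validate a dataset on disk, returning findings instead of raising.

    The report enumerates every violated invariant; an empty report means the
    dataset is valid.  Findings are deterministic and order-stable.
    """
    root = Path(root_path)
    try:
        man = _read_manifest(root)
    except (MissingSweepError, SchemaError) as exc:
        return [Finding("error", "manifest", str(exc))]
    findings = _manifest_findings(man)
    lengths: dict[tuple[str, int], int] = {}
    for row in man.sort_values(["cell_id", "sweep_index"]).itertuples(index=False):
        path = root / row.sweep_file
        if not path.exists():
            findings.append(Finding("error", "missing-file",
                                    f"manifest references missing sweep file: {path}"))
            continue
        try:
            rec = _read_sweep_file(path)
        except (SchemaError, FormatError) as exc:
            findings.append(Finding("error", "bad-waveform", str(exc)))
            continue
        lengths[(row.cell_id, int(row.sweep_index))] = rec.n_samples
    if len(set(lengths.values())) > 1:
        findings.append(Finding("warning", "ragged-lengths",
                                f"sweeps differ in length: {sorted(set(lengths.values()))}"))
    return findings
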