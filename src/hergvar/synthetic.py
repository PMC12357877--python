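"""Synthetic data generators with known ground truth.

Four generators mirror the statistical structure of a multi-laboratory hERG
concentration-inhibition study:

* :func:`simulate_study` — per-experiment pIC50s under the two-way
  fixed-effects + residual-heterogeneity model
  ``pIC50_rec = drug + lab_offset + u + eps`` with ``u ~ N(0, tau_group^2)``
  and ``eps ~ N(0, sigma_rec^2)``, the per-record sigma drawn uniformly from a
  configurable range and recorded as the known within-experiment SD.
* :func:`simulate_concentration_response` — per-cell fractional inhibition
  values around a Hill curve, with additive Gaussian noise on the fraction
  scale (optionally clipped to [-0.1, 1.1] to mimic real over/under-shoot).
* :func:`simulate_cell_recording` — whole step-ramp sweeps: a bell-shaped
  hERG ramp current (peak near -30 mV on the repolarizing ramp), ohmic leak,
  geometric per-sweep rundown and Gaussian noise, across ordered
  vehicle → drug → e4031 phases.
* :func:`simulate_loss_samples` — bioanalysis triplicates whose expected
  percent loss follows the logistic loss-vs-LogP curve
  ``loss = 100 / (1 + exp((x50 - LogP)/dx))``.

Every generator is deterministic given its seed.

:func:`default_study_design` reproduces the real study's roster: five
laboratories, 28 drugs in two phases, blind repeats and extra repeat
experiments, for 145 experiments in total (Labs 1 and 4: 30; Lab 2: 36;
Lab 3: 16; Lab 5: 33), with one laboratory ("Lab 2") carrying a large
systematic offset for Phase 1 and the first half of Phase 2 that resolves
for the last seven drugs it tested ("Lab 2*").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidDesignError
from .exposure import LossRecord
from .hill import hill_fraction
from .protocol import DEFAULT_PROTOCOL, StepRampProtocol
from .ted import CellExperiment, SweepRecord


# ---------------------------------------------------------------------------
# study-level simulation

@dataclass(frozen=True)
class DrugSpec:
    name: str
    true_pic50: float  # -log10 molar
    true_nH: float
    logP: float
    phase: str = "phase1"


@dataclass(frozen=True)
class LabSpec:
    """One laboratory variance group.

    A physical laboratory whose residual behaviour changed mid-study may
    appear as two LabSpec entries sharing ``lab_id`` but with different
    ``group_label`` (and possibly different offsets).

    ``experiments`` lists (drug_name, repeat_flag) pairs, one per experiment.
    """

    lab_id: str
    offset: float  # pIC50 units, added to the drug's true value
    group_label: str
    experiments: tuple[tuple[str, bool], ...]


@dataclass(frozen=True)
class StudyDesign:
    drugs: tuple[DrugSpec, ...]
    labs: tuple[LabSpec, ...]
    tau: float | dict[str, float] = 0.18
    sigma_range: tuple[float, float] = (0.02, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise InvalidDesignError("duplicate drug names")
        for d in self.drugs:
            if d.true_nH <= 0:
                raise InvalidDesignError(f"{d.name}: true_nH must be > 0")
        taus = (self.tau.values() if isinstance(self.tau, dict) else [self.tau])
        if any(t < 0 for t in taus):
            raise InvalidDesignError("tau must be >= 0")
        lo, hi = self.sigma_range
        if lo < 0 or hi < lo:
            raise InvalidDesignError("sigma_range must satisfy 0 <= lo <= hi")
        known = set(names)
        for lab in self.labs:
            if not lab.experiments:
                raise InvalidDesignError(f"{lab.lab_id}/{lab.group_label}: no experiments")
            for drug, _rep in lab.experiments:
                if drug not in known:
                    raise InvalidDesignError(f"{lab.lab_id}: unknown drug {drug!r}")

    def tau_for(self, group_label: str) -> float:
        if isinstance(self.tau, dict):
            return self.tau[group_label]
        return self.tau


def simulate_study(design: StudyDesign,
                   seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one multi-lab study; returns (records, truth).

    ``records`` carries the columns the variability analyses consume
    (drug_id, lab_id, experiment_id, pic50, sd_pic50, group_label, phase,
    repeat); ``truth`` additionally stores the generating components.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    drug_map = {d.name: d for d in design.drugs}
    rec_rows, truth_rows = [], []
    for lab in design.labs:
        tau_g = design.tau_for(lab.group_label)
        for k, (drug_name, repeat) in enumerate(lab.experiments):
            drug = drug_map[drug_name]
            lo, hi = design.sigma_range
            sigma = float(rng.uniform(lo, hi))
            u = float(rng.normal(0.0, tau_g)) if tau_g > 0 else 0.0
            eps = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
            pic50 = drug.true_pic50 + lab.offset + u + eps
            exp_id = f"{lab.group_label}:{drug_name}:{k}"
            rec_rows.append({
                "drug_id": drug_name, "lab_id": lab.lab_id,
                "experiment_id": exp_id, "pic50": pic50, "sd_pic50": sigma,
                "group_label": lab.group_label, "phase": drug.phase,
                "repeat": repeat,
            })
            truth_rows.append({
                "experiment_id": exp_id, "drug_id": drug_name,
                "lab_id": lab.lab_id, "group_label": lab.group_label,
                "true_pic50": drug.true_pic50, "lab_offset": lab.offset,
                "tau_group": tau_g, "u": u, "eps": eps, "sigma": sigma,
            })
    return pd.DataFrame(rec_rows), pd.DataFrame(truth_rows)


# 28 drugs with literature-plausible potencies, Hill slopes and LogP values.
_PHASE1 = [
    # name, true_pic50, nH, logP
    ("ranolazine", 4.6, 0.9, 2.8), ("terfenadine", 7.6, 0.9, 7.1),
    ("dofetilide", 8.3, 1.0, 1.8), ("chlorpromazine", 5.8, 1.0, 5.2),
    ("verapamil", 6.8, 1.0, 3.8), ("metoprolol", 3.9, 0.9, 1.9),
    ("tamoxifen", 6.0, 0.8, 7.1), ("ondansetron", 6.0, 1.0, 2.4),
    ("cisapride", 7.7, 0.9, 3.9), ("clozapine", 5.6, 1.0, 3.2),
    ("pimozide", 7.7, 0.8, 6.3), ("sotalol", 4.0, 0.9, 0.2),
    ("azimilide", 6.3, 0.9, 3.1), ("disopyramide", 4.9, 1.0, 2.6),
]
_PHASE2 = [
    ("astemizole", 8.6, 0.9, 6.0), ("bepridil", 6.8, 1.0, 6.1),
    ("vandetanib", 6.4, 1.0, 4.9), ("ibutilide", 7.8, 0.9, 4.2),
    ("pitolisant", 5.8, 1.0, 4.0), ("domperidone", 7.0, 1.0, 3.9),
    ("droperidol", 7.2, 1.0, 3.5), ("quinine", 4.6, 0.9, 3.4),
    ("hydrodolasetron", 5.3, 1.0, 2.5), ("clarithromycin", 4.4, 1.0, 3.2),
    ("moxifloxacin", 4.0, 1.0, 0.0), ("diltiazem", 4.9, 0.9, 2.8),
    ("risperidone", 6.5, 1.0, 3.5), ("mexiletine", 4.3, 0.9, 2.2),
]

# The seven Phase 2 drugs Lab 2 tested first (systematic offset present) and
# the seven it tested last (offset resolved).
LAB2_FIRST7 = ("astemizole", "risperidone", "pitolisant", "hydrodolasetron",
               "quinine", "diltiazem", "moxifloxacin")
LAB2_LAST7 = ("ibutilide", "bepridil", "domperidone", "droperidol",
              "vandetanib", "clarithromycin", "mexiletine")

BLIND_REPEAT_DRUGS = ("dofetilide", "ondansetron")

# Averaged pIC50 lab offsets (pIC50_lab - group average), negated caption
# values of the study's across-lab comparison figures.
DEFAULT_LAB_OFFSETS = {
    "Lab1": 0.16, "Lab2": -0.65, "Lab2*": 0.11,
    "Lab3": 0.15, "Lab4": 0.20, "Lab5": 0.14,
}


def default_drugs() -> tuple[DrugSpec, ...]:
    return tuple(
        [DrugSpec(n, p, h, l, "phase1") for n, p, h, l in _PHASE1]
        + [DrugSpec(n, p, h, l, "phase2") for n, p, h, l in _PHASE2])


def default_study_design(tau: float | dict[str, float] = 0.18,
                         sigma_range: tuple[float, float] = (0.02, 0.15),
                         seed: int = 0,
                         offsets: dict[str, float] | None = None) -> StudyDesign:
    """The 145-experiment roster of the five-laboratory study."""
    off = dict(DEFAULT_LAB_OFFSETS)
    if offsets:
        off.update(offsets)
    p1 = [n for n, *_ in _PHASE1]
    p2 = [n for n, *_ in _PHASE2]
    all28 = p1 + p2
    repeats = [(d, True) for d in BLIND_REPEAT_DRUGS]

    def initial(drugs):
        return [(d, False) for d in drugs]

    labs = (
        LabSpec("Lab1", off["Lab1"], "Lab1",
                tuple(initial(all28) + repeats)),                    # 30
        LabSpec("Lab2", off["Lab2"], "Lab2",
                tuple(initial(p1) + initial(list(LAB2_FIRST7)) + repeats
                      + [("ranolazine", True)] * 3
                      + [("metoprolol", True), ("clozapine", True),
                         ("sotalol", True)])),                       # 29
        LabSpec("Lab2", off["Lab2*"], "Lab2*",
                tuple(initial(list(LAB2_LAST7)))),                   # 7
        LabSpec("Lab3", off["Lab3"], "Lab3",
                tuple(initial(p1) + repeats)),                       # 16
        LabSpec("Lab4", off["Lab4"], "Lab4",
                tuple(initial(all28) + repeats)),                    # 30
        LabSpec("Lab5", off["Lab5"], "Lab5",
                tuple(initial(all28) + repeats
                      + [("metoprolol", True)] * 2
                      + [("astemizole", True)])),                    # 33
    )
    return StudyDesign(drugs=default_drugs(), labs=labs, tau=tau,
                       sigma_range=sigma_range, seed=seed)


# ---------------------------------------------------------------------------
# concentration-response panels

def simulate_concentration_response(ic50: float, nH: float,
                                    concentrations: list[float] | np.ndarray,
                                    n_cells: int, noise_sd: float, seed: int,
                                    clip: tuple[float, float] | None = (-0.1, 1.1),
                                    drug: str = "drug",
                                    lab_id: str = "lab") -> pd.DataFrame:
    """Per-cell fractional inhibition around a Hill curve."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise InvalidDesignError("empty concentration list")
    if ic50 <= 0 or nH <= 0 or np.any(conc <= 0) or noise_sd < 0 or n_cells < 1:
        raise InvalidDesignError("ic50, nH, concentrations must be > 0; "
                                 "noise_sd >= 0; n_cells >= 1")
    rng = np.random.default_rng(seed)
    truth = hill_fraction(ic50, nH, conc)
    rows = []
    for cell in range(n_cells):
        y = truth + (rng.normal(0.0, noise_sd, size=conc.size)
                     if noise_sd > 0 else 0.0)
        if clip is not None and noise_sd > 0:
            y = np.clip(y, clip[0], clip[1])
        for c, v in zip(conc, y):
            rows.append({"drug": drug, "lab_id": lab_id,
                         "cell_id": f"cell{cell}",
                         "concentration_molar": c, "inhibition": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweep-level simulation

@dataclass(frozen=True)
class PhaseSpec:
    label: str  # "vehicle" | "drug" | "e4031"
    concentration_molar: float  # NaN for vehicle / e4031
    n_sweeps: int


@dataclass(frozen=True)
class SweepSimConfig:
    """Phenomenological cell model for the step-ramp protocol.

    The hERG component is a bell-shaped function of the command voltage
    during the depolarization and ramp (maximal near ``peak_voltage_mV`` on
    the ramp, normalised so the noise-free vehicle ramp peak equals
    ``herg_amplitude_pA`` exactly); leak is ohmic; rundown is geometric per
    sweep.  During drug phases the hERG component is scaled by
    ``1 - Hill(ic50, nH, conc)`` and during the e4031 phase by 0.
    """

    phases: tuple[PhaseSpec, ...]
    protocol: StepRampProtocol = field(default_factory=lambda: DEFAULT_PROTOCOL)
    herg_amplitude_pA: float = 1000.0
    peak_voltage_mV: float = -30.0
    bell_width_mV: float = 18.0
    leak_conductance_nS: float = 0.0
    leak_reversal_mV: float = 0.0
    rundown_per_sweep: float = 0.0  # fraction lost per sweep
    noise_sd_pA: float = 0.0
    drug_ic50_molar: float = float("nan")
    drug_nH: float = 1.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise InvalidDesignError("at least one phase required")
        for ph in self.phases:
            if ph.n_sweeps < 1:
                raise InvalidDesignError(f"phase {ph.label}: n_sweeps must be >= 1")
            if ph.label not in ("vehicle", "drug", "e4031"):
                raise InvalidDesignError(f"unknown phase label {ph.label!r}")
            if ph.label == "drug" and not (ph.concentration_molar > 0):
                raise InvalidDesignError("drug phase needs a positive concentration")
        if any(ph.label == "drug" for ph in self.phases) and \
                not (self.drug_ic50_molar > 0):
            raise InvalidDesignError("drug phases require drug_ic50_molar > 0")
        if not (0 <= self.rundown_per_sweep < 1):
            raise InvalidDesignError("rundown_per_sweep must be in [0, 1)")
        if not (-80 <= self.peak_voltage_mV <= 40):
            raise InvalidDesignError("peak_voltage_mV must lie on the ramp")


def _herg_shape(config: SweepSimConfig) -> np.ndarray:
    """Unit-peak hERG waveform over the sweep time grid."""
    proto = config.protocol
    t = proto.time_grid()
    v = proto.command_voltage(t)
    active = np.zeros(t.shape)
    d0, _ = proto.depol_window
    _, r1 = proto.ramp_window
    win = (t >= d0) & (t < r1)
    bell = np.exp(-0.5 * ((v - config.peak_voltage_mV) / config.bell_width_mV) ** 2)
    active[win] = bell[win]
    ramp = proto.window_slice(t, proto.ramp_window)
    peak = active[ramp].max()
    return active / peak


def simulate_cell_recording(config: SweepSimConfig, seed: int,
                            cell_id: str = "cell0", lab_id: str = "lab",
                            drug: str = "drug") -> CellExperiment:
    """Generate ordered sweeps across the configured phases."""
    rng = np.random.default_rng(seed)
    proto = config.protocol
    t = proto.time_grid()
    v = proto.command_voltage(t)
    leak = config.leak_conductance_nS * (v - config.leak_reversal_mV)
    shape = _herg_shape(config)
    sweeps, phases, concs = [], [], []
    sweep_no = 0
    for ph in config.phases:
        if ph.label == "vehicle":
            inhib = 0.0
        elif ph.label == "drug":
            inhib = hill_fraction(config.drug_ic50_molar, config.drug_nH,
                                  ph.concentration_molar)
        else:  # e4031: complete block
            inhib = 1.0
        for _ in range(ph.n_sweeps):
            scale = (1.0 - inhib) * (1.0 - config.rundown_per_sweep) ** sweep_no
            current = leak + config.herg_amplitude_pA * scale * shape
            if config.noise_sd_pA > 0:
                current = current + rng.normal(0.0, config.noise_sd_pA, size=t.size)
            sweeps.append(SweepRecord(t.copy(), v.copy(), current))
            phases.append(ph.label)
            concs.append(ph.concentration_molar if ph.label == "drug" else float("nan"))
            sweep_no += 1
    return CellExperiment(cell_id=cell_id, lab_id=lab_id, drug=drug,
                          sweeps=sweeps, phase_per_sweep=phases,
                          conc_per_sweep=concs, protocol=proto)


# ---------------------------------------------------------------------------
# bioanalysis loss samples

def expected_percent_loss(logP: float, x50: float, dx: float) -> float:
    """Logistic loss-vs-LogP curve, bounded in [0, 100]."""
    if dx == 0:
        raise InvalidDesignError("dx must be nonzero")
    return 100.0 / (1.0 + math.exp((x50 - logP) / dx))


def simulate_loss_samples(logP: float, x50: float, dx: float, cv: float,
                          n: int, seed: int,
                          nominal_molar: float = 1e-6,
                          drug: str = "drug", lab_id: str = "lab") -> LossRecord:
    """Starting/final bioanalysis replicates with multiplicative noise."""
    if n < 1:
        raise InvalidDesignError("n must be >= 1")
    if cv < 0:
        raise InvalidDesignError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    loss = expected_percent_loss(logP, x50, dx) / 100.0
    start = nominal_molar * np.ones(n)
    final = nominal_molar * (1.0 - loss) * np.ones(n)
    if cv > 0:
        start = start * (1.0 + rng.normal(0.0, cv, size=n))
        final = final * (1.0 + rng.normal(0.0, cv, size=n))
    return LossRecord(drug=drug, lab_id=lab_id,
                      nominal_concentration_molar=nominal_molar,
                      starting_molar=start, final_molar=final, logP=logP)
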