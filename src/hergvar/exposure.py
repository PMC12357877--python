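"""Drug-exposure correction for nonspecific binding loss.

Nominal bath concentrations in manual patch-clamp experiments can overstate
the concentration the cell actually sees, because hydrophobic drugs bind to
perfusion tubing and chamber plastics.  Loss is quantified from bioanalysis
triplicates taken before (``starting``) and after (``final``) delivery to the
recording chamber: ``fractional loss = 1 - mean(final)/mean(starting)``.
Nominal concentrations are then multiplied by ``1 - loss``, either with the
loss averaged across all tested concentrations of a drug (default) or, for
drugs with concentration-dependent loss, per concentration.

Across drugs, percent loss rises with hydrophobicity (LogP) along a logistic
curve ``loss = 100 / (1 + exp((x50 - LogP)/dx))`` whose midpoint ``x50`` is
the LogP at which half the drug is lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitInputError


@dataclass
class FractionalLoss:
    """Result of one triplicate loss computation."""

    value: float  # clamped to [0, 1]
    raw: float    # unclamped 1 - mean(final)/mean(starting)
    negative_flagged: bool  # final > starting (assay noise); clamped to 0

    def __float__(self) -> float:
        return self.value


@dataclass
class LossRecord:
    """Bioanalysis record for one (drug, lab, nominal concentration)."""

    drug: str
    lab_id: str
    nominal_concentration_molar: float
    starting_molar: np.ndarray
    final_molar: np.ndarray
    logP: float = float("nan")

    @property
    def fractional_loss(self) -> float:
        return fractional_loss(self.starting_molar, self.final_molar).value

    @property
    def percent_loss(self) -> float:
        return 100.0 * self.fractional_loss


def fractional_loss(starting, final) -> FractionalLoss:
    """Fractional drug loss from replicate measurements.

    ``1 - mean(final)/mean(starting)``, clamped to [0, 1].  A negative raw
    value (final above starting, i.e. assay noise) is clamped to 0 and
    flagged: a negative loss would push the corrected concentration above
    nominal, which the correction never does.
    """
    s = np.asarray(starting, dtype=float)
    f = np.asarray(final, dtype=float)
    if s.size == 0 or f.size == 0:
        raise FitInputError("starting and final replicates must be non-empty")
    if np.any(s <= 0) or np.any(f <= 0):
        raise FitInputError("concentrations must be positive")
    raw = 1.0 - f.mean() / s.mean()
    clamped = min(max(raw, 0.0), 1.0)
    return FractionalLoss(value=clamped, raw=raw, negative_flagged=raw < 0)


def correct_concentrations(nominals, losses, mode: str = "averaged") -> np.ndarray:
    """Apply loss correction to nominal concentrations.

    mode="averaged": every nominal is multiplied by ``1 - mean(losses)``
    (also the rule for blind-repeat experiments whose nominals differ from
    the ones the losses were measured at).  mode="per_concentration":
    elementwise, requiring one loss per nominal.
    """
    nom = np.asarray(nominals, dtype=float)
    loss = np.asarray([float(l) for l in np.atleast_1d(losses)], dtype=float)
    if np.any((loss < 0) | (loss > 1)):
        raise FitInputError("losses must lie in [0, 1]")
    if mode == "averaged":
        return nom * (1.0 - loss.mean())
    if mode == "per_concentration":
        if loss.size != nom.size:
            raise FitInputError(
                f"per_concentration mode needs one loss per nominal "
                f"({loss.size} losses for {nom.size} nominals)")
        return nom * (1.0 - loss)
    raise FitInputError(f"unknown correction mode {mode!r}")


@dataclass
class SigmoidFit:
    """Least-squares fit of percent loss vs LogP."""

    x50: float
    dx: float
    x50_ci: tuple[float, float]
    dx_ci: tuple[float, float]
    residual_sd: float
    n_points: int
    converged: bool
    extrapolated: bool = False  # x50 beyond the observed LogP range
    message: str = ""

    def predict(self, logp) -> np.ndarray:
        x = np.asarray(logp, dtype=float)
        return 100.0 / (1.0 + np.exp((self.x50 - x) / self.dx))


def _loss_sigmoid(x, x50, dx):
    return 100.0 / (1.0 + np.exp((x50 - x) / dx))


def fit_loss_vs_logp(logp, percent_loss) -> SigmoidFit:
    """Fit ``loss = 100/(1 + exp((x50 - LogP)/dx))`` by least squares.

    Asymptotes are fixed at 0 and 100.  Initialised at x50 = median LogP,
    dx = 1, with dx bounded in (0, 10].  Non-convergence returns a
    ``converged=False`` result rather than raising.
    """
    x = np.asarray(logp, dtype=float)
    y = np.asarray(percent_loss, dtype=float)
    if x.size != y.size:
        raise FitInputError("logp and percent_loss differ in length")
    if x.size < 4:
        raise FitInputError("need at least 4 (LogP, loss) points")
    x50_0 = float(np.median(x))
    lo = [x.min() - 50.0, 1e-6]
    hi = [x.max() + 50.0, 10.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                _loss_sigmoid, x, y, p0=[x50_0, 1.0], bounds=(lo, hi),
                maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return SigmoidFit(float("nan"), float("nan"),
                          (float("nan"), float("nan")),
                          (float("nan"), float("nan")),
                          float("nan"), int(x.size), False, message=str(exc))
    resid = y - _loss_sigmoid(x, *popt)
    dof = max(x.size - 2, 1)
    s = float(np.sqrt((resid ** 2).sum() / dof))
    se = np.sqrt(np.diag(pcov))
    tq = stats.t.ppf(0.975, dof)
    x50, dx = popt
    return SigmoidFit(
        x50=float(x50), dx=float(dx),
        x50_ci=(float(x50 - tq * se[0]), float(x50 + tq * se[0])),
        dx_ci=(float(dx - tq * se[1]), float(dx + tq * se[1])),
        residual_sd=s, n_points=int(x.size), converged=True,
        extrapolated=bool(x50 > x.max() or x50 < x.min()),
    )


def losses_from_bioanalysis(table) -> "pd.DataFrame":
    """Per-(drug, lab, nominal) loss from a long-format bioanalysis table.

    Expected columns: drug, lab_id, nominal_concentration_molar,
    replicate_index, sample_type in {starting, final},
    measured_concentration_molar.
    """
    import pandas as pd

    required = {"drug", "lab_id", "nominal_concentration_molar",
                "sample_type", "measured_concentration_molar"}
    missing = required - set(table.columns)
    if missing:
        raise FitInputError(f"bioanalysis table missing columns: {sorted(missing)}")
    rows = []
    for (drug, lab, nom), grp in table.groupby(
            ["drug", "lab_id", "nominal_concentration_molar"], sort=True):
        start = grp.loc[grp.sample_type == "starting",
                        "measured_concentration_molar"].to_numpy()
        final = grp.loc[grp.sample_type == "final",
                        "measured_concentration_molar"].to_numpy()
        fl = fractional_loss(start, final)
        rows.append({"drug": drug, "lab_id": lab,
                     "nominal_concentration_molar": nom,
                     "fractional_loss": fl.value,
                     "negative_flagged": fl.negative_flagged})
    return pd.DataFrame(rows)
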