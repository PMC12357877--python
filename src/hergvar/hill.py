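"""Variable-slope Hill fitting of concentration-inhibition data.

The model is ``inhibition = 1 / (1 + (IC50/[drug])^nH)``.  Fitting is done on
the log10-concentration axis with parameters (pIC50, log nH), which makes the
problem well conditioned across the nanomolar-to-hundred-micromolar range:
with ``x = log10([drug] / M)`` and ``p = pIC50 = -log10(IC50 / M)``,

    inhibition = 1 / (1 + 10^(nH * (-p - x))).

Per-cell fractional inhibition values from all cells of one experiment are
pooled unweighted into a single fit.  Values below 0 or above 1 are fitted
as-is; clipping biases shallow curves.  The within-experiment SD of pIC50 is
the Jacobian-based standard error of ``p``; 95% CIs use a Student-t quantile
with ``n_points - 2`` degrees of freedom (Wald CIs; a profile-likelihood CI
for pIC50 is available via ``ci_method="profile"``).

When no point reaches the inhibition threshold (default 0.5) the IC50 is not
determined — the fit result retains the maximum observed inhibition instead,
mirroring how experiments with weak blockers are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitInputError

PIC50_BOUNDS = (3.0, 12.0)
NH_BOUNDS = (0.2, 6.0)


def hill_fraction(ic50, nH, conc):
    """Fractional inhibition ``1 / (1 + (ic50/conc)^nH)``; all args > 0."""
    ic50 = np.asarray(ic50, dtype=float)
    nH = np.asarray(nH, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if np.any(ic50 <= 0) or np.any(nH <= 0) or np.any(conc <= 0):
        raise FitInputError("hill_fraction requires ic50, nH, conc > 0")
    out = 1.0 / (1.0 + (ic50 / conc) ** nH)
    return float(out) if out.ndim == 0 else out


@dataclass
class HillFit:
    """Result of a Hill fit for one experiment."""

    ic50: float
    ic50_ci: tuple[float, float]
    nH: float
    nH_ci: tuple[float, float]
    pic50: float
    pic50_sd: float
    pic50_ci: tuple[float, float]
    n_points: int
    converged: bool
    determined: bool
    max_observed_inhibition: float
    residual_sd: float = float("nan")
    fixed_nH: float | None = None
    subset: str | None = None  # provenance of any concentration filter
    message: str = ""


def _undetermined(y: np.ndarray, n: int, msg: str) -> HillFit:
    nan = float("nan")
    return HillFit(ic50=nan, ic50_ci=(nan, nan), nH=nan, nH_ci=(nan, nan),
                   pic50=nan, pic50_sd=nan, pic50_ci=(nan, nan),
                   n_points=n, converged=False, determined=False,
                   max_observed_inhibition=float(np.max(y)), message=msg)


def _extract(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        conc = points["concentration_molar"].to_numpy(dtype=float)
        y = points["inhibition"].to_numpy(dtype=float)
    else:
        conc, y = (np.asarray(a, dtype=float) for a in points)
    if conc.size != y.size:
        raise FitInputError("concentration and inhibition differ in length")
    if np.any(conc <= 0):
        raise FitInputError("concentrations must be positive")
    if not np.all(np.isfinite(y)):
        raise FitInputError("inhibition values must be finite")
    return conc, y


def _model(x: np.ndarray, p: float, n: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (n * (-p - x)))


def _init_pic50(x: np.ndarray, y: np.ndarray) -> float:
    # concentration whose observed inhibition is nearest 0.5
    p0 = -x[np.argmin(np.abs(y - 0.5))]
    return float(np.clip(p0, *PIC50_BOUNDS))


def fit_hill(points, *, inhibition_threshold: float = 0.5,
             fixed_nH: float | None = None,
             ci_method: str = "wald") -> HillFit:
    """Unweighted nonlinear least-squares Hill fit.

    ``points``: DataFrame with columns ``concentration_molar``/``inhibition``
    (molar, fraction) or an (concentrations, inhibitions) pair of arrays.
    Requires >= 3 distinct concentrations (2 when ``fixed_nH`` is given).
    """
    conc, y = _extract(points)
    n_distinct = np.unique(conc).size
    min_needed = 2 if fixed_nH is not None else 3
    if n_distinct < min_needed:
        raise FitInputError(
            f"need >= {min_needed} distinct concentrations, got {n_distinct}")
    if np.max(y) < inhibition_threshold:
        return _undetermined(
            y, conc.size,
            f"max inhibition {np.max(y):.3f} below threshold {inhibition_threshold}")
    x = np.log10(conc)

    if fixed_nH is not None:
        if fixed_nH <= 0:
            raise FitInputError("fixed_nH must be > 0")
        theta0 = np.array([_init_pic50(x, y)])
        lo, hi = [PIC50_BOUNDS[0]], [PIC50_BOUNDS[1]]

        def resid(theta):
            return _model(x, theta[0], fixed_nH) - y
    else:
        theta0 = np.array([_init_pic50(x, y), 0.0])  # log nH = 0 -> nH = 1
        lo = [PIC50_BOUNDS[0], np.log(NH_BOUNDS[0])]
        hi = [PIC50_BOUNDS[1], np.log(NH_BOUNDS[1])]

        def resid(theta):
            return _model(x, theta[0], np.exp(theta[1])) - y

    res = optimize.least_squares(resid, theta0, bounds=(lo, hi),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    converged = bool(res.success)
    p = float(res.x[0])
    nH = fixed_nH if fixed_nH is not None else float(np.exp(res.x[1]))
    n_par = res.x.size
    dof = max(conc.size - 2, 1)  # reported df follows the two-parameter model
    ssr = float(2.0 * res.cost)
    s2 = ssr / dof
    # covariance from the Jacobian at the solution
    JtJ = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = np.full((n_par, n_par), np.nan)
    tq = float(stats.t.ppf(0.975, dof))
    sd_p = float(np.sqrt(max(cov[0, 0], 0.0)))
    if ci_method == "profile":
        p_ci = _profile_ci_pic50(x, y, p, nH, fixed_nH, ssr, dof)
    elif ci_method == "wald":
        p_ci = (p - tq * sd_p, p + tq * sd_p)
    else:
        raise FitInputError(f"unknown ci_method {ci_method!r}")
    if fixed_nH is None:
        sd_logn = float(np.sqrt(max(cov[1, 1], 0.0)))
        nH_ci = (nH * np.exp(-tq * sd_logn), nH * np.exp(tq * sd_logn))
    else:
        nH_ci = (nH, nH)
    ic50 = 10.0 ** (-p)
    return HillFit(
        ic50=ic50, ic50_ci=(10.0 ** (-p_ci[1]), 10.0 ** (-p_ci[0])),
        nH=nH, nH_ci=nH_ci,
        pic50=p, pic50_sd=sd_p, pic50_ci=p_ci,
        n_points=int(conc.size), converged=converged, determined=True,
        max_observed_inhibition=float(np.max(y)),
        residual_sd=float(np.sqrt(s2)), fixed_nH=fixed_nH,
        message="" if converged else res.message)


def _profile_ci_pic50(x, y, p_hat, nH_hat, fixed_nH, ssr_min, dof):
    """Profile-likelihood (SSR-ratio / F) CI for pIC50."""
    fcrit = float(stats.f.ppf(0.95, 1, dof))
    target = ssr_min * (1.0 + fcrit / dof)

    def ssr_at(p):
        if fixed_nH is not None:
            return float(((_model(x, p, fixed_nH) - y) ** 2).sum())
        res = optimize.minimize_scalar(
            lambda ln: float(((_model(x, p, np.exp(ln)) - y) ** 2).sum()),
            bounds=(np.log(NH_BOUNDS[0]), np.log(NH_BOUNDS[1])),
            method="bounded")
        return float(res.fun)

    def bound(direction):
        step, pb = 0.05, p_hat
        for _ in range(200):
            pb += direction * step
            if ssr_at(pb) > target or not (PIC50_BOUNDS[0] <= pb <= PIC50_BOUNDS[1]):
                break
        else:
            return pb
        inner = pb - direction * step
        try:
            return float(optimize.brentq(lambda q: ssr_at(q) - target,
                                         min(inner, pb), max(inner, pb)))
        except ValueError:
            return pb

    return (bound(-1.0), bound(+1.0))


def subset_refit(points, concentration_filter, *,
                 fixed_nH_when_two: float = 1.0, **kwargs) -> HillFit:
    """Refit on a concentration subset, recording the filter's provenance.

    ``concentration_filter``: iterable of concentrations to keep, or a
    predicate over concentration.  With exactly two distinct concentrations
    remaining the Hill slope is fixed (default 1).
    """
    conc, y = _extract(points)
    if callable(concentration_filter):
        keep = np.array([bool(concentration_filter(c)) for c in conc])
        label = "predicate"
    else:
        allowed = np.asarray(list(concentration_filter), dtype=float)
        keep = np.isclose(conc[:, None], allowed[None, :],
                          rtol=1e-9, atol=0.0).any(axis=1)
        label = f"concentrations={sorted(set(allowed.tolist()))}"
    if not keep.any():
        raise FitInputError("concentration filter excludes every point")
    sub = (conc[keep], y[keep])
    n_distinct = np.unique(sub[0]).size
    if n_distinct < 2:
        raise FitInputError("filter leaves fewer than 2 distinct concentrations")
    if n_distinct == 2 and "fixed_nH" not in kwargs:
        kwargs["fixed_nH"] = fixed_nH_when_two
    fit = fit_hill(sub, **kwargs)
    return replace(fit, subset=label)


def fit_experiments(points: pd.DataFrame,
                    by=("drug", "lab_id")) -> pd.DataFrame:
    """Fit every (drug, lab) experiment in a long table of inhibition points.

    Returns one row per experiment with the HillFit fields flattened; the
    pIC50 SD column is the within-experiment SD the meta-analysis consumes.
    """
    rows = []
    for key, grp in points.groupby(list(by), sort=True):
        try:
            fit = fit_hill(grp)
            err = ""
        except FitInputError as exc:
            fit, err = None, str(exc)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        if fit is None:
            row.update({"determined": False, "message": err})
        else:
            row.update({
                "ic50_molar": fit.ic50, "nH": fit.nH, "pic50": fit.pic50,
                "sd_pic50": fit.pic50_sd,
                "pic50_ci_lo": fit.pic50_ci[0], "pic50_ci_hi": fit.pic50_ci[1],
                "n_points": fit.n_points, "converged": fit.converged,
                "determined": fit.determined,
                "max_observed_inhibition": fit.max_observed_inhibition,
                "message": fit.message,
            })
        rows.append(row)
    return pd.DataFrame(rows)
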