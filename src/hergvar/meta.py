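"""Variance decomposition of multi-laboratory pIC50 data.

Two complementary routes attribute observed per-experiment pIC50s to drug
effects, laboratory effects and residual (unexplained) variability:

**Descriptive decomposition.**  Per-drug means over all records remove
drug-specific potency; averaging each laboratory group's distances to those
means yields a fixed laboratory offset; what remains after removing both is
residual variability, summarised by the span between its 2.5th and 97.5th
empirical percentiles.  ``10^span`` converts that span to a fold-ratio of
IC50s — the factor separating two potency estimates before they should be
considered different.

**Random-effects meta-analysis.**  The model

    pIC50_{ijk} = drug_i + laboratory_j + u_{ijk} + eps_{ijk}

treats drug and laboratory as fixed effects (reference-level coding; every
reported quantity is coding-invariant), u ~ N(0, tau^2) as residual
heterogeneity and eps ~ N(0, sigma_{ijk}^2) as within-experiment measurement
error with *known* variance (the squared SD of each experiment's fitted
pIC50).  tau is estimated by REML; its 95% CI by profiling the restricted
likelihood against the chi-square(1 df) cutoff.  The location-scale variant
lets the residual SD differ by laboratory group, tau_g, while keeping a
single SD across drugs.  Residual SDs convert to fold-ratios via
``10^(2 * z_0.975 * tau)``, the IC50 ratio spanning the central 95% of the
residual distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitInputError, InsufficientDataError

#: 97.5th percentile of the standard normal distribution
Z975 = float(stats.norm.ppf(0.975))

TAU_MAX = 3.0
_CHI2_95_1 = float(stats.chi2.ppf(0.95, 1))


class DesignWarning(UserWarning):
    """The fixed-effect design is (near-)non-identifiable."""


# ---------------------------------------------------------------------------
# conversions

def sd_to_ratio(sd: float) -> float:
    """Fold-ratio of IC50s spanning the central 95% of a residual SD.

    ``10^(2 * qnorm(0.975) * sd)`` with the unrounded normal quantile
    (1.959964); sd in pIC50 units, sd >= 0.
    """
    if sd < 0:
        raise FitInputError("sd must be >= 0")
    return float(10.0 ** (2.0 * Z975 * sd))


def span_to_ratio(span: float) -> float:
    """Fold-ratio for a percentile span in pIC50 units: ``10^span``."""
    return float(10.0 ** span)


# ---------------------------------------------------------------------------
# descriptive decomposition

@dataclass
class Decomposition:
    drug_means: pd.Series          # per-drug mean pIC50 over all records
    lab_offsets: pd.Series         # per lab-group mean of (drug mean - pIC50)
    residuals: pd.Series           # per-record, index = experiment_id
    span: float                    # 97.5th - 2.5th percentile of residuals
    fold_ratio: float              # 10^span
    singleton_drugs: tuple[str, ...] = ()   # drugs with a single record


def _require_columns(records: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise FitInputError(f"records table missing columns: {missing}")


def decompose_descriptive(records: pd.DataFrame,
                          lab_grouping: str = "group_label") -> Decomposition:
    """Drug-mean / lab-offset / residual decomposition of pIC50 records.

    Steps: (1) per-drug mean pIC50 over ALL records for that drug, repeats
    included; (2) distances ``d = drug mean - pIC50``; (3) lab-group offset =
    mean of d within the group; (4) residual = d - offset.  The span is the
    97.5th minus the 2.5th empirical percentile of the residuals (linear
    interpolation, Hyndman-Fan definition 7).
    """
    _require_columns(records, ["drug_id", "pic50", lab_grouping])
    if len(records) < 2:
        raise InsufficientDataError("need >= 2 records")
    if records[lab_grouping].isna().any():
        raise FitInputError("every record needs a lab group assignment")
    drug_means = records.groupby("drug_id")["pic50"].mean()
    counts = records.groupby("drug_id")["pic50"].size()
    singletons = tuple(counts.index[counts == 1])
    d = records["drug_id"].map(drug_means) - records["pic50"]
    offsets = d.groupby(records[lab_grouping]).mean()
    resid = d - records[lab_grouping].map(offsets)
    if "experiment_id" in records.columns:
        resid.index = records["experiment_id"]
    lo, hi = np.percentile(resid.to_numpy(), [2.5, 97.5])
    span = float(hi - lo)
    return Decomposition(drug_means=drug_means, lab_offsets=offsets,
                         residuals=resid, span=span,
                         fold_ratio=span_to_ratio(span),
                         singleton_drugs=singletons)


# ---------------------------------------------------------------------------
# REML machinery

def _design_matrix(records: pd.DataFrame,
                   lab_effect: str) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded drug and laboratory dummies."""
    drug = pd.Categorical(records["drug_id"])
    lab = pd.Categorical(records[lab_effect])
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for cat, prefix in ((drug, "drug"), (lab, "lab")):
        for level in cat.categories[1:]:
            cols.append((np.asarray(cat) == level).astype(float))
            names.append(f"{prefix}:{level}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "fixed-effect design is rank deficient (a laboratory may be "
            "observed only for drugs present in no other laboratory)",
            DesignWarning, stacklevel=3)
    return X, names


def restricted_nll(tau2_per_record: np.ndarray, X: np.ndarray,
                   y: np.ndarray, s2: np.ndarray) -> float:
    """-2x-free restricted negative log-likelihood (constants dropped).

    ``0.5 * (sum log v + log|X' V^-1 X| + r' V^-1 r)`` with diagonal
    ``V = diag(tau2 + s2)`` and r the GLS residual.  Shared by the
    optimizer, the profile CI and the grid-search oracle in the tests.
    """
    v = tau2_per_record + s2
    w = 1.0 / v
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return float("inf")
    beta = np.linalg.solve(XtWX, Xw.T @ y)
    r = y - X @ beta
    return float(0.5 * (np.log(v).sum() + logdet + (w * r * r).sum()))


def _ml_nll(tau2_per_record, X, y, s2) -> float:
    v = tau2_per_record + s2
    w = 1.0 / v
    Xw = X * w[:, None]
    beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    r = y - X @ beta
    return float(0.5 * (np.log(v).sum() + (w * r * r).sum()))


@dataclass
class MetaFit:
    """Random-effects fit: fixed drug/lab effects + residual SD(s)."""

    fixed_effects: pd.Series
    fixed_cov: pd.DataFrame
    tau: float | dict[str, float]
    tau_ci: tuple[float, float] | dict[str, tuple[float, float]]
    fold_ratio: float | dict[str, float]
    fold_ratio_ci: tuple[float, float] | dict[str, tuple[float, float]]
    loglik_restricted: float   # up to an additive constant
    converged: bool
    n_records: int
    method: str = "REML"
    group_sizes: dict[str, int] = field(default_factory=dict)

    def predict(self, records: pd.DataFrame, lab_effect: str) -> np.ndarray:
        X, names = _design_matrix(records, lab_effect)
        beta = self.fixed_effects.reindex(names).to_numpy()
        return X @ beta


def _prepare(records: pd.DataFrame, lab_effect: str | None):
    lab_effect = lab_effect or (
        "group_label" if "group_label" in records.columns else "lab_id")
    _require_columns(records, ["drug_id", "pic50", "sd_pic50", lab_effect])
    if records["drug_id"].nunique() < 2 or records[lab_effect].nunique() < 2:
        raise FitInputError(
            "need >= 2 drug levels and >= 2 laboratory levels")
    if (records["sd_pic50"] < 0).any():
        raise FitInputError("sd_pic50 must be >= 0")
    y = records["pic50"].to_numpy(dtype=float)
    s2 = records["sd_pic50"].to_numpy(dtype=float) ** 2
    X, names = _design_matrix(records, lab_effect)
    return lab_effect, X, names, y, s2


def _gls(X, y, v):
    w = 1.0 / v
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ y)
    cov = np.linalg.inv(XtWX)
    return beta, cov


def _profile_tau_ci(nll_of_tau, tau_hat, nll_min,
                    upper: float = TAU_MAX) -> tuple[float, float]:
    """Profile restricted-likelihood CI: {tau : 2(nll(tau) - nll_min) <= chi2}."""
    crit = nll_min + _CHI2_95_1 / 2.0

    def g(t):
        return nll_of_tau(t) - crit

    if g(0.0) <= 0:
        lo = 0.0
    else:
        lo = float(optimize.brentq(g, 0.0, tau_hat)) if tau_hat > 0 else 0.0
    if g(upper) <= 0:
        hi = upper
    else:
        hi = float(optimize.brentq(g, max(tau_hat, 1e-12), upper))
    return (lo, hi)


def fit_mixed_effects(records: pd.DataFrame, *, lab_effect: str | None = None,
                      method: str = "REML", compute_ci: bool = True) -> MetaFit:
    """Single-tau random-effects meta-regression with known sampling SDs.

    REML by default; ``method="ML"`` switches to maximum likelihood.
    ``compute_ci=False`` skips the profile CI (useful in simulation loops).
    """
    if method not in ("REML", "ML"):
        raise FitInputError(f"unknown method {method!r}")
    lab_effect, X, names, y, s2 = _prepare(records, lab_effect)
    n = len(y)
    obj = restricted_nll if method == "REML" else _ml_nll

    def nll(tau: float) -> float:
        return obj(np.full(n, tau * tau), X, y, s2)

    res = optimize.minimize_scalar(nll, bounds=(0.0, TAU_MAX),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    tau_hat = float(res.x)
    # bounded search cannot land exactly on the boundary; snap when flat
    if nll(0.0) <= res.fun + 1e-12:
        tau_hat = 0.0
    nan = float("nan")
    ci = (_profile_tau_ci(nll, tau_hat, nll(tau_hat)) if compute_ci
          else (nan, nan))
    beta, cov = _gls(X, y, tau_hat ** 2 + s2)
    return MetaFit(
        fixed_effects=pd.Series(beta, index=names),
        fixed_cov=pd.DataFrame(cov, index=names, columns=names),
        tau=tau_hat, tau_ci=ci,
        fold_ratio=sd_to_ratio(tau_hat),
        fold_ratio_ci=((sd_to_ratio(ci[0]), sd_to_ratio(ci[1]))
                       if compute_ci else (nan, nan)),
        loglik_restricted=-nll(tau_hat), converged=True, n_records=n,
        method=method)


def fit_location_scale(records: pd.DataFrame, *,
                       group_col: str = "group_label",
                       lab_effect: str | None = None,
                       compute_ci: bool = True) -> MetaFit:
    """Location-scale REML: residual SD tau_g per laboratory group.

    The fixed-effect (location) structure is identical to
    :func:`fit_mixed_effects`; only the scale part differs, one residual SD
    per level of ``group_col``.  Groups with a single record have an
    unidentifiable tau_g, reported as NaN with an open CI.
    """
    _require_columns(records, [group_col])
    lab_effect, X, names, y, s2 = _prepare(records, lab_effect or group_col)
    groups = pd.Categorical(records[group_col])
    levels = list(groups.categories)
    gidx = np.asarray(groups.codes)
    n = len(y)
    sizes = {lv: int((gidx == i).sum()) for i, lv in enumerate(levels)}
    identifiable = np.array([sizes[lv] >= 2 for lv in levels])

    def tau2_vec(taus: np.ndarray) -> np.ndarray:
        return (taus ** 2)[gidx]

    def nll_vec(taus: np.ndarray) -> float:
        return restricted_nll(tau2_vec(taus), X, y, s2)

    x0 = np.full(len(levels), 0.2)
    res = optimize.minimize(nll_vec, x0, method="L-BFGS-B",
                            bounds=[(0.0, TAU_MAX)] * len(levels),
                            options={"ftol": 1e-14, "gtol": 1e-12,
                                     "maxiter": 500})
    taus = np.asarray(res.x, dtype=float)
    # polish each coordinate with a bounded scalar search
    for _ in range(2):
        for i in range(len(levels)):
            def nll_i(t, i=i):
                tt = taus.copy()
                tt[i] = t
                return nll_vec(tt)
            r = optimize.minimize_scalar(nll_i, bounds=(0.0, TAU_MAX),
                                         method="bounded",
                                         options={"xatol": 1e-10})
            if r.fun <= nll_vec(taus):
                taus[i] = float(r.x)
            if nll_i(0.0) <= nll_vec(taus) + 1e-12:
                taus[i] = 0.0

    nll_min = nll_vec(taus)
    tau_d: dict[str, float] = {}
    ci_d: dict[str, tuple[float, float]] = {}
    for i, lv in enumerate(levels):
        if not identifiable[i]:
            tau_d[lv] = float("nan")
            ci_d[lv] = (float("nan"), float("nan"))
            continue
        tau_d[lv] = float(taus[i])
        if not compute_ci:
            ci_d[lv] = (float("nan"), float("nan"))
            continue

        def profile_i(t, i=i):
            others = [j for j in range(len(levels)) if j != i]

            def inner(free):
                tt = taus.copy()
                tt[i] = t
                tt[others] = free
                return nll_vec(tt)
            if not others:
                tt = taus.copy()
                tt[i] = t
                return nll_vec(tt)
            r = optimize.minimize(inner, taus[others], method="L-BFGS-B",
                                  bounds=[(0.0, TAU_MAX)] * len(others),
                                  options={"ftol": 1e-12})
            return float(r.fun)

        ci_d[lv] = _profile_tau_ci(profile_i, taus[i], nll_min)

    beta, cov = _gls(X, y, tau2_vec(taus) + s2)
    return MetaFit(
        fixed_effects=pd.Series(beta, index=names),
        fixed_cov=pd.DataFrame(cov, index=names, columns=names),
        tau=tau_d,
        tau_ci=ci_d,
        fold_ratio={lv: sd_to_ratio(t) if np.isfinite(t) else float("nan")
                    for lv, t in tau_d.items()},
        fold_ratio_ci={lv: (sd_to_ratio(c[0]), sd_to_ratio(c[1]))
                       if np.isfinite(c[0]) else (float("nan"), float("nan"))
                       for lv, c in ci_d.items()},
        loglik_restricted=-nll_min, converged=bool(res.success),
        n_records=n, group_sizes=sizes)


# ---------------------------------------------------------------------------
# descriptive lab-vs-group ratios and within-experiment summaries

@dataclass
class LabRatio:
    lab: str
    mean_diff_pic50: float  # mean over drugs of (group avg pIC50 - lab pIC50)
    fold_ratio: float       # 10^mean_diff = IC50_lab / IC50_group_avg
    n_drugs: int


def lab_ratio_to_group(records: pd.DataFrame, lab: str,
                       drugs=None, lab_col: str = "lab_id") -> LabRatio:
    """Averaged ratio of one laboratory's IC50s to the group averages.

    Per drug: the group-average pIC50 (mean over all records of that drug)
    minus the laboratory's mean pIC50; averaged over the drug subset and
    returned both in pIC50 units and as the fold-ratio ``10^mean``.
    """
    _require_columns(records, ["drug_id", "pic50", lab_col])
    subset = list(drugs) if drugs is not None else sorted(
        records.loc[records[lab_col] == lab, "drug_id"].unique())
    if not subset:
        raise FitInputError("empty drug subset")
    diffs = []
    for drug in subset:
        all_rec = records[records.drug_id == drug]
        lab_rec = all_rec[all_rec[lab_col] == lab]
        if lab_rec.empty:
            raise FitInputError(f"lab {lab!r} has no records for drug {drug!r}")
        diffs.append(all_rec["pic50"].mean() - lab_rec["pic50"].mean())
    mean_diff = float(np.mean(diffs))
    return LabRatio(lab=lab, mean_diff_pic50=mean_diff,
                    fold_ratio=span_to_ratio(mean_diff), n_drugs=len(subset))


@dataclass
class WithinExperimentSummary:
    per_lab: pd.DataFrame  # median / 2.5th / 97.5th pct of sd_pic50 per lab
    correlation_r: float   # Pearson r of sd_pic50 vs (drug mean - pIC50)
    n_records: int


def within_experiment_summary(records: pd.DataFrame,
                              lab_col: str = "lab_id") -> WithinExperimentSummary:
    """Within-experiment SD summaries and their (lack of) relation to bias."""
    _require_columns(records, ["drug_id", "pic50", "sd_pic50", lab_col])
    if len(records) < 2:
        raise InsufficientDataError("need >= 2 records")
    rows = []
    for lab, grp in records.groupby(lab_col, sort=True):
        sd = grp["sd_pic50"].to_numpy()
        lo, med, hi = np.percentile(sd, [2.5, 50, 97.5])
        rows.append({lab_col: lab, "n": len(sd), "median_sd": float(med),
                     "p2_5_sd": float(lo), "p97_5_sd": float(hi)})
    drug_means = records.groupby("drug_id")["pic50"].mean()
    dist = records["drug_id"].map(drug_means) - records["pic50"]
    r = float(np.corrcoef(records["sd_pic50"].to_numpy(), dist.to_numpy())[0, 1])
    return WithinExperimentSummary(per_lab=pd.DataFrame(rows),
                                   correlation_r=r, n_records=len(records))
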