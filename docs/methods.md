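# Methods

## Scope and data model

The package analyses concentration–inhibition experiments on the hERG
potassium channel performed with a step-ramp voltage command (holding
−80 mV; −90 mV test step for 100 ms; +40 mV for 500 ms; 100 ms ramp back to
−80 mV; 0.2 Hz pacing). One *experiment* is one concentration–inhibition
curve for one drug in one laboratory, built from several cells; its result
is a pIC50 with a within-experiment SD. A *study* is a table of such
records across drugs and laboratories. Data enter either as such a potency
table, or as raw waveforms in the TED-lite dialect (a `manifest.csv` of
conditions plus one `time_s,voltage_mV,current_pA` CSV per sweep — a small,
fully documented layout, deliberately not a bit-exact copy of any deposited
schema).

## Trace processing

Per sweep: the ramp peak is the maximum (signed, outward-positive) current
in the ramp window with the command voltage at the argmax; I(−80 mV) is the
mean holding current before the test step; R_input = 10 mV divided by the
steady-state deflection of the −90 mV step (second half of the step
window), which makes it invariant to constant current offsets. The
hERG-mediated component is isolated by E-4031 subtraction: `trace` mode
subtracts the averaged E-4031 sweep pointwise before peak extraction (and
removes any leak present in both sweeps exactly); `peak` mode subtracts the
mean E-4031 ramp peak; `none` uses the absolute ramp peak for cells
recorded without an E-4031 phase. Choices the underlying protocol leaves
open, fixed here: the E-4031 reference averages the **last 3** blocker
sweeps; a phase's reported amplitude averages the **last 5** in-phase
sweeps; fractional inhibition `1 − drug/baseline` is **not clipped** —
negative values (current increase) flow into fitting, since clipping biases
shallow curves. The stability QC metric is the percent change between the
first and fifth of the last five in-phase amplitudes (20 s apart at 0.2 Hz).

## Exposure correction

Fractional loss is `1 − mean(final)/mean(starting)` over bioanalysis
triplicates, computed per (drug, laboratory, concentration). A negative
raw loss (assay noise) is clamped to 0 and flagged, because a negative loss
would push a corrected concentration above nominal. Correction multiplies
nominals by `1 − loss`, averaged across concentrations by default, or
elementwise for drugs with concentration-dependent loss; the averaged mode
also covers repeat experiments whose nominals differ from those the losses
were measured at. The mean-of-per-concentration-losses convention is used
for averaging (it coincides with pooled-means for equal designs). Across
drugs, percent loss versus LogP is fitted with
`loss = 100/(1 + exp((x50 − LogP)/dx))`, asymptotes fixed at 0 and 100,
initialised at x50 = median LogP and dx = 1 with dx bounded in (0, 10];
non-convergence returns a flagged result rather than raising, and an x50
outside the observed LogP range (e.g. an all-hydrophilic panel) is flagged
as extrapolated.

## Hill fitting

Unweighted nonlinear least squares of
`1/(1 + 10^(nH·(−pIC50 − log10 c)))` in parameters (pIC50, log nH), bounds
pIC50 ∈ [3, 12], nH ∈ [0.2, 6], initialised at the concentration whose
observed inhibition is nearest 0.5 and nH = 1. Per-cell points are pooled
unweighted because the experiments pool cells into one curve without a
stated weighting. The pIC50 SD is the Jacobian-based standard error; 95%
CIs are Wald with a Student-t quantile at `n_points − 2` df (the exact CI
algorithm of the original instrument software is unknown; a
profile-likelihood CI is available via `ci_method="profile"`). IC50 CIs
are the pIC50 CI mapped through `10^−p`, keeping the two scales consistent
by construction. When no point reaches the inhibition threshold (default
0.5), the IC50 is reported undetermined and the maximum observed inhibition
retained — the behaviour reported for weak blockers in practice.
`subset_refit` refits on a concentration subset (e.g. the two highest
concentrations when low-concentration sweeps did not reach steady state),
fixing nH (default 1) when only two distinct concentrations remain, and
records the filter in the result.

## Variance decomposition

**Descriptive.** (1) per-drug mean pIC50 over all records, repeats
included; (2) distances `d = drug mean − pIC50`; (3) laboratory-group
offset = mean d within group; (4) residual = d − offset (so residuals sum
to zero within each group). A laboratory whose behaviour changed mid-study
can be split into two groups (the default design's "Lab2" vs "Lab2*").
The spread is the 97.5th − 2.5th empirical percentile span of the
residuals, with linear-interpolation quantiles (Hyndman–Fan definition 7),
converted to a fold-ratio as `10^span`.

**Meta-analysis.** `pIC50_ijk = drug_i + lab_j + u_ijk + eps_ijk`, drug and
laboratory fixed (intercept + reference-level dummies; all reported
quantities are coding-invariant, verified by a relabeling test),
`u ~ N(0, τ²)` and `Var(eps)` known per record. τ maximises the restricted
likelihood (REML; ML available via a flag); fixed effects are GLS at τ̂.
The restricted negative log-likelihood is evaluated directly
(`Σ log v + log|XᵀV⁻¹X| + rᵀV⁻¹r`, V diagonal) and optimised by bounded
scalar search on τ ∈ [0, 3], which handles the τ = 0 boundary without a
log-scale epsilon floor; a flat profile snaps to 0. The 95% CI profiles the
restricted likelihood against the χ²(1 df) cutoff. The location-scale
variant assigns each laboratory group its own τ_g (box-constrained
multivariate optimisation with per-coordinate polishing); per-group CIs
re-profile the other τ_g at each candidate value; a single-record group's
τ_g is reported undetermined. Fold-ratio conversion uses
`10^(2·1.959964·τ)` with the unrounded normal quantile. Both estimators
reproduce R `metafor`'s REML estimates (standard and location-scale with
identity link) to ~1e-5 on test data, and the single-τ estimator matches a
dense grid search of the restricted likelihood to 1e-3.

## Synthetic data

The generator mirrors the structure the analyses assume, with defaults set
to the study conditions: 28 drugs in two phases with literature-plausible
potencies, Hill slopes and LogP values; five laboratories with experiment
rosters of 30/36/16/30/33 (blind dofetilide/ondansetron repeats and extra
repeat experiments included) totalling 145 experiments; laboratory offsets
(pIC50 units) of +0.16/−0.65/+0.11/+0.15/+0.20/+0.14 for
Lab1/Lab2/Lab2*/Lab3/Lab4/Lab5, the negated published lab-vs-group-average
differences; residual SD τ = 0.18; within-experiment SDs drawn uniformly
from (0.02, 0.15) and recorded as the known SD (the source material reports
medians and percentiles per laboratory but no distribution, so a uniform
range spanning the reported scale was chosen once). Inhibition noise is
additive Gaussian on the fraction scale, optionally clipped to [−0.1, 1.1]
to mimic real over/under-shoot. Sweep simulation uses a phenomenological
bell-shaped hERG conductance over the depolarization and ramp, normalised
so the noise-free vehicle ramp peak equals the configured amplitude
exactly, peaking near −30 mV on the ramp; leak is ohmic; rundown is
geometric per sweep; repeat experiments are exchangeable given τ (no extra
within-laboratory repeat correlation is modelled, as none is quantified in
the source material). What the generator does **not** emulate: channel
gating kinetics and their temperature dependence, series-resistance and
liquid-junction-potential artefacts, slow drug-block onset, and
drug-specific residual variances — so passing recovery tests demonstrate
estimator correctness under the stated statistical model, not robustness to
those real-data features.

## Problem sizes and numerical choices

Recovery suites use 200 replicates of the 145-record design (pooled τ) and
200 replicates of a 100-record two-group design (location-scale ordering);
Hill calibration uses 500 replicates of 3-cell × 5-concentration panels and
a noise-free grid over IC50 ∈ [1e-9, 1e-4] M × nH ∈ [0.5, 3]. The
grid-search REML oracle uses 20 random 12-record instances with a 1e-4 τ
grid. Sweep-level tests sample at 1 ms to keep waveforms small; the
protocol default is 0.1 ms. Optimiser tolerances: least-squares xtol/ftol
1e-14; τ search xatol 1e-10. Degenerate inputs are first-class: zero-noise
sigma ranges are allowed (the noise-free limit used by exactness tests),
R_input is infinite at zero step deflection, and a drug whose maximum
inhibition stays below threshold yields an undetermined, not failed, fit.

## Known limitations

Within-experiment SDs are treated as known variances, as is standard in
meta-analysis but optimistic when experiments have few cells. The
descriptive span at n = 145 carries substantial sampling noise in its tail
percentiles. The location-scale profile CIs can be very wide for small
groups (e.g. a 7-record group), which is honest but limits their use. The
generator's laboratory offsets are fixed constants; uncertainty in the
offsets themselves is not propagated.
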