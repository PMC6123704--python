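# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `metadyn`, and what the synthetic benchmarks do
and do not demonstrate.

## Ion annotation

Annotation is by accurate mass only, as appropriate for flow-injection
data without chromatographic separation.  Monoisotopic masses are sums of
most-abundant-isotope masses from a bundled table (NIST/CODATA values to
≥ 8 decimals, elements H, C, N, O, P, S, Na, K, Cl, F, Br, I, Se, Fe, Mg,
Ca, Zn; see `metadyn.chem.ELEMENT_MASSES`).  Deprotonation subtracts the
proton mass 1.007276467 Da — the hydrogen-atom mass minus the electron
mass — not the H-atom mass; the ~0.5 mDa difference matters at the 0.003
Da matching tolerance, and the proton convention reproduces the lock-mass
standard (C₃H₉NO₃S → [M−H]⁻ 138.02304) to printed precision.

Choices made where the procedure was open:

* The matching tolerance is applied inclusively (|Δm| ≤ 0.003 Da).
* Ties at exactly equal |mass error| keep all matches; the single
  reported annotation is the lexicographically smallest metabolite id, so
  output is deterministic.
* Isobaric metabolites are all retained in `all_matches`; flow injection
  cannot distinguish them and downstream mapping uses the best match only,
  so an ambiguous isobar contributes once to enrichment.
* The formula grammar is flat (no parentheses, hydrates, charges or
  isotope labels): reference exports must be pre-expanded.
* Which metabolites are α-keto acids (and hence receive a phenylhydrazone
  entry, +C₆H₈N₂ −H₂O = +90.058184 Da) is declared per record via
  `is_keto_acid` rather than hard-coded.

## Steady-state model

For each ion, intensities of all cell lines are regressed at once on the
block design [N_c per line | 1], giving line-specific per-cell abundances
α and one shared background β.  The shared offset encodes the assumption
that the MS background is a property of the instrument, not of the cell
type.  Estimation is ordinary least squares with no weighting — matching
the original procedure — and per-coefficient significance is the F
statistic with one numerator degree of freedom against zero (identical to
the squared t statistic).  Missing intensities are dropped sample-wise per
ion; no imputation, since missingness at the detection limit is not
verifiable as random.  A cell line whose remaining samples do not span two
distinct cell numbers is flagged non-estimable rather than fitted.

Reliability per (ion, line) is α > 0 and p ≤ 0.001 (default).  Ions with
no reliable line are reported as background / below detection limit.  The
coefficient of variation reported per estimate is SE(α̂)/α̂ from the
regression — one of two defensible readings of a "CV of the parameter
estimates" (the other being a replicate-based CV); the regression-based
one is documented and used throughout.

Samples above 80% confluence are excluded before fitting (cell-number
extraction from bright-field images degrades in crowded wells and growth
departs from steady state).  The filter applies to the baseline fit only,
not to perturbed samples.

*Known limitation.*  FIA intensity noise is multiplicative (constant CV),
so residual variance grows with the square of intensity and unweighted
OLS standard errors are anti-conservative: at 15% noise, empirical
coverage of ±3 SE intervals is ≈ 85% rather than the nominal ≈ 99.7%.
Point estimates remain unbiased — median |α̂−α|/α is well under 15% in the
benchmark fixtures — and the p ≤ 0.001 reliability screen is not
materially affected for background rejection (see the acceptance suite),
but downstream consumers should not treat SE(α̂) as exact.  A log-scale
fit would equalize the variance but change the model; it is deliberately
not the default.

Cross-line differences in baseline abundance are tested by one-way ANOVA
on the per-sample abundances (I − β̂)/N_c with Benjamini–Hochberg
adjustment across ions (Storey's q-values optional).

## Fold-change dynamics

The unperturbed reference intensity of a treated sample is predicted from
the fitted α, β and the cell number extracted at sampling time; replicate
log₂ ratios against that prediction are averaged and tested against zero
with a two-sided one-sample t-test.  A two-sample mode (Welch test
against time-matched untreated wells) exists for designs that include
parallel controls.  Conventions: fewer than two replicates → p missing;
zero-variance replicates exactly at zero → p = 1.  Non-positive measured
intensities or predicted baselines drop the replicate (the background
term already absorbs the detector floor; no pseudo-counts).

Uncertainty in α̂ and β̂ is *not* propagated into the t-test, as in the
original procedure.  Consequence: the accuracy floor of a recovered
fold-change is the replicate noise (σ_log₂/√n ≈ 0.124 log₂ units at 15%
CV and three replicates) plus the baseline prediction error of that ion.
The benchmark bound of 0.15 log₂ RMSE is therefore a property of
well-detected ions under a well-constrained baseline (the benchmark uses
six replicate baseline wells per time point); ions near the detection
limit cannot meet it in principle, and their fold-changes should be read
qualitatively.

## Fingerprints and enrichment

Per (ion, line) the signed log₂ FC at the time point of maximal |FC| is
extracted (earliest time on ties); per ion, the median of these signed
values across lines and the product of per-line minimal p-values
summarize the response.  Keeping the sign at the maximal response (rather
than the maximal absolute value) preserves direction in the volcano-style
summary; an absolute-value mode is available via a flag.

The combined p (product of minima) is **not a calibrated p-value** — both
the min-over-time and the product across lines are anti-conservative.  It
is used exactly as a ranking/selection score with the conventional cuts
(|median FC| ≥ 1, combined p ≤ 1e−10, both inclusive), never interpreted
as a significance level.  Cell-line-specific responses are selected by
the sample standard deviation (n−1) of the per-line maxima, ≥ 1.5.

Enrichment is the hypergeometric upper tail on the best-match metabolite
sets, pathways intersected with the universe first.  The enrichment
universe is all reliable annotated ions (mapped to metabolites) by
default and configurable, since the original choice of universe is not
fixed by the procedure.  Correction is Benjamini–Hochberg by default;
Storey's q-values (π₀ by cubic-spline λ-smoothing over λ ∈ [0.05, 0.9])
require ≥ 100 tests and otherwise fall back to BH with a warning.

## Growth and GI50

Growth rates are slopes of ln(confluence) vs time (replicates pooled into
one regression) — the log-linear form is exact for exponential growth and
numerically stabler than a nonlinear exponential fit.  Points above 80%
confluence or at non-positive confluence are excluded.  Inhibition is
1 − r(d)/r(0); the dose–response is a two-parameter Hill curve on log₁₀
dose with asymptotes fixed at 0 and 1 (inhibition is defined relative to
the untreated rate, so the lower asymptote is 0 by construction); a
four-parameter logistic is available behind a flag.  Dose 0 defines the
untreated rate only and never enters the sigmoid fit.  Results are
flagged when the GI50 lies outside the tested dose range (extrapolated)
or when observed inhibition does not span [0.2, 0.8] (low confidence).

## CoA kinetic model

Two Michaelis–Menten-type reactions:

    v_CoA     = v_CoA,max / max([HoPan], 1) · ([DCA]/([DCA]+K_DCA) + 1)
    v_biomass = v_biomass,max · [CoA] / ([CoA] + K_CoA·(1 + [CoA]³/K_i))

with reference parameters v_biomass,max = 1, K_CoA = 0.01, K_i = 1
(units of concentration³, as the cubic term implies), v_CoA,max = 0.45,
[CoA]₀ = 10, [DCA] = 0.01, [HoPan] = 5, all in arbitrary model units.
K_DCA is not part of the reference set; the default 0.01 (equal to the
reference [DCA], activation factor 1.5) is exposed as a parameter.
Dividing v_CoA,max by the HoPan concentration is applied only for
[HoPan] ≥ 1 — dividing by a fraction would increase biosynthesis, which
contradicts an inhibitor — and [HoPan] = 0 means untreated.

The state equations are a declared reconstruction (the original state
variables are not printed): CoA is consumed directly into biomass with
unit stoichiometry, and biomass grows autocatalytically,

    d[CoA]/dt = v_CoA − c·v_biomass        (c = 1 by default)
    dB/dt     = v_biomass · B

This coupling reproduces every qualitative reference behaviour: the
stable untreated fixed point (v_biomass → 0.45), concentration-dependent
growth inhibition by exogenous CoA (modeled purely as a raised initial
pool, no uptake kinetics), DCA-driven runaway CoA accumulation with
growth collapse, biphasic growth under hopantenate passing through the
analytic utilization maximum at [CoA]* = (K_i/2)^{1/3} ≈ 0.794, and early
growth rescue under DCA+HoPan co-treatment.

Numerics: LSODA with rtol 1e−8 / atol 1e−10, CoA clamped at ≥ 0 inside
the right-hand side, t_end = 200 by default (long enough for the
untreated trajectory to be within 1e−4 of its fixed point).  Regime
classification needs margins: the untreated trajectory itself grazes the
v_biomass maximum on its way from [CoA]₀ = 10 down to the fixed point and
ends marginally below its initial rate, so a naive "transient peak +
lower end" rule would label it biphasic.  The classifier used is:
*runaway* if CoA exceeds 10× its start while growth falls below 10% of
its initial value, or if the trajectory fails to converge to the
biosynthesis–consumption balance with CoA still rising; *biphasic* if the
growth rate transiently exceeds its initial value by > 5% and ends below
80% of it; *stable* otherwise.

## Synthetic data: what it does and does not emulate

The generators produce data from each stage's own forward model:
intensities (α·N + β)·exp(ε) with lognormal ε matched to a target CV
(σ = √ln(1+CV²); the ≈1% mean bias of the uncentred lognormal is
deliberate — raw MS intensities are not mean-corrected either), per-line
exponential cell growth with 5% well-to-well seeding jitter, treated
intensities scaled by 2^fc on the full (signal + background) intensity —
matching the estimator's definition exactly — and Hill-inhibited
confluence curves.  Default dimensions mirror the study design: 5 cell
lines, 3 replicates, sampling at {0, 24, 48, 72, 96} h, nine-dose GI50
grids; benchmark fixtures scale ion counts (50–500) to keep the test
suite fast.

Not emulated: ion-specific noise floors and saturation, drift/batch
structure, correlated metabolite responses, in-source fragments, isotope
patterns, missing-value mechanisms.  Passing recovery benchmarks on these
fixtures therefore demonstrates correctness of the estimators under the
model's own assumptions, not robustness to everything real FIA data can
do.

## Benchmark problem sizes

The acceptance-style checks run at: 200 ions × 5 lines × 8 samples for
fitter recovery; 100 seeds × 10 background ions for the reliability
screen; 20 injected trajectory ions × 5 lines (3 treated replicates, 30
baseline samples/line) for fold-change recovery; 50 seeds × 500 ions ×
10 injected for fingerprint selection; 100 seeds × 9 doses for GI50;
fixed-step RK4 at 10⁻³ time units as the integration oracle.  These sizes
were chosen to give stable pass/fail statistics at interactive runtimes.
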