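# Methods

## Recording model and time axis

A kinetic measurement is two FCS list-mode files: a baseline recording of
the resting Fluo-4 signal and an activation recording started after the
activating agent was added outside the instrument. The operator measures
the gap between agent contact and acquisition restart; `append_recordings`
shifts activation event times by `baseline_duration + gap_seconds` and
defines `t_act` at that point. The baseline duration is taken as the last
baseline event time rather than the nominal 60 s, so clock drift cannot
misplace `t_act`. Curves are standardized to end at `t_end = 780 s`
(60 s baseline + 720 s activation); with a positive gap, events shifted
beyond 780 s are truncated rather than compressing the axis (the count is
logged, and truncation can be disabled). Only FCS 3.0/3.1 with float or
integer list-mode data are supported; values are assumed compensated and
linear, and the time channel is identified by its `$PnN` short name
(default `Time`, overridable) and scaled by `$TIMESTEP`.

## Gating

The default hierarchy is: time-stability interval → singlets (FSC-H/FSC-A
ratio band, default [0.85, 1.15]) → lymphocytes (FSC/SSC polygon) → live
dye-loaded cells (Fluo-4⁺ against the Fluo-4 FMO) → B cells (CD3⁻CD19⁺) →
leaves {naive IgD⁺CD27⁻, NSw IgD⁺CD27⁺, Sw IgD⁻CD27⁺, DN IgD⁻CD27⁻, ASC
IgD⁻CD27ʰⁱCD38ʰⁱ}. ASC events are carved out of the IgD⁻ fraction before
Sw/DN assignment, so the five leaves partition the B-cell gate exactly.

Positivity thresholds are empirical upper quantiles (default 0.999) of the
FMO control's distribution on the left-out channel. The "high" gates of the
ASC leaf multiply the base FMO threshold by a configurable factor (default
10 on the linear scale): no quantitative placement of CD27ʰⁱ/CD38ʰⁱ exists
to copy, so the default reproduces a visually high gate and is meant to be
overridden per panel. The same applies to the lymphocyte polygon, whose
default vertices are sized for the simulator's scatter scales. A reduced
tree without IgD (leaves CD27⁻/CD27⁺) supports panels that only separate
naive from memory cells.

A population is refused for fitting when its total event count falls below
`min_total` (default 300) or when more than 20% of the 5-s bins spanning
the window hold fewer than `min_per_bin` (default 5) events. An "any bin
below the floor" rule would exclude every rare population through single
Poisson-fluctuation bins (a bin at mean 10 falls below 5 about 3% of the
time, and there are ~156 bins); the 20% rule keeps such traces — the sparse
bins themselves are dropped during binning — while still rejecting
populations too thin to constrain a seven-parameter curve.

## Traces and normalization

Per-population traces are fixed-width bins (default 5 s) over `[0, 780]`,
summarized by the per-bin **median** of the Fluo-4 channel; medians make
the trace insensitive to the heavy right tail of cytometry fluorescence and
to the per-cell dye-loading spread, which multiplies every cell's signal by
a (median-1) factor. The trace is divided by the resting fluorescence,
estimated as the median of the pre-activation bin medians (the mean is
selectable); after division the median of the baseline bins equals 1
exactly, so every curve starts at 1 and subsets with different absolute
resting Ca²⁺ are comparable across days and samples. All descriptors are
invariant to rescaling the raw fluorescence.

## Curve fitting

The model family is constant `f = S`, single logistic (`H2 = 0`), and the
double logistic

f(t) = S + H1·σ(k1(t−m1)) − H2·σ(k2(t−m2)),  σ(x) = 1/(1+e⁻ˣ).

Fitting is weighted nonlinear least squares (trust-region reflective,
weights ∝ bin event counts so sparse late bins do not dominate; unweighted
mode available). Initialization is deterministic from the trace: S₀ = 1,
H1₀ = max − 1, m1₀ = first crossing of 1 + H1₀/2, k1₀ = 4/(rise span), and
analogously on the descending limb; five seeded lognormal-perturbed
restarts guard against local minima, and identical inputs always produce
identical fits. Bounds: rates in [10⁻⁴, 10] s⁻¹, amplitudes in
[0, 10·H1₀+1], midpoints in [0, t_end]. `model="auto"` fits all three
candidates and selects by small-sample-corrected AIC, so a flat
not-activated control resolves to the constant model instead of a
degenerate sigmoid. Minimum retained bins: 2 (constant), 4 (logistic),
8 (double logistic).

## Descriptors

Start and Ending are the function's limits at −∞ and +∞ (`S` and
`S + H1 − H2`). Max is the maximum over the observation window
`[t_act, t_end]` — not the analytic supremum — located by a 4001-point
grid scan refined by bounded scalar minimization; for a curve still rising
at 780 s this is the value actually reached during observation, in which
case the Ending limit may exceed it. Times are measured from `t_act`,
because they describe reaction speed to the agent. The first 50% level is
halfway between Start and Max (earliest ascending crossing, slope `f′`
there is positive); the second halfway between Max and Ending (descending
crossing, possibly beyond 780 s; slope negative). AUC integrates `f − S`
in closed form via the logistic antiderivative `(H/k)·log(1+e^{k(t−m)})`
(numerically as `softplus`); integrating above zero instead of above the
starting level is a flag. Descriptors that do not exist for the fitted
shape — e.g. descending-limb times when `Max − Ending` is below tolerance,
or all times for a constant fit — are NaN and propagate as empty cells
through the long table and the median pivot.

## Dose–response

Titration responses (per-sample Max or Ending values, all points pooled —
by default three samples per concentration, matching the titration design)
are fit with the hyperbolic stimulation model
`Y = Bottom + X(Top−Bottom)/(EC50+X)` (Hill slope 1; a variable-slope 4PL
is optional). Initialization is deterministic; the fit errors out on a flat
response, where EC50 is unidentifiable. By construction the fitted curve
passes through `(EC50, (Top+Bottom)/2)`, and rescaling concentration units
rescales EC50 exactly.

## Statistics

Shapiro–Wilk screens normality (3 ≤ n ≤ 5000; constant vectors are
rejected as undefined). Matched designs: Wilcoxon signed-rank for two
groups (exact null for ≤ 25 non-zero differences, normal approximation
with continuity correction above), Friedman omnibus plus all pairwise
Wilcoxon tests BH-adjusted for more. The pairwise statistic behind the
Friedman follow-up is a documented, swappable choice. Independent designs:
Kruskal–Wallis plus Dunn's z on pooled ranks with tie correction,
BH-adjusted. Normally distributed data can be dispatched (automatically or
forced) to paired t-tests or two-way ANOVA with Tukey's HSD. The Friedman
p-value is the standard chi-square approximation; when validated against
permutation re-randomization its comparison uses the mid-p convention,
since the permutation distribution of the statistic is a lattice.

## Synthetic data

The generator emulates the acquisition design: Poisson event arrivals
(default 300 events/s), 60 s baseline + 720 s activation, six populations
(five B subsets at 60/10/12/5/1% of events plus 12% non-B lymphocytes),
scatter and marker channels drawn from per-population lognormal components
whose log-scale separation is configurable (default 6σ; the FMO "negative"
component equals the autofluorescence the FMO tubes draw from), and a
Fluo-4 signal equal to `baseline_mfi × f_pop(t − t_act) × loading × noise`
with per-cell lognormal dye-loading (CV 25%) and multiplicative noise
(CV 5%). Baseline-stream events carry the resting level only — cells
cannot respond before agent contact. All cells of a population share one
trajectory: per-cell kinetic heterogeneity is deliberately absent, which
is sufficient (and stated) because the analysis consumes population
medians. Real cytometry marginals are heavier-tailed and spectrally
coupled; passing gating tests therefore demonstrate correctness of the
gate logic under controllable overlap, not expected concordance on
instrument data.

Truth curves per subset and agent encode the qualitative study pattern:
memory subsets out-respond naive cells under BCR cross-linking, ASCs
respond but decay back without a plateau, ionomycin drives every subset
strongly with ASCs plateauing lowest, CpG gives a slow monotone rise, and
the not-activated control is flat (an optional linear drift emulates
instrument drift). Titration datasets scale both amplitudes by the
receptor occupancy `X/(EC50+X)` — scaling the rise alone would push the
plateau below the resting level at low doses — so Max−S and Ending−S are
exact hyperbolas in concentration with the true EC50. Generation is fully
deterministic in `(seed, agent, sample)`.

## Problem sizes

Test and acceptance runs use generation sizes chosen to keep the whole
suite desk-scale while leaving every estimate comfortably inside its
tolerance: 300 events/s for single-sample recovery and the 15-sample
pattern cohorts (ASC bins then hold ~15 events, enough for a stable
median), 40–100 events/s for structural and gating checks, 20 Monte-Carlo
replicates for noise-recovery medians, 2,000 simulations for null
calibration, 10⁵ permutations for p-value validation, and 3–4 cohort seeds
for the ordering-reproduction rate.

## Known limitations

Single-wavelength normalization only (no ratiometric Fura-2/Indo-1 mode);
population-median kinetics only (no single-cell trajectory fitting); no
spectral compensation or spillover simulation; no automated gating; FCS
2.0 and log-amplified legacy scaling unsupported. The window-maximum
convention makes `Max` depend on `t_end` for curves still rising at the
window edge.
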