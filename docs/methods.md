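# Methods

## Scores and band conventions

The three calculators implement additive point systems over presentation
variables. The published band labels are printed to one decimal
("22.4–27.9"); we read each as a half-open interval on the printed lower
edge ([22.4, 28)), so the bands tile the positive axis with no gaps — a
value such as BUN 22.35, falling in a printed gap, belongs to the interval
containing it under this convention. The original Blatchford bands are
contiguous, so the printed gaps are rounding artifacts, not exclusions.

Two threshold asymmetries are deliberate and preserved exactly as
specified by the scores: mGBS/GBS award the pulse point at **≥ 100**, the
Rockall shock item at **> 100** (a pulse of exactly 100 scores 1 in
mGBS/GBS and 0 in Pre-E RS). The Rockall shock item is a single ordinal
category: hypotension (SBP < 100, 2 points) takes precedence over
tachycardia (1 point); the two are never summed. BUN is scored in mg/dL
as the bands state; no urea/mmol conversion is offered. Presence flags
default to absent when a column is missing — the scores award points only
for documented presence — while vitals and labs are mandatory and
strictly positive, rejected with an error naming the field otherwise.

## AUC and the DeLong machinery

Grouped per-score counts are the native data shape. The AUC is the
tie-corrected Mann–Whitney estimator (ties credited ½), computed with
integer/rational arithmetic (`fractions.Fraction`) so grouped-count AUCs
are exact; it equals the trapezoidal area under the empirical ROC built
with the strictly-greater rule. The threshold convention matters: the
published threshold rows ("score > c") are only self-consistent under
strictly-greater, which is why the alternative ≥ rule is not offered.

Variances, 95% CIs and paired tests use the DeLong structural components.
For a class with a single member the component sample variance is
undefined; we define its contribution as zero (such a class carries no
estimable variability), which gives se = 0 for a one-pair perfect AUC.
When two score vectors produce identical AUC estimates the z statistic is
defined as exactly 0 (p = 1) rather than 0/0; a nonzero AUC difference
with zero estimated variance yields ±∞ and p = 0. CIs are the DeLong
normal-approximation interval auc ± 1.96·se truncated to [0, 1]; the
Hanley–McNeil variance is not offered.

The paired test requires patient-level pairing. The published tables are
marginal (per-system), so paired tests run only on per-patient cohorts —
in practice the synthetic generator's output — and the reproduction
report says so explicitly rather than substituting anything.

## Threshold diagnostics and 2×2 analyses

Metrics are kept unrounded internally; reports round to the conventional
precision (sens/spec 2 d.p., PPV/NPV 1 d.p., OR/chi-square 3 d.p.). An
empty denominator (e.g. PPV when nothing is called positive) is reported
as missing, never as 0 or 100. Youden-optimal cutoffs break ties toward
the smaller cutoff (favouring sensitivity in triage).

`reconstruct_confusion` inverts a printed (sens, spec) row to the integer
2×2 by nearest-integer rounding of sens·n⁺ and spec·n⁻; on every printed
row this reproduces the printed PPV and NPV at 1 d.p., which validates
both the inversion and the printed class sizes (280/310 for intervention,
25/565 for mortality).

Pearson's chi-square is computed without continuity correction; the
published statistics (21.675, 19.380) reproduce exactly without Yates and
do not reproduce with it, pinning the choice. The odds-ratio CI is
Woolf's log-normal interval (via `statsmodels` `Table2x2`), validated by
exact reproduction of both published CI pairs; it requires all four cells
positive, and a zero cell raises rather than silently applying a
continuity correction.

`derive_survivor_split` recovers unprinted survivor cells of a mortality
2×2 by exhaustive enumeration of integer splits, matching the one printed
statistic at 3 d.p. and failing loudly unless exactly one split matches.
For the delayed-endoscopy analyses both searches are unique and each
recovered table cross-validates against the *other* printed statistics.

## Fixtures and derived reconstructions

The study tables ship as commented CSV inside the package. Transcription
preserves print with one deliberate correction: the GBS score-9
intervention-negative cell is 66, not the printed 55, because two
independent printed constraints (row total 70, column total 310) both
force 66 — the marginals win over the single cell. The diagnosis table
sums to 588 as printed (two patients short of enrolment); it is inert and
uncorrected. The text's "397 patients with GBS > 9" disagrees with the
corrected count table's 399; the timing analyses use 397 as printed, and
both values sit in fixture metadata.

The per-score mortality distribution of the Rockall score is not printed;
it is derived by differencing the cumulative death counts implied by the
published mortality sensitivities (25 deaths; 23/22/22/8/8 above cutoffs
2–6) against the per-score totals. This locates all deaths at scores ≥ 3
and leaves two deaths somewhere at scores ≤ 2. Of the six feasible
placements (AUCs 0.908–0.949), exactly one — one death at score 0 and one
at score 2 — yields the published mortality AUC 0.929 at 3 d.p.; that
placement is the packaged derived fixture, the enumeration ships as
fixture metadata, and the sensitivity of the conclusion to the placement
is bounded by the enumerated AUC range.

Two published quantities are irrecoverable and left that way: the GBS and
mGBS intervention AUCs (0.727/0.733) — the printed grouped counts yield
0.653/0.632, so the count table and the published ROC analysis are
mutually inconsistent for those two systems — and all paired DeLong
p-values. The reproduction report lists both with reasons; the estimators
behind them are validated structurally instead (brute-force pair-counting
equivalence on every small input; DeLong se within 15% of a
10,000-replicate bootstrap at n = 20; ≥ 95% rejection rate for an
informative-vs-noise pair at n = 500 over 200 seeds).

## Synthetic cohort generator

The generator exists so every pipeline stage — including patient-level
analyses no printed table supports — is testable without any download. It
encodes the minimal structure behind the study's crossed result: two
independent standard-normal latent axes, **bleeding severity** and
**frailty**. Severity drives the four quantitative variables through
monotone links with Gaussian noise (pulse 86 + 16·S ± 10; SBP 118 − 15·S
± 12; BUN log-normal exp(3.3 + 0.5·S ± 0.35); Hb 9.5 − 2·S ± 1.3, −0.5
for women), truncated to physiologic ranges (pulse 40–180 bpm, SBP 60–220
mmHg, BUN 5–150 mg/dL, Hb 4–18 g/dL) so record invariants always hold.
Severity also drives melena, syncope and hepatic disease; frailty drives
age (a deterministic quantile map matching the published age-band
frequencies 28.1/22.5/49.3%), cardiac disease and severe comorbidity.
Need of intervention follows a logistic model on severity (slope 1.6);
30-day death follows one on frailty (slope 2.5). All intercepts are
solved by Gauss–Hermite quadrature so large-cohort marginals equal the
published frequencies (female 36.4%, melena 48.8%, syncope 3.4%, liver
disease 6.9%, heart disease 57.1%, death 4.2%, intervention 280/590);
the slopes and vital links are invented package defaults chosen once to
give a high-risk cohort resembling the published score distributions
(mean GBS/mGBS/Pre-E RS ≈ 9.6/7.8/2.8 against the published
10.0/9.4/2.0). A single integer seed feeds one `numpy` Generator; no
global RNG state is touched.

What the generator does *not* emulate: correlation between the two axes
(comorbid patients bleed no worse, by construction), measurement error or
missingness, time-to-event structure beyond the 30-day binary, and any
fit to real per-patient data (none exists to fit). Passing tests
therefore demonstrate that the pipeline recovers the structure the
generator encodes — e.g. that the Rockall score beats the Blatchford
scores on mortality AUC in ≥ 95% of seeds at n = 20 000 — not that real
cohorts exhibit that structure.

## Problem sizes and numerical choices

Fixture-path computations are exact and instantaneous (≤ 590 patients,
≤ 18 score levels, survivor searches over ≤ 377 splits). Stochastic
properties use 200 replicates at n = 500 for test power, 10 000 bootstrap
replicates at n = 20 for the variance cross-check, and 100 seeds at
n = 20 000 for the generator's discrimination-ordering property; the
parameter-recovery check refits the outcome models on one n = 50 000
cohort and requires agreement within 10%. Tie handling everywhere is
mid-probability; equality comparisons on derived statistics use the
printed precision of the quantity (3 d.p. for AUC/OR/chi-square), and
internal ROC/AUC identities are asserted to 1e-12.
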