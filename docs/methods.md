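# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the places where the design was genuinely open.

## Data model

Items are six-option (1–6) bipolar questions; higher = more impaired.
Responses live on the 1..6 scale everywhere except inside the Rasch
module, which recodes to 0-based analysis categories (a one-way, monotone
mapping recorded per item). Missing values are empty cells or the literal
`NA` in files and `NaN` in memory — no numeric sentinels. Reverse-scored
items (none in the motivating instrument; the flag defaults to false) are
recoded as 7 − x exactly once, at load. All thresholds driving the
analyses travel in one `AnalysisConfig`, so a run is reproducible from a
single configuration file.

## Item reduction

Five stages in fixed order; the first rule an item trips is the one
reported. All boundaries are strict inequalities, so an item at exactly
20 % missing, exactly 49 % floor, exactly r = 0.7, or exactly 5 used
categories is retained. Floor/ceiling denominators exclude missing
responses — the conservative reading of "percent of respondents".
Correlations use pairwise-complete observations (listwise deletion would
discard too much of a ~70-row cohort); pairs with fewer than 3 complete
observations or a zero-variance member are reported as undefined rather
than propagated as NaN.

Redundancy tie-break (open design point): of a pair with r above the
threshold, delete the member with the higher missing fraction, then the
higher floor fraction, then the later instrument position — keep the
better-measured item, deterministically. With more than two mutually
correlated items, pairs are processed in descending |r| and an
already-deleted item cannot trigger further deletions. Stage 5
("conceptual") is a user-supplied list only; ids in the list that are
absent from the instrument (e.g. already deleted in an earlier pass) are
skipped, which makes the algorithm idempotent on its own output.

## Multitrait scaling

The item × domain matrix uses Pearson correlations on pairwise-complete
respondents. The overlap correction (own-domain score excludes the item)
is the default — the standard convention; an uncorrected flag preserves
the alternative since the original study does not state its choice. The
correlated-correlations z-test follows the Meng–Rosenthal–Rubin form with
the shrinkage factor f capped at 1 (unit-tested). N per comparison is the
smaller of the two cells' pairwise-complete counts; r_yy is the
correlation between the two domain scores involved (the item-corrected
own score when the matrix is corrected). Tests are two-sided at α = 0.05.
Ties (r₁ = r₂) classify as probable with z = 0. Rescaling is a single
pass of proposals — the analyst accepts moves and re-runs; the pipeline
never iterates rescaling to convergence.

## Partial credit model

Model choice: per-item step difficulties (PCM), not a shared rating
scale — items within one instrument can use different numbers of
categories, which a rating-scale model cannot express. Estimation is
joint maximum likelihood: alternating Newton sweeps over step
difficulties and person measures. Each block update uses the diagonal
observed information as a preconditioner with a per-item / per-person
backtracking line search (block likelihoods are separable), so the joint
likelihood is non-decreasing by construction — tracked explicitly when
`track_likelihood` is on. Items are re-centred each cycle so the mean
item difficulty is 0 (the identification constraint); convergence is the
largest cycle-over-cycle parameter change on that identified scale
falling below 0.001 logits (default), with a 200-cycle cap reported as
non-convergence. Parameters are clamped to ±10 logits during iteration.

Categories the sample never used are removed structurally (renumbering),
so an item observed in c categories is estimated with c − 1 thresholds.
Persons answering everything at the minimum (or maximum) analysis
category carry no information and are excluded; exclusions cascade to a
fixed point (perfectly deterministic Guttman-style data therefore
collapses entirely — a property, not a bug, of ML estimation in the
Rasch family). Excluded extremes receive finite post-hoc measures by
solving for θ at a raw score adjusted 0.3 score points inward (a
convention, flagged as extrapolated). Missing responses are simply
omitted from the sums — JMLE handles incomplete data natively; nothing is
imputed inside the Rasch stage. An optional (L−1)/L multiplicative
correction for the known JMLE step bias is available (default off);
parameter-recovery studies switch it on because they measure estimator
accuracy.

Fit: infit is the information-weighted mean-square residual, outfit the
unweighted mean; the useful band is [0.5, 1.5] with values above 2.0
classified as degrading and everything else (including below 0.5, the
overfit direction) as noisy-but-usable.

## Scoring and validity

Scale scores are sums; when responses are missing, the unrounded mean of
the answered items substitutes for each missing one provided at least
half the scale is answered — "at least half" is inclusive, and the
unrounded mean avoids manufacturing floor/ceiling hits from rounding.
Cronbach's alpha uses respondents complete on the scale: imputation is a
scoring convenience, not part of the measurement model. The total score
sums all final items (domain members plus standalone items), not the
domain scores.

Severity correlations are restricted to respondents whose spirometry fell
within 92 days of the questionnaire. Tertiles use interpolated (type-7)
sample quantiles with boundary respondents assigned to the lower
tertile. Group comparisons are pooled-variance t-tests (a Welch flag
exists, default off); the effect size SDU is the mean difference divided
by the pooled SD. No multiple-testing adjustment is applied — per-scale
unadjusted p-values mirror standard practice for instrument-development
reports. (In the published oxygen-group table the total-score difference
prints as 32.7 while the printed means give 32.8 — unrounded means behind
the table, presumably — so summary-level recomputation is only asserted
for the scales whose printed values reconcile exactly.)

## Synthetic cohort

The generator is first-class, tested code; it defines the study
conditions for every downstream test. Defaults: 69 respondents × 56
items; four latent traits (exertional dyspnea, cough, fatigue,
emotional well-being) with correlations 0.4–0.5 among dyspnea, fatigue
and emotional and 0.1 between cough and everything else; 29 clean domain
items (13/6/5/5, echoing the final published structure), 3 clean
standalone items driven by an equally weighted composite, and 24 planted
defects: 3 restricted-category items (outer steps at ±13 logits, so the
extreme categories have probability < 10⁻⁴ anywhere in |θ| ≤ 3), 2
heavy-missing items (35 % MCAR), 10 floor-heavy items (steps shifted +3
logits, putting ~3/4 of the population at the floor — unambiguous at
n = 69), 7 redundant near-duplicates, and 2 standalone "relationship"
items earmarked for conceptual deletion. Background missingness is 1 %
MCAR (missingness is minimal in such studies; MCAR keeps the
deletion-rule ground truth unambiguous).

Responses are drawn from the PCM through the same probability function
the Rasch module estimates with — one shared implementation, so
simulation and estimation cannot drift apart. Each item's latent
propensity is λ·η_trait + √(1−λ²)·ε with loading λ = 0.85: real items
are imperfect indicators of their trait, and a loading below 1 keeps
distinct same-trait items from crossing the redundancy threshold by
sampling accident at n = 69 (with λ = 1 the population same-trait
correlation is ≈ 0.5 and spurious r > 0.7 pairs appear in over a third of
cohorts). The resulting clean-domain alphas are ≈ 0.75 (5–6-item scales)
to ≈ 0.88 (13-item scale) — high, though below the published instrument's
0.89–0.94, which would require inter-item correlations incompatible with
a false-positive-free redundancy rule at this sample size. Redundant
partners copy the partner's realized latent propensity plus N(0, 0.1)
noise and reuse the partner's categorization random draw (common random
numbers); a single 6-category item's reliability otherwise caps the
observed pair correlation near 0.6, below the 0.7 rule. Each item's
marginal distribution remains exactly PCM. Duplicates also carry 10 %
missingness — near-duplicate items plausibly get skipped, and it makes
the tie-break keep the original deterministically.

Severity is percent-predicted-FEV1-like: 65 − 10·η_dyspnea − 8·η_fatigue
+ N(0, 14²), clipped to [0, 150] (mean ≈ 65, SD ≈ 21). Cough enters only
through its 0.1 trait correlation, giving r(severity, cough score) ≈
−0.08 versus ≈ −0.64 for dyspnea. Oxygen use is "ever" iff severity <
60 %, flipped with probability 0.05 (record misclassification).
Spirometry windows are uniform on 0–120 days, so the 92-day filter
removes about a quarter of respondents. One global random stream per run,
seeded from the spec.

What the generator does *not* emulate: informative missingness,
differential item functioning, response styles, test–retest structure,
or the qualitative item-authoring phase. Passing tests therefore show the
pipeline's statistical machinery is correct under a known PCM world, not
that the real instrument's published coefficients are recoverable.

## Study sizes used in tests and the acceptance script

Chosen as the smallest sizes at which each quantity is stable: deletion
ground truth at the native n = 69 over 20 seeds; correlation-level
properties (scaling, validity directions) on an n = 500 variant;
parameter recovery on 500 persons × 29 three-category items — with three
categories every threshold sits in dense data, so step difficulties are
recovered with r > 0.99 and RMSE < 0.15 logits (with 6-category items
each threshold's sampling SD alone is ≈ 0.16–0.2 logits at this n, so
precision targets of that order are a property of the design, not the
estimator); calibrations at 2000 null replicates (Monte-Carlo SE on a 5 %
rate ≈ 0.5 percentage points). The planted-misfit check adds one item
whose responses are driven by an independent trait; its infit lands near
1.6–1.8 against ≈ 0.96 for clean items.

## Known limitations

JMLE carries the usual incidental-parameter bias (mitigated, not removed,
by the optional (L−1)/L correction) and is evaluated here by parameter
recovery rather than against an external implementation. The Meng test's
N uses the more conservative of the two cells' pairwise-complete counts —
with heavy, uneven missingness a dedicated missing-data model would be
preferable. Dimensionality is assessed through fit statistics only; no
factor analysis, DIF analysis, responsiveness or minimal-important-
difference estimation is included.
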