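# Methods

This note documents the models, parameters and design decisions behind
`esmine`: what each stage assumes, which knobs matter, and what the synthetic
test bed does and does not establish about real literature.

## Detection grammar

Detection is windowed pattern matching, not sentence-level NLP.  An ES term
(acronym `OR`/`RR`/`HR`, adjusted acronym `aOR`/`aRR`/`aHR`, or full wording
with optional plural/hyphen/`adjusted` prefix) is paired with the nearest
following number within an 80-character **statement window**, provided no
second ES term intervenes; the CI is then parsed from the 120 characters
after the value.  The window sizes are a design choice balancing recall
against false pairing: common reporting styles put the value within a few
tokens of the term, while 80 characters still tolerates interposed clauses.
Statements whose value sits beyond the window are accepted false negatives
(the generator's "undetectable" style renders exactly this case).

The CI grammar recognizes level-first ("95% CI", "95 % CI", "95% confidence
interval"), level-last ("CI 95%") and level-less introducers, brackets
`()`/`[]`/none, and the range separators `-`, `–`, `—`, `to`, `;`, plus `,`
inside brackets only (an unbracketed comma range is indistinguishable from a
list).  Decimal commas are converted only when *both* bounds match the
`digits,1-2 digits` shape.  A CI with no stated level is assigned 95 — by
far the dominant convention — and flagged `ci_level_imputed` so subgroup
analyses can exclude imputed levels.  Reversed bounds make the CI parse fail
and flag the mention (`bounds_swapped_discarded`) rather than silently
swapping: a reversed interval usually signals a mis-paired range, not a typo.

**Polysemy.**  Acronym collisions are handled text-globally and
per-acronym: if any registered trap wording ("heart rate" for HR, etc.)
occurs anywhere in the text, bare-acronym mentions of that acronym are
suppressed, and adjusted acronyms are kept only when backed by a CI; full
wordings are always kept (a spelled-out "hazard ratio" cannot be a heart
rate).  This is deliberately conservative — specificity is the scarce
quantity at corpus scale, where true negatives outnumber true positives by
~50:1 and even a 0.1% false-positive rate would rival the true-positive
count.

**Plausibility.**  The numeric filter drops values outside (0, 10 000] and
values outside their own CI beyond a 5% relative tolerance (covering
rounding in the source text).  It is numeric only; it never revisits
polysemy, and it never modifies values.  CI-less mentions are retained
flagged, since downstream condensation filters on CI presence anyway.

## Transformations and condensation

Four modes: raw (T4), `ln v` (T2), inverse-standardized on the original
scale (T1: protective values inverted), and normalized-then-standardized
reported on the linear scale (T3: `exp|ln v|`).  T1 and T3 coincide
pointwise; the distinction is aggregation — the per-abstract mean is taken
on the log scale (`exp(mean |ln v|)`, a geometric mean), which is the
natural scale for ratio measures and makes the summary invariant under the
protective↔risk inversion `(v, L, U) → (1/v, 1/U, 1/L)`.  The published
figure-legend descriptions pin these modes down only partially; the mapping
used here is a reconstruction from the stated scales and aggregation rules,
and the T-mode is recorded in output metadata so a different reading can be
swapped in.

Classification thresholds are inclusive: *large* when `v ≤ 0.2` or `v ≥ 5`,
*tiny* when `0.95 ≤ v ≤ 1.05` — except `v = 1` exactly, which is *neutral*,
its own direction class, excluded from the tiny count and from risk/
protective medians.  Significance requires the CI to exclude 1; a limit
exactly at 1 is read as encompassing (not significant), the conservative
reading.  "Nearest to / farthest from 1" for `es_min`/`es_max` is measured
in `|ln|` distance so the extremes are well defined when protective and risk
values coexist in one abstract.

The primary analysis profile condenses non-review abstracts using mentions
with a 95% CI; review-only and 90/99%-CI subgroups reuse the identical
condensation with a different upstream filter, never different formulas.

## Trend statistics

Mann-Kendall with tie-corrected variance, ±1 continuity correction, and a
two-sided normal p-value; the minimum series length for the approximation
defaults to 8.  Kendall's τ is reported as τ-b (tie-adjusted denominator)
because monthly medians tie frequently; τ-a is exposed for sensitivity
analyses since published τ values may have used either.  Months are
calendar months since 1990-01 (index 0) through 2015-12 (index 311); months
with no abstracts are absent from the series, not zero-filled — imputing
empty months would manufacture trend signal.  The significance threshold
for trend verdicts is P < 0.001 (configurable α).

Dunn's post-hoc z-tests use Bonferroni adjustment by default (Holm
available) and are summarized with an insert-and-absorb compact letter
display.  Mann-Whitney uses the tie-corrected normal approximation; at very
small group sizes (≤ ~8 per group) an exact test would be preferable, but
the pipeline's group comparisons operate on thousands of abstracts per
group.

## Synthetic corpus

The generator emulates the features the pipeline must measure, not
linguistic realism:

- `|ln ES|` is half-normal with scale interpolating linearly across the
  month range (default 1.36 → 1.11, chosen so monthly medians of
  standardized ESs sweep from ≈2.5 down to ≈2.1, the magnitudes the
  pipeline targets on real data); the sign of `ln ES` is ±1 equiprobably,
  so the corpus is inversion-symmetric by construction.
- CIs are geometric around the value, `(v·e^{−w}, v·e^{+w})`, with the
  half-width's schedule 0.70 → 0.54 and lognormal mention-level noise
  (σ = 0.3).  A monthly significance schedule (default 0.74 → 0.85) is
  enforced by clamping `w` below/above `|ln v|`, which preserves the
  geometric symmetry; ground-truth significance is recomputed from the
  *printed* (rounded) bounds, so gold never disagrees with what a reader of
  the abstract would conclude.
- Eight detectable rendering styles cover acronym vs wording, adjusted
  variants, `=`/`:`/comma separators, `()`/`[]`/bare brackets, `–`/`to`
  ranges, level placement before/after, and 1–3 decimal precision; the
  printed lower bound is floored and the upper ceiled at the style's
  precision so `L ≤ v ≤ U` survives rounding, and precision is bumped when
  flooring would print a zero bound.  A ninth, "undetectable" style parks
  the value beyond the statement window and is excluded from sensitivity
  scoring.
- Trap sentences (rate 0.1) reuse each acronym for a non-ES quantity;
  abstracts carry ESs with probability 0.3 (an enriched validation mixture:
  real PubMed abstracts carry ESs far more rarely, but a validation corpus
  needs both classes well populated), with 1–5 statements per positive
  abstract (mean ≈ 2.4).
- Metadata (dates, including numeric-month and free-form `MedlineDate`
  variants; MeSH descriptors; journals drawn from the shipped OA/CCJ/plain
  lists; 1–2 country affiliations with a 5% cross-continental rate; 10%
  reviews) exercises the reader and annotator paths.

Determinism: each abstract gets its own counter-based substream seeded by
`(seed, month, slot)`, so corpora are byte-identical across runs and stable
under parallel generation.

**What passing tests do and do not show.**  On this corpus the detector
reaches ≈98% mention-level sensitivity (the shortfall is restrictive-mode
suppression, by design) and ≥99.9% abstract-level specificity.  The
generator's styles are drawn from the same dialect family the grammar
targets, so these figures bound performance on *covered* styles only; real
abstracts contain long-tail phrasings the corpus does not model, and real
sensitivity depends on that tail's mass.  Trend-recovery results show the
statistics chain is unbiased under the generator's drift model; they cannot
validate the drift model itself against real literature.

## Annotation resources

All lookups are flat TSV configs with documented columns, loadable from
user paths: gazetteer (country, continent, `|`-separated aliases; longest
match wins, so "South Korea" beats the "Korea" alias; historical entities
map via aliases), MeSH descriptor → tree numbers (field = first two tree
levels within branches C and G), OA and CCJ journal lists (ISSN primary,
normalized-title fallback).  The shipped OA list is a small fixture —
era-accurate OA status is a data-provenance problem, and the list is meant
to be replaced; the shipped CCJ list is a subset of the NLM Abridged Index
Medicus titles.  Field-level trend reports prune branches below 1 000
abstracts; pruning never touches per-citation annotation.

## Numerical and degenerate-input choices

- Unicode minus and typographic spaces are normalized 1:1 inside the
  detector so spans keep their original offsets; the reader leaves dashes
  untouched.
- Mention matching in evaluation rounds numbers to 6 decimals before exact
  comparison (TSV round trips).
- An abstract with no month is excluded from monthly series rather than
  imputed.
- Constant series give S = 0, τ = 0, p = 1; a tie-saturated τ-b denominator
  of zero reports τ = 0.
- Cohen's κ with `p_e = 1` (all mass in one cell) returns 1 for perfect
  agreement, else 0.
- `evaluate_detection` at the mention unit counts trap records as the
  negative units (a trap is a true negative when it attracts no false
  positive of its type in its abstract); the abstract unit needs the full
  corpus universe because pure negatives carry no gold rows.

## Problem sizes used in the validation battery

The shipped test battery uses a 2 160-abstract validation corpus (24 months
× 90), full-window trend recovery at 312 months × 30 abstracts, 10 000
replicates for the type-I calibration of the Mann-Kendall test, and an
exhaustive oracle over all value series of length ≤ 10 on a 3-letter
alphabet.  These sizes give stable estimates (binomial SE on sensitivity at
n ≈ 1 500 is ≈ 0.4 points) while keeping the whole battery under a minute.

## Known limitations

- The grammar targets the enumerated dialects; ESs phrased outside them
  (e.g. value-first "1.9 (95% CI 1.1–3.3) for the odds ratio") are missed.
- ESs expressed per unit of a continuous variable are not filtered out and
  are indistinguishable from categorical-contrast ESs.
- Other ES metrics (Cohen's d, Hedges' g, correlations) are out of scope,
  as is converting them to ORs.
- The trap list ships as a static config; it is not a live abbreviation
  database, and coverage of rarer collisions depends on the user's list.
- No autocorrelation correction (e.g. Hamed-Rao) in the trend test;
  monthly medians of independent abstracts are treated as exchangeable
  under the null.
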