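# Methods

## Scope and model

`bindyn` starts where differential-expression calling ends: its inputs are
per-comparison DEG tables (gene, log₂ fold-change, adjusted p), a
gene→functional-bin map, and a manifest tying comparisons to growth stages
and soil-water status. Upstream read processing, assembly, mapping and the
DE test itself are out of scope, as is rendering pathway diagrams.

A DEG is defined by threshold exceedance only: |log₂FC| > `lfc_min`
(strict) and adjusted p ≤ `alpha` (inclusive), defaults 1 and 0.05. The
strict/inclusive split matters at the boundaries — a gene at exactly
|log₂FC| = 1 is not a DEG, one at exactly p = 0.05 is — and both boundary
cases are tested explicitly. Filtering is idempotent and monotone in the
thresholds. p-values are consumed as already adjusted; a
Benjamini–Hochberg step (via statsmodels) is available as an explicit
opt-in for tables carrying raw p-values, never applied implicitly,
because the adjustment used upstream is generally unknown.

## Bin accounting

Each gene resolves to exactly one bin. When a mapping file lists a gene
under several bins, the bin with the lexicographically-lowest dotted code
(numeric comparison per segment, so 1.9 < 1.10 < 2) wins. This
primary-bin rule is what makes per-bin counts sum exactly to per-stage
totals: every DEG is counted once, unmapped genes in the reserved
"Not assigned" bin, which is materialized as an ordinary row so totals
are conserved. The bin universe of a count matrix is the union of bins
observed at any stage (absent-everywhere bins are omitted, not
zero-filled), ordered by bin code with "Not assigned" last.

## The two statistics

*Percentage of total* is `100·N[b,s]/total_s`; columns sum to 100 and an
empty stage yields an all-NaN column rather than an error. It is the
conventional annotation-tool profile and is reported mainly as the
baseline against which the second statistic is motivated: it scales with
the number of genes a function employs, so gene-rich housekeeping
categories dominate regardless of biology.

*Percentage change from baseline* is
`round(100·(N[b,t]−N[b,s])/N[b,s])`, undefined when the baseline count is
zero. It is deliberately asymmetric — pct_change(a,b) ≠ −pct_change(b,a)
— because each direction is normalized by its own baseline; this is a
property of the statistic, documented and tested, not a bug. Transition
labels (up/down/nc) come from the raw counts, so a 0→k transition is
"up" even though its percent change is `na`; conversely, a change smaller
than half a percent of the baseline rounds to a printed 0 while its
pattern label still reflects the raw count direction.

All printed percentages round half-away-from-zero. This convention is the
only one consistent with every verifiable cell of the reference table
(86.67→87, −15.79→−16, 184.48→184, 8.63→9); Python's default banker's
rounding would disagree on ties.

The per-transition **mean percent change** averages the rounded integer
per-bin values over every bin with a defined value — including
"Not assigned", excluding zero-baseline bins — and rounds the result.
This include-unassigned / exclude-undefined rule reproduces the reference
means (307 / 6 / 191) in all three transitions; for the reference matrix,
averaging the unrounded values gives identical results, so the choice of
averaging the displayed integers is cosmetic there and is kept for
display-consistency.

One cell of the reference table is internally inconsistent: a bin with
counts 0→0 is printed with pattern "up", although an equal-count
transition is by definition "nc". The implementation follows the
definition; the test oracle records "nc" for that cell.

## Pathway subsets and the stage t-test

Pathway membership is configuration, not code: the shipped default maps
bin-code prefixes (1.1 light reactions, 1.2 photorespiration, 1.3 Calvin
cycle, 2.1.1/2.1.2/2.2.1/2.2.2 sucrose/starch synthesis/degradation) and
is overridable by a JSON file of bin prefixes and/or explicit gene lists,
since published analyses rarely print their gene-to-sub-pathway tables. A
DEG is "unique" to a pathway iff it occurs in exactly one stage's set;
unique + shared = total distinct, and sub-pathway per-stage counts sum to
their parent's when the sub-pathways partition it.

The stage comparison uses a two-sample two-sided pooled-variance
(Student) t-test on replicate-level DEG counts, significant at p < 0.05
strict. Pooled variance is the field default for a balanced n = 3 design;
Welch is available via `equal_var=False`. Two constant samples with equal
means give t = 0, p = 1 by convention. Whether the original analysis
tested replicate counts or some other replicate statistic is not
documented; the replicate-count interpretation is an explicit assumption
of this package.

## Synthetic data generator

The generator emulates the *statistical structure* the pipeline consumes
— threshold exceedance, bin membership, up/down split, cross-stage
identity overlap — not expression biology. There is no count model, no
negative-binomial noise, no correlation structure: a planted gene's
|log₂FC| is uniform on ±[1.5, 8], its adjusted p uniform below 0.049;
non-DEGs keep |log₂FC| ≤ 0.9 or p ≥ `null_p_floor` (default 0.2), with
background classes that exercise each criterion separately. The margins
around both thresholds mean floating-point cannot flip a gene's status,
so the pipeline recovers any feasible target matrix *exactly* — the
round-trip property the test suite leans on. Consequently, passing tests
demonstrate correct accounting and statistic computation, not robustness
to borderline effect sizes or miscalibrated p-values, which real data
can exhibit.

Defaults describe the reference study's conditions: a 24,000-gene leaf
transcriptome universe, three stages (pwd R2 / wd R3 / ww R4) with the
published per-bin DEG targets and up-fractions, three biological
replicates, and replicate noise of SD 50 DEG counts per bin (a few
percent of stage totals of ~1,000–3,000; the study does not report
replicate-level dispersion, so this is a fixed realism choice).
`stage_overlap` (default 0.05) controls the fraction of a bin's DEG
identities reused from the previous stage, giving the low cross-stage
sharing seen in the study's pathway sets (e.g. 19 of 20 major-CHO DEGs
stage-specific). One `numpy.random.default_rng(seed)` stream drives all
draws; identical specs produce byte-identical files.

Replicate tables jitter each bin's count by rounded Gaussian noise
truncated at zero, then add/remove genes from per-bin spare pools; bin
pools are sized `max stage count + ceil(4·sd) + 4` so jitter never
exhausts a pool, and infeasible specs (pools exceeding the universe) are
rejected before any file is written.

## Numerical and degenerate-input choices

* Undefined percentages serialize as the token `na`, no-change patterns
  as `nc`; result tables are TSV with fixed integer formatting and
  write→read round-trips are exact.
* An empty DEG list yields an all-zero summary with 0 % up/down (not
  NaN); pct_up and pct_down round independently, so they may sum to
  99 or 101.
* Negative counts, empty trajectories, p-values outside [0,1], duplicate
  gene ids and malformed bin codes are contract violations raising typed
  errors, not silently coerced.
* Dotted bin codes compare numerically per segment everywhere (ordering,
  primary-bin resolution, prefix matching).

## Problem sizes

The test suite and the acceptance script run the full reference-scale
simulation (24,000 genes × 3 stages × 4 tables each) plus many
hundred-gene micro-simulations; the whole suite completes in a few
seconds on one CPU, chosen so the exact-recovery property can be checked
at the study's actual scale rather than a toy one.

## Known limitations

* The generator cannot produce borderline cases by design; robustness to
  near-threshold data is untested and out of scope.
* The t-test interpretation of "difference between stages" (replicate
  DEG counts) is an assumption, as noted above.
* Percentage-of-total denominators in some published figure captions are
  ambiguous (total vs assigned DEGs); this package always uses the
  stage's total DEG count and documents that choice rather than guessing
  per-figure.
* Plotting is not part of the contract; outputs are tables meant for
  downstream tools.
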