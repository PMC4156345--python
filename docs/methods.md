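# Methods

This note documents the models, conventions and numerical choices behind
`ocsn`, and what the synthetic generator does and does not emulate.

## Data model and cleaning

An interaction is one post or comment: `item_id`, `user_id`, naive local
timestamp, `kind`, `thread_id` (the root post's id; posts are their own
root), and text or its surrogate (whitespace word count plus SHA-1 digest of
the exact UTF-8 bytes). Timestamps are treated as a single local timezone
with no timezone arithmetic. Comments whose root post is absent are loaded
and flagged as orphans, never discarded — truncated extracts are common and
orphans still carry user activity.

Deduplication compares digests **within a thread only**; identical text in
different threads is legitimate repetition (e.g. a stock greeting) and is
retained. Among within-thread duplicates the earliest timestamp survives,
ties broken by smallest item id. Text is hashed exactly as stored — no case
folding or whitespace normalisation — because accidental double-submissions
are byte-identical, and any normalisation would silently merge near-misses.
Cleaning is a projection: a second pass removes nothing, and the report
counts always satisfy `n_raw = n_final + n_dup + n_staff`.

## Engagement classification

"Three months" is operationalised as a 90-day window advanced daily (the
HEU bar is exactly "two or more items per day over 90 days"); calendar-month
triplets would be coarser and make the threshold depend on month lengths.
Windows are constrained to lie wholly inside the calendar year being
classified, so annual labels never borrow activity from adjacent years;
users with zero items in the year are excluded from that year's
classification. Thresholds (HEU ≥ 180, MEU ≤ 2, window 90 days) are
parameters with these defaults.

Contribution CIs use the percentile bootstrap over **users** (n_boot = 2000
by default, seed mandatory): labels stay fixed and each resample recomputes
group and total item counts from the sampled users. ± figures are
half-widths of the 95% interval. The two-proportion test uses the pooled
z statistic with an unpooled Wald CI, the textbook large-sample pairing.

## Temporal models

A first-time post is the first post (not comment) a user ever makes, judged
against the full history when one is supplied. Monthly counts get exact
Garwood intervals from chi-square quantiles (`[χ²(α/2, 2k)/2,
χ²(1−α/2, 2k+2)/2]`, lower bound 0 at k = 0) rather than normal
approximations, because small months occur in modest simulations.

The weekday model is a GEE with a saturated day-of-week factor, Poisson
variance, identity link, independence working correlation, and clusters at
the ISO-8601 week (Monday start, matching the Monday-anchored contrasts).
With this working structure the point estimates are exactly the per-weekday
arithmetic means of daily totals — the fit is started at those means, so
convergence is immediate and the identity holds to machine precision —
while the sandwich covariance over weeks absorbs within-week correlation.
Weeks in which a calendar event falls on Monday–Friday are excluded before
fitting; weekend events exclude nothing. The bundled calendar (NZ national
public holidays incl. Mondayised observances, plus World Smokefree Day,
31 May) is an editable YAML. A constant series makes every contrast 0 with
zero variance; that degenerate case is reported as z = 0, p = 1.

## Early MEU prediction

A user's start date is their first item's date (registration data are not in
scope). First day = that calendar date; first week = that date plus six
days; word length = whitespace token count. The MEU label is ≤ 2 items in
the 90 calendar days from the start date, and labelling refuses cohorts
whose follow-up would run past the data. The 70/30 split is simple random
(not stratified), seeded. Models are unregularised maximum-likelihood
logistic fits; complete separation is flagged on the report but scores are
still produced. Retained variable sets are fixed (first-day: posts,
comments made, % comments, total words; first-week: posts, comments made);
an exhaustive subset search over the candidate list exists but is off the
default path. A score of exactly 0.5 predicts non-MEU. AUROC is the
Mann–Whitney rank statistic with ties counted half, exact against all-pairs
enumeration.

## Reporting conventions

Means are totals over denominators; 95% margins use the normal
approximation (1.96·s/√n) and IQRs the midpoint-interpolation quantile
convention; growth is rounded to integer percent and is undefined (flagged
`None`, never sign-flipped) on a zero or empty base. Activity span is
inclusive of both endpoints, so a user active 1 Jan–31 Dec of a leap year
spans 366 days. Comments are attributed to the year of their own timestamp;
comments-per-post counts all in-thread comments within the analysis period,
regardless of the comment's calendar year.

## The synthetic generator

The generator is a calibration device, not a behavioural model of any real
community. Users draw an engagement class from a finite mixture — defaults:
3% "high" (8 items/active day, ~180 active days, decay scale 240 d), 57%
"regular" (1.5, ~25, 45 d), 40% "minimal" (0.55, ~1.2, 30 d) — a
first-activity date (month weights peaked in January with a late-May bump
and December trough; successive years scaled ×1.5; day uniform), and an
active-day set whose days after the first decay exponentially, concentrating
activity early in a user's life as observed for new community members. Each
active day emits Poisson items modulated by weekday weights (work-week high,
Friday dip, weekend low); the first active day emits at least one item so
the drawn start date is observable. A share 1/(1+`comment_rate`) of items
open threads; the rest attach to a uniformly chosen post from the preceding
seven days, so posts attract `comment_rate` (default 6) comments on average
and comments come from concurrently active other users, which keeps
comments-received features non-degenerate. Artifact injection appends
verbatim copies 1–60 s later in the same thread (0.4% of items by default)
and staff replies under a single reserved account (6% of posts), all
flagged in the ground truth. Base texts are drawn from a pseudo-word
vocabulary and re-rolled until unique within each thread, so exact-text
duplicates exist *only* as injected artifacts and cleaning can be verified
exactly against the flags.

These defaults were calibrated once against the qualitative anchors of real
OCSN usage (≈14% of items are posts, ≈6 comments per post with ≈1%
uncommented, a top-3% user group contributing the majority of items,
year-over-year arrival growth ≈50%) and are not adjusted per analysis. What
the generator does **not** emulate: message content and semantics, lurkers
(no observable events), comment-on-comment structure, user-level
autocorrelation beyond the active-day mechanism, or any linkage between
engagement and cessation outcomes. Tests passing on synthetic data
therefore validate the pipeline's correctness and its behaviour under the
assumed statistical structure — not substantive claims about any real
network.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (`SimConfig.seed`,
bootstrap/split seeds); identical configs give byte-identical streams. The
test suite runs simulations at 300–2,800 users (the cleaning worked example
runs at its full published scale of 134,782 items, which the generator
produces in seconds), the bootstrap coverage check at 500 replicates of
40-user cohorts with n_boot = 200, and the Garwood coverage check at 10,000
replicates of rate-20 Poisson draws — sizes chosen so the whole suite
completes in well under a minute while keeping every statistical check
comfortably powered.

## Known limitations

* The HEU/MEU thresholds are absolute by design (stable under network
  growth, easy to operationalise in interventions) but arbitrary; nothing
  here relates them to cessation outcomes.
* GEE results are only as good as the independence working correlation;
  strong within-week dependence is absorbed by the sandwich variance but
  not modelled.
* The Wald CI of the two-proportion test can be poor at extreme
  proportions or tiny samples; the permutation cross-checks in the tests
  bound the error at moderate sizes only.
* `window_max` confines windows to the calendar year, so genuinely
  sustained activity straddling New Year can be under-counted for
  late-year starters — a property of the definition, not a bug.
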