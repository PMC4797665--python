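# Methods

## Input model

The toolkit consumes four delimited text files (comma by default, tab via a
flag; UTF-8 with a header row):

| file      | columns                                | one row per |
|-----------|----------------------------------------|-------------|
| page flow | `user_id,page_id,start,duration_s`     | page view   |
| user data | `user_id,<free columns>`               | participant |
| coding    | `page_id,code,group_label`             | page        |
| colors    | `code,hex`                             | page group  |

Timestamps are ISO 8601 and normalized to UTC (naive timestamps are assumed
UTC); durations are non-negative reals in seconds. `user_id` is treated as
an opaque string throughout so mixed ID schemes survive round trips. Many
pages share one code; each code has exactly one group label — the group is
the unit of coloring, aggregation and filtering. Pages absent from the
coding file map to the reserved code 0 / group `uncoded` / color `#CCCCCC`:
coding gaps then show up as gray in plots rather than silently disappearing.
Strict assembly turns any unresolvable page or user into an error instead.

## Sequences and binning

Each participant's views are sorted by start time (file order breaks ties),
mapped to group codes, and quantized into 30-second blocks:
`blocks = max(1, ceil(duration / 30))`. Partial blocks round **up** with a
one-block floor so that every visited page is visible in the plot — a 2-s
glance and a 29-s read both occupy one block. Adjacent views with equal
code merge into runs; merging preserves the block total, so total viewing
time is conserved regardless of how views are split or merged. The x-axis
is cumulative viewing time: calendar gaps between logins carry no width.

"Sequence length", the plot-ordering key, is total viewing time in blocks
(not page count); ties order lexicographically by user id so output is
deterministic.

### Occasions and reuse

Reuse statistics need a notion of a login occasion. A new occasion starts
when the gap between the end of one view (`start + duration`) and the start
of the next exceeds **60 minutes**. A participant *reused* a page group if
they viewed it on at least two distinct occasions — i.e. on some occasion
after the occasion of first exposure. The 60-minute threshold is a design
choice (typical session-timeout scale for web analytics); it is exposed as
a parameter everywhere it matters.

### Percentage conventions

Usage tables in this literature mix two rounding conventions, and the
package reproduces both explicitly rather than guessing per value:
`pct_1dp` truncates to one decimal (104/132 → 78.7, 76/132 → 57.5) and
`pct_int` rounds half away from zero (120/132 → 91, 62/132 → 47). Both use
exact integer arithmetic, so no floating-point edge case can flip a printed
digit.

## Plots

All four plot types draw each run as one bar patch, which makes the
rendering contract testable on the scene graph rather than on rasters: the
number of lanes equals the number of sequences, and a lane's summed patch
width equals the participant's `total_blocks`. SVG output is
byte-reproducible: matplotlib's `svg.hashsalt` is pinned to the seed and
date metadata is suppressed.

The *clustered* plot groups participants by usage profile. The feature
vector is total blocks per code, L2-normalized so profiles compare by
shape, not volume; clustering is agglomerative with Ward linkage on
Euclidean distance — chosen for determinism and interpretability, since the
input order is the only thing that could break ties. With `k='auto'` the
cluster count in 2..8 maximizing mean silhouette is used. Whether any
particular historical tool used this clustering cannot be asserted; the
method is documented here as this package's reconstruction.

## Cohorts and moderator tests

Filters (exposure: seen / not seen / reused / not reused a group; variable:
`==,!=,<,<=,>,>=,in` predicates) combine by conjunction only, which keeps
provenance unambiguous — OR is expressible by unioning two exports.
`usage_indicator` materializes an exposure as a 0/1 user-table column; the
moderator report then compares every requested variable between the two
indicator levels: pooled t for numeric variables (Welch on demand),
Pearson chi-square for categorical ones, optional Benjamini–Hochberg
adjustment. Group order is (indicator = 0) − (indicator = 1), so "users
scored higher" prints as a negative t. CSV is the canonical export format
(bit-exact and diffable); XLSX is offered for spreadsheet follow-up.

Numerical edge cases: zero pooled variance with equal means returns t = 0,
p = 1; with unequal means the t is infinite and a warning is raised rather
than an exception, since a degenerate variable should not abort a
multi-variable report. Variance-based tests require n ≥ 2 per group; a
constant indicator (one empty group) is an error. A zero margin in a
contingency table (expected count 0) is an error.

## Synthetic cohorts

The generator emulates the structure the analyses assume, not behavioral
realism (no circadian timing, no device effects):

* **Tunnel**: 3 core sessions unlock weekly in order (session 1 split into
  two parts plus a final page, so "completed session 1" is observable);
  weeks 4–12 offer one of 9 optional sessions with probability `p_opt`;
  every login from week 2 opens with a goal-and-weight review.
* **Attrition**: constant weekly continuation probability `q` (default
  0.9), with an `early_drop` multiplier (default 0.8) on the week-1→2
  transition to emulate the rapid early drop these trials report, after
  which retention decays geometrically: with `early_drop = 1`, the
  fraction reaching core session *k* converges to `q^(k−1)`.
* **Dwell times**: log-normal per page, `μ_log = 3.4`, `σ_log = 0.8`
  (median ≈ 30 s) — a plausible invented scale, documented as such.
* **Tool reuse**: each tools group (food diary, steps diary,
  getting-support tools) is exposed during its core session; reuse
  occasions are Poisson with per-group rates (0.86, 0.21, 1.05), chosen so
  expected reuse fractions match the magnitudes reported for this class of
  intervention (food diary ≈ 55–58% of users, steps diary ≈ 13%, support
  tools ≈ 65% of those exposed). Reuse logins are separate occasions three
  days after the weekly session, so the >60-minute occasion rule recovers
  the latent reuse flags exactly — verified in tests.
* **Outcome**: `weight_change = β0 + β1·reused(steps diary) + N(0, σ_w)`
  with defaults β0 = 2.63 kg, β1 = 3.15 kg, σ_w = 5.73 kg (the pooled SD of
  the two published groups; the model has a single noise SD). Ground truth
  (latent flags, realized attrition, true coefficients) is serialized next
  to the four files so tests never re-infer it.

Everything is driven by one `numpy` generator seeded from `SimConfig.seed`;
identical configs produce byte-identical files.

What passing tests on this generator do **not** show: real logs have
heavy-tailed and truncated dwell times, within-user correlation of session
lengths, revisits inside a session that the tunnel forbids, and informative
missingness in outcomes. Conclusions about those features require real
data.

## Problem sizes and calibration checks

The calibration suite uses sizes chosen to keep Monte-Carlo error well
inside the tolerances: session-3 retention at n = 2000 (binomial SE
≈ 0.009 against a ±0.02 band, with a law-of-large-numbers variant at
n = 10⁴ in the unit suite), type-I error of the moderator test over 1000
replicates at the published group sizes (119 vs 17, SE ≈ 0.007), and power
under the injected 3.15 kg effect over 400 replicates compared against the
noncentral-t analytic power (≈ 0.56 at those sizes — a reminder that the
published steps-diary comparison is underpowered; its observed significance
is the expected outcome only slightly more often than not). Replicates
simulate the outcome model at the user-table level; the flow layer is
exercised by its own tests.

## Known limitations

* Dwell durations are taken as logged; no imputation for truncated final
  page views.
* The occasion rule is a threshold heuristic; platforms with explicit
  session/login ids should prefer those (not currently an input column).
* Clustering equivalence with any specific historical tool's clusters
  cannot be asserted (see above).
* Welch group sizes cannot be recovered from a published fractional df
  alone; tests from summaries require the n's.
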