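# Methods

## The model

A job exposure matrix (JEM) for second-hand smoke assigns each 4-digit
occupation code three ordinal ratings — likelihood *L* ∈ {0, 1} (1 means
at least 10% of jobholders are exposed at work), frequency *F* ∈ {0..4}
and intensity *I* ∈ {0..3} — under a conditional scheme: *F* and *I* are
rated only when *L* = 1, and a rater who assigns *L* = 0 records nothing
else for that code. Missing ratings are therefore a first-class state,
kept distinct from the substantive level 0 ("never"/"none"); conflating
them would corrupt both agreement statistics and consensus. Occupation
codes are identifiers, stored as strings (leading zeros and dialect
variants survive round-trips), and the 2-digit parent group is always the
code's first two characters.

The compound severity of a code is the product *S = L·F·I*. Exhaustive
enumeration of the 13 legal triples shows the attainable set is
{0, 1, 2, 3, 4, 6, 8, 9, 12}; the maximum, 12, corresponds to daily,
long-duration exposure indoors in a poorly ventilated space. *S* is
monotone in each argument and collapses to 0 whenever *L* = 0.

## Inter-rater agreement

Agreement between raters is measured with Fleiss' κ in its standard
formulation: with *n* raters per item and *n₍ᵢⱼ₎* raters assigning
category *j* to item *i*,

    Pᵢ = (Σⱼ n₍ᵢⱼ₎² − n) / (n(n−1)),  P̄ = meanᵢ Pᵢ,  P̄ₑ = Σⱼ pⱼ²,
    κ = (P̄ − P̄ₑ) / (1 − P̄ₑ).

κ is computed on the likelihood axis only: under the conditional scheme,
frequency and intensity are undefined whenever a rater sees no exposure,
so pooling them would artificially depress apparent agreement. Panels for
the conditional axes are available behind an explicit opt-in and are
restricted to items every rater rated. Items with missing ratings are
excluded with a logged count rather than imputed (the Fleiss formulation
assumes equal rater counts; silent imputation would bias κ); a strict mode
turns unequal counts into an error listing the items. If every assignment
falls in a single category, P̄ₑ = 1: observed agreement is then
necessarily perfect too and κ is defined as 1; the degenerate-margin error
branch is kept for defensive completeness but is unreachable from real
panels. No variance or CI is attached to κ by default; a seed-controlled
percentile bootstrap over items is offered as an extra.

Disagreement is localised by mapping the items with ≥2 distinct
likelihood assignments onto their 2-digit groups, reporting
n_disagreeing/n_total per group; numerators always sum to the total
number of disagreeing codes.

## Consensus adjudication

Conflicting round-two ratings are resolved per axis, likelihood first:
unanimity keeps the value; with three raters and two agreeing, the
repeated value wins; when only two raters rated the axis the higher
(worse) ordinal value is taken — on the binary likelihood axis the max is
the logical OR, applied uniformly for simplicity and worst-case
consistency. Frequency and intensity are resolved only when the consensus
likelihood is 1, over the subset of raters who rated them; if no rater
did, that code is an error (a level cannot be fabricated). The three-way
distinct case has no documented rule — a human consensus process
guarantees a majority or a two-rater case — so the package must choose:
the default takes the median, which respects the ordinal scale and
assumes least, logs a warning and flags the record's provenance as
`tiebreak` so the deviation stays auditable; a strict policy raises
instead. Every consensus record carries a per-axis provenance
(`unanimous`, `majority`, `higher_of_two`, `tiebreak`); axes forced to 0
by a likelihood-0 consensus are marked `unanimous`, since all (zero)
contributing ratings trivially agree.

## Workforce estimation

Jobholder counts per 4-digit code arrive keyed to some classification
version and may need recoding (e.g. SOC2010 → SOC2020). One-to-many
splits are never resolved silently: the crosswalk must carry explicit
weights summing to 1 per source (to 1e-9), and a file without a weight
column is completed as an equal split with a loud warning. Target counts
are the weight-mixed sums rounded half-to-even to whole workers; the
drift of the rounded total against the exact total is logged and is
bounded by half a worker per target code. Rounded official extracts carry
counts in multiples of 100, which is validated when asserted.

The cross-tabulation places each code's jobholders in the cell of its
consensus (frequency, intensity); likelihood-0 codes occupy the (0, 0)
cell. Cells that the conditional scheme makes impossible (frequency 0
with nonzero intensity and vice versa) do not exist in the object. The
JEM and workforce must share a code universe exactly — codes present on
one side only are an error listing them — which makes the conservation
property (grand total = workforce total) exact. From the table follow the
headline estimates: workers in likely-exposed jobs (everything outside
(0, 0)), their share of all jobs, and the floor on exposed workers,
`min_prevalence × n_in_exposed_jobs`, linear and increasing in the
threshold (default 0.10, matching the likelihood rating's definition).
The share of daily-indoor-exposed workers among "indoor" jobs depends on
which intensity levels count as indoors (3 only, or 2–3); both
denominators are computable and neither is asserted.

## Synthetic data

The simulator emulates the study conditions: 412 codes in 26 two-digit
groups, three raters, a 20.4% prevalence of likely codes. Likely codes
draw (F, I) from categorical laws whose defaults — frequency
(0.12, 0.30, 0.54, 0.04) over levels 1–4, intensity (0.36, 0.20, 0.44)
over 1–3 — echo the published JEM's distribution of likely codes over the
cross-tabulation cells. Rater noise is a per-axis error probability ε: the
binary likelihood flips symmetrically; the conditional axes move one step
on the ordinal scale (reflecting at the ends), because expert disagreement
on ordinal exposure scales is overwhelmingly between neighbouring levels;
a uniform relabelling kernel is available for worst-case tests. A rater
who erroneously reports likelihood 1 for a truly unexposed code must still
commit to legal nonzero (F, I), drawn from the same laws. Workforce counts
are lognormal (μ = 11.1, σ = 1.0 by default, giving a mean code size near
110 000 jobholders and a ≈46 M national workforce) rounded to the nearest
100; the crosswalk mixes identity, merge (2→1) and split (1→2, weighted)
mappings in configurable proportions (default 0.8/0.1/0.1). Identical
config and seed give byte-identical outputs; per-stage RNG streams are
derived from the seed so stages can be regenerated independently.

What the simulator does **not** emulate: real SOC code semantics and
titles, correlation of exposure profiles within 2-digit groups, rater
biases that are systematic rather than independent, the round-1 →
discussion → round-2 human dynamic, and workforce counts correlated with
exposure. Passing recovery tests therefore demonstrates the mechanical
correctness of the pipeline under controlled noise, not the validity of
any expert panel's judgements on real occupations.

Because the deposited per-code UK 2020 JEM table is journal supplementary
material and is not redistributed here, the package also provides a
deterministic **synthetic stand-in** (`synthetic_uk_jem`, labelled as such)
constructed to satisfy every summary margin reported for that table: 412
codes, 84 (20.4%) likely, mean severity exactly 1.0 with range 0–12,
exactly three codes (6116, 6135, 6137) at severity 12, the reported
2-digit-group likely-fractions (5/5, 11/12, 16/26, 4/8, 7/16, 0/20,
0/28), and per-cell code counts consistent with the published jobholder
cross-tabulation, so that pairing it with `synthetic_uk_workforce`
reproduces that table cell for cell. Ratings beyond these constraints are
arbitrary; the stand-in exercises the real parsing, summarising and
tabulation code paths against known headline figures, and is not the
published table.

## Numerical and design choices

* Group mean severity is an unweighted mean over codes; the
  workforce-weighted variant lives in a separate, explicitly requested
  column to keep the two readings distinct.
* Severity rankings break ties by code ascending, making orderings fully
  deterministic.
* The NS-SEC (socio-economic class) mapping is always an input file —
  official derivations are versioned externally and are not inferred.
* Percentages in reports are displayed to 1 decimal place but always
  carried at full precision, with numerator and denominator alongside.
* Agreement, consensus and tabulation are exact integer/rational-style
  computations except for κ itself (double precision; the test suite
  checks it against an independent pairwise-enumeration oracle to 1e-12)
  and crosswalk rounding (half-to-even, drift reported).
* Test problem sizes: oracle cross-checks use 1000 random panels of ≤12
  items × ≤4 raters; noise–degradation curves use 200 replicates of
  30-code panels per error rate; recovery tests use the full 412-code
  universe with 3 raters at ε ∈ {0, 0.1}.

## Limitations

The consensus stage models only the mechanical post-discussion rules, not
the discussion itself; κ on conditional axes is conditional on the
complete-item subset; the stand-in JEM constrains only published margins,
so per-code values in it carry no evidential weight; and reproduction of
the original panel's κ values (0.42/0.66) or per-rater disagreement
counts is impossible without the unpublished per-rater data — those
quantities are covered instead by oracle-equivalence, recovery and
conservation properties on synthetic panels.
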