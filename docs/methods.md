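# Methods

## Disproportionality model

Signal detection treats the deduplicated spontaneous-report corpus as a
2×2 cross-classification per drug-event pair: a (drug & event), b (drug,
other events), c (event, other drugs), d (neither).  The unit of counting
is the report, not the drug-event mention, so a + b + c + d equals the
corpus size on every row; a report counts toward a drug when it lists that
drug with a suspect role (PS or SS — concomitant and interacting mentions
are excluded by default and can be included via the `roles` argument).

Point estimates are PRR = [a/(a+b)]/[c/(c+d)] and ROR = ad/bc.  Intervals
are log-scale Wald:

    ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)
    ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))

with z the exact two-sided 95% normal quantile (1.959963985…, i.e. what
`norm.ppf(0.975)` returns).  The exact quantile rather than the textbook
1.96 matters only in the fourth decimal of a CI bound, but reconstruction
of printed tables (below) operates at exactly that precision, and the exact
quantile is what standard statistical software uses.

χ² is Pearson's statistic, N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]; the Yates
continuity correction (subtract N/2 from |ad−bc|, clamped at zero) is
available behind a flag and is off by default for forward screening.  When
any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe) before
ratios and intervals are computed — only then, so fully populated tables
are bit-identical to the uncorrected formulas — and the row is marked
`corrected`.  Statistics that remain undefined (zero margins without
correction) raise a typed error naming the offending cell; they are never
silently returned as zero.

Screening applies both published rules with strict inequalities: the PRR
rule PRR > 2 ∧ χ² > 4 ∧ N > 2, and the ROR rule (lower 95% ROR bound) > 1
∧ N > 2, where N is cell a.  No multiplicity adjustment is applied across
pairs (none is standard in this screening setting).

## Inverse reconstruction of printed tables

Published signal tables print a, one or both ratios with CIs, and χ², but
not b, c, d.  `reconstruct_table` recovers integer cells whose forward
statistics reproduce the printed values to half a unit in their last
printed decimal ("half-ULP").  The search exploits the precision imbalance
among the inputs: a χ² printed to 2–3 decimals on a value in the thousands
carries ~1e-7 relative precision, while a ratio printed to two decimals
carries ~5e-5.  Scanning the small cell over the feasible range implied by
the CI width (the squared log-SE minus 1/a bounds 1/b + 1/c + 1/d), the
remaining cells follow per candidate from the point estimate and the χ²
root (Brent), leaving a handful of integer candidates to verify against
every printed rounding.  The result reports residuals in half-ULP units
and the number of admissible tables.

Two caveats are inherent to the inputs, not the search.  First, a ROR with
its CI and χ² are all exactly invariant under swapping b and c, so a
ROR-based row admits two solution branches and any statistic not supplied
(such as the PRR) differs between them.  Second, rounding leaves a thin
tube of integer solutions even within one branch.  `reconstruct_corpus`
resolves both by using table coherence across drugs screened on the same
corpus: with shared totals T (all reports) and H (all event reports), the
cells of every drug collapse to b_i = n_i − a_i, c_i = H − a_i,
d_i = T − n_i − c_i, leaving 2 + (number of drugs) integer unknowns against
four printed statistics per drug.  A continuous least-squares fit (each
residual scaled by its half-ULP; per-drug multi-start solves choose the
branch combination with the most coherent implied totals) is polished over
the integer lattice by exhaustive minimax search (totals within a few
units, T within a few thousand, vectorised).  On the published LMWH-HIT
table this pins every supplied statistic within one half-ULP and returns
the held-out ratios at printed precision.  The published rows are not
perfectly mutually consistent — no integer corpus reproduces all 21
printed statistics simultaneously at half-ULP, a printing-precision issue
the minimax criterion absorbs.

Reconstruction of the published table requires the Yates-corrected χ²:
with the uncorrected statistic no integer table matches any drug's printed
point + CI + χ² at printed precision, while with the correction all three
drugs admit solutions.  The reconstruction entry points therefore default
to `yates=True`; forward screening keeps the uncorrected default, and at
screening magnitudes the choice never flips a flag.

## FAERS-style ingestion

The reader consumes one quarter's demographics/drug/reaction tables in a
configurable delimited dialect (default "$"-separated with FAERS-like
column names; the outcome code is folded into the demographics table as a
single precedence-resolved code — death dominates, then the
hospitalization/life-threatening/disability group).  Orphan child rows and
reports lacking drugs or reactions are counted and logged, never silently
dropped; a missing mandatory column is a hard error naming the column.
Deduplication keeps, per case id, the highest version, breaking ties by
latest receipt date and then stable input order, and is idempotent.

Drug names are matched against a shipped synonym dictionary for the seven
LMWH generics (brand names and salt forms, e.g. LOVENOX → enoxaparin),
case-, whitespace- and punctuation-insensitively, with a trailing
sodium/calcium token tolerated.  Event matching is exact string equality
(after case-folding and whitespace collapse) against the three HIT
Preferred Terms — a closed keyword list, so substring matching would
over-count (plain "thrombocytopenia" must not match).

The baseline table stratifies a drug's event reports by age band (<18,
18–60 inclusive of both boundaries, >60, unknown), sex, outcome group
(death / hospitalization-life-threatening-disability / others) and
reporter country (US vs other); each block partitions the reports, and
percentages are rounded half-up to two decimals as clinical tables print
them.

## Warkentin 4Ts score

Each of the four criteria contributes 0–2 points: thrombocytopenia
(platelet fall and nadir), timing (days from exposure), thrombosis, and
other causes; totals 0–3/4–5/6–8 map to low/intermediate/high pretest
probability.  The published thrombocytopenia rows overlap — a >50% fall
can coexist with a nadir <10×10⁹/L, matching both the 2-point and 0-point
wording — so the implementation lets the 0-point features dominate: score
0 when fall <30% or nadir <10, 2 only when fall >50% and nadir ≥20, else
1.  This is the only total reading under which worsening either feature
alone never lowers the sub-score, which the property suite enforces.
Timing scores 2 for onset days 5–10 or ≤1 day with re-exposure within 30
days, 1 for onset >10 days, unclear timing, or ≤1 day with exposure 30–100
days prior, else 0.  A criterion left unobserved yields an explicit
missing result; sub-scores are never imputed.

## Case-series fixture

The 43-case series ships as a CSV (one row per case) rebuilt
deterministically by `build_case_fixture(seed)`.  It is a synthetic
reconstruction: every drug-stratified marginal of the published
descriptive tables is satisfied exactly (drug totals 21/14/4/2/2; onset,
platelet nadir and fall bands, anti-PF4 positivity, 4Ts bands and
recovery-time bands per drug; demographics, indications, history,
co-medication, symptoms, treatments, alternative anticoagulants and
outcomes in aggregate), but the joint structure across variables is filled
by seeded permutation and carries no information — correlations the
publication does not constrain are arbitrary.  Within each drug block the
banded attributes are dealt by shuffled assignment; multi-valued
attributes (history, symptoms, co-medication, alternative anticoagulants,
treatment extras) are dealt round-robin over a shuffled holder order,
which guarantees no item repeats on one case as long as its count does not
exceed the number of holders (true for every published count).

Values the publication reports only in bands (onset, platelet counts,
recovery time) are stored as bands; operations needing raw values degrade
explicitly — the series summary reports the modal onset band with a
`binned_only` marker instead of fabricating a median.  Two layout quirks
of the published tables are mirrored rather than corrected: the
co-medication block divides by 42 (not 43), and the indication counts sum
to 44 over 43 patients, so indications are modelled set-valued with
exactly one case carrying two.  Percentages are rounded half-up to two
decimals everywhere.

## Synthetic corpus generator

`generate_reports` draws one drug per report from configured exposure
probabilities (remaining mass spread over named comparator drugs), then
assigns the HIT event with probability p₀ off the target drug and
p₁ = σ(logit p₀ + ln OR) on it, so the injected OR is the exact
conditional odds ratio.  Defaults model the operating regime of the
screening rules: 20,000 reports, 5% target-drug share, 0.5% background
event probability, OR 10, 5% duplicate re-submissions (incremented case
version, later receipt date), and FAERS-like missingness (13% age, 9% sex,
5% outcome, 3% country).  Demographics roughly follow the published
baseline (age mass above 60, balanced sex, ~24% death outcome); drug names
are emitted through randomly chosen dictionary synonyms and case styles so
normalisation is exercised end to end.  Ground truth (realized tables on
the base corpus, duplicate case ids, injected parameters) is returned
alongside and written as a JSON sidecar by the CLI.

`simulate_tables` is the count-level equivalent for repeated-corpus
experiments: because a corpus reduces to (exposed?, event?) per report for
the target drug's table, the four cells are jointly binomial and can be
drawn directly; the report-level and count-level paths are
distributionally identical, and the object path is cross-checked against
its own ground truth in the tests.  All randomness flows through a single
PCG64 generator per seed; fixed seeds reproduce corpora and the fixture
byte-for-byte.

What the generator does not emulate: real FAERS free-text noise beyond the
synonym list, multi-drug polypharmacy reports (one drug per report by
default; concomitant role-C mentions behind a flag), reporting trends over
time, and duplicate submissions that alter content between versions.
Passing tests therefore demonstrate correctness of the counting and
inference machinery under known truth, not robustness to real-world coding
noise.

## Problem sizes and numerical choices

The test suite screens corpora of 4,000–50,000 reports and calibrates the
rules over 500 corpora of 20,000 reports per arm (null OR 1 and injected
OR 10) via the count-level path; the null false-flag rate stays below the
nominal one-sided 2.5% plus discreteness slack, ROR CI coverage of the
true OR sits in the 93–97% band, and both rules fire in >95% of injected
runs.  Formula agreement with brute-force oracles (expected-count χ²
summation, direct log-SE evaluation) is asserted at 1e-9 relative
tolerance on 1,000 random tables.  Reconstruction tolerances are expressed
in half-ULP units of each printed value; the corpus polish scans totals
±3 and T ±5,000 around the continuous optimum, which covers the rounding
tube with a wide margin at the published magnitudes.

## Known limitations

Deduplication is exact-key (case id/version); no probabilistic record
linkage.  Only the three HIT Preferred Terms are matched — no MedDRA
hierarchy navigation.  Bayesian disproportionality (IC, EBGM) is out of
scope.  The case-series fixture supports descriptive reproduction, not
inference about cross-variable association, which its construction does
not preserve.  Reconstruction assumes the printed statistics were computed
with the standard formulas above; a publication using different CI or χ²
conventions would surface as irreducible residuals, which the result
objects expose rather than hide.
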