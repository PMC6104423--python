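# Methods

## The analysis model

The package implements frequentist disproportionality analysis on a
spontaneous-report database. The unit of analysis is the distinct case
report; for a drug *j* and MedDRA preferred term (PT) *i* the margins
are N (all cases in the window), N<sub>j</sub> (cases carrying the drug
under an included suspect role), N<sub>i</sub> (cases with the event,
any drug) and N<sub>ij</sub> (both). From the derived 2×2 cells it
computes the ROR with the Woolf log-scale interval, the PRR with its
delta-method interval, the Yates-corrected chi-squared statistic, and a
shrinkage Information Component

IC = log₂((N<sub>ij</sub>+0.5)/(E+0.5)),  E = N<sub>i</sub>N<sub>j</sub>/N,
SD(IC) = 1/(ln2·√(N<sub>ij</sub>+0.5)),

with an unshrunk log₂(observed/expected) variant behind a flag. The IC
is a pragmatic moment-style approximation to the Bayesian confidence
propagation form: the +0.5 shrinkage keeps zero-count pairs finite and
pulls sparse pairs toward the null, and the delta-method SD is accurate
once N<sub>ij</sub> is more than a handful. A pair is signalled when all
three legs hold: PRR ≥ 2 with chi-squared ≥ 4 and N<sub>ij</sub> ≥ 3;
IC − 2SD > 0; ROR interval lower bound > 1 (strict inequalities on the
interval rules).

Assumptions worth stating: reports are treated as exchangeable across
quarters (no reporting-trend correction — the Weber effect and notoriety
bias are out of scope and should be kept in mind when reading real-data
output); no multiple-comparison control is applied across PTs, matching
standard practice for hypothesis-generating screens; and the comparator
is the whole database rather than a restricted drug class.

## Semantics and conventions

- **Counting unit**: distinct deduplicated cases, never rows or
  drug–event pair mentions. A PT repeated in one case counts once; a
  drug on two rows of one case selects it once. N is the number of
  deduplicated cases across the analysed quarters (report-level, not
  pair-level, counting; pair-level N is deliberately not offered).
- **Suspect-role filter**: a case counts as exposed only if a drug row
  matches the query name *and* carries an included role code on the same
  row; the default included set is {PS, SS}. Name matching is
  case-insensitive substring by default (salt and brand decorations),
  with an exact mode.
- **Deduplication**: per case id, the highest version number wins (ties
  broken by the larger report key); the kept version defines the case's
  drugs and events. A no-dedup mode treats every version as its own
  unit. The count of collapsed versions is reported so the case funnel
  is conserved: parsed versions = cases + collapsed.
- **PT normalisation**: trim, collapse internal whitespace, casefold for
  the comparison key; a display form preserves case.
- **Continuity correction**: +0.5 on all four cells only when some cell
  is zero, flagged in the output; nonzero tables are never perturbed.
  With the correction disabled, zero-cell statistics are reported as
  undefined (NaN plus a reason) and fail their criterion — never
  silently zero.
- **Output order**: signal tables rank by N<sub>ij</sub> descending with
  alphabetical PT tie-breaks; frequency tables are alphabetical. Floats
  are written at 6 significant digits. Nothing in any output depends on
  wall-clock time, so identical inputs give byte-identical files.

## File dialects

The quarterly extracts changed layout at 2012Q4: before, rows are keyed
by ISR with a separate CASE column (`ISR$CASE$FOLL_SEQ$...`); after, by
primaryid with caseid and caseversion. Both dialects are described by a
column-mapping table (data, not code) and auto-detected from the DEMO
header. In the legacy layout the drug and reaction files carry no case
id, so it is resolved through the demo file's ISR→CASE map (falling back
to the ISR itself for unlisted keys). Files are read as UTF-8 with a
latin-1 fallback; replacement characters, malformed rows (embedded `$`
in a value, missing mandatory fields, empty PTs), unknown role codes and
orphaned reaction keys are all counted in a rejects report with the
first few offending lines — rejected rows are never silently dropped,
and orphaned reactions are retained.

## The synthetic generator

The generator emulates the structure of a quarterly report stream, not
its clinical content. Per case: each vocabulary drug is present as an
independent Bernoulli draw with its marginal probability; each
vocabulary event likewise, except that for a planted (drug, event,
rate_ratio) triple the event probability is multiplied by rate_ratio
when the drug is present (capped at 1). Each drug row draws a role code
from a configurable (PS, SS, C) distribution, default (0.6, 0.3, 0.1).
A configured fraction of cases is emitted twice as versions 1 and 2 of
one case id, identical except for a perturbed age, so deduplication is
observable. Demographics (age 15–60, sex ~90% female as fits a
contraceptive exposure) exist only to exercise parsing. One planted drug
per event is allowed, keeping every expectation in closed form.

Cases that draw no vocabulary drug receive a filler `OTHER-SUSPECT` row,
and cases with no event a filler `Unevaluable event` row, so every case
appears in all three files without disturbing the vocabulary marginals
the closed forms rely on. The filler PT behaves like any other
background term downstream (it can top the frequency ranking in sparse
event vocabularies, as in the README example) and is never signalled, as
its association with any drug is null by construction.

Because role filtering excludes some genuinely exposed cases (a case
carrying the drug as concomitant keeps its elevated event probability
but lands in the comparator column), the quantity the ROR estimates is
not the planted rate ratio but the odds ratio of the role-filtered
table; `true_odds_ratio` gives its exact value and `expected_counts` the
exact filtered margins. For a rare event and the default role mix the
two differ by well under 1%. `simulate_pair_tables` draws 2×2 tables
from the same generative law directly at count level (nested binomials),
which is what makes 500-replicate calibration runs at 50,000 cases each
take seconds.

What the generator does **not** emulate: drug co-prescription structure,
reporter demographics effects, reporting trends over time, verbatim-name
noise, or MedDRA hierarchy. Passing tests therefore demonstrate the
correctness of the machinery — parsing, dedup, counting, statistics,
classification — under a known model, not robustness to the messiness of
real FAERS data.

## Published-value fixtures

A 2018 screen of levonorgestrel, the emergency oral contraceptive,
printed point values of (IC, ROR, PRR) for 15 clinically chosen PTs and
CI lower bounds for the ten it reported as signals. Those printed
numbers are packaged as inputs (`pvsignal.fixtures`) and exercised with
point-value null rules (IC>0, ROR>1, PRR>1) and, where printed, the CI
rules. Two caveats are handled explicitly: the printed IC column is not
on any standard log₂ observed/expected scale (values reach 129.22, which
no 2×2 margin consistent with the printed ROR can produce), so it is
carried verbatim for threshold comparisons and never re-derived; and the
negative printed ROR/PRR values for the non-signal terms are likewise
treated as opaque published numbers that simply fail the positivity
rules. The underlying raw counts are not public, so point-value
classification — not numerical reproduction of the ROR/PRR from counts —
is what these fixtures check.

## Numerical and design choices

- Interval z-value is the exact 97.5% normal quantile (1.959963...),
  not 1.96 rounded — differences are far below reporting precision.
- Chi-squared uses Yates by default because the PRR/chi-squared/n≥3
  criterion historically does; the Pearson form is a flag away. The
  implementation's cross-product form is tested to 1e-9 against an
  expected-cell recomputation and against an independent library
  implementation.
- The clinically-relevant-PT selection step is a human judgment and
  enters only as an optional whitelist; whitelisted terms absent from
  the data yield all-zero tables rather than errors.
- Quarter labels are `YYYYQn`; a label's era decides its file dialect.
  Each quarter draws from an independent stream seeded by (config seed,
  quarter index), so any quarter can be regenerated alone and the whole
  dataset is reproducible from one seed.
- Problem sizes in the test and acceptance runs (10⁴-case end-to-end
  datasets, 500 replicates of 50,000 cases for calibration) were chosen
  as the smallest at which the binomial noise bands quoted in the tests
  are comfortably informative.

## Known limitations

- The legacy-dialect handling is a reasonable reconstruction of the
  2012 format transition, not a claim about how any particular published
  analysis handled it.
- Drug-name matching is string-based; there is no ingredient mapping
  (RxNorm etc.), so combination products are caught only by substring.
- No probabilistic record linkage: deduplication trusts the case-id
  field.
- The IC interval uses a delta-method SD, not the full Bayesian
  posterior; for N<sub>ij</sub> < ~5 the 2·SD bound is conservative.
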