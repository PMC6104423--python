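# pvsignal

Disproportionality-based signal detection for spontaneous adverse-event
report databases, in the style of the FDA Adverse Event Reporting System
(FAERS) quarterly extracts — with a synthetic report-stream generator so
the whole pipeline can be validated against known ground truth.

## Who this is for

Pharmacovigilance analysts and methods researchers who want a
transparent, testable implementation of the classic frequentist
signal-detection workflow: from raw quarterly `DEMO`/`DRUG`/`REAC`
`"$"`-delimited files, through suspect-role filtering and case
deduplication, to a per-event signal table with the Reporting Odds Ratio
(ROR), Proportional Reporting Ratio (PRR), chi-squared statistic and
Information Component (IC), and a three-way signal classification.

A *signal* here is a drug–event pair reported disproportionately often
relative to its expectation under independence. It warrants clinical
review; it is not evidence of causation.

## The statistics

For a drug *j* and event *i*, counts over distinct deduplicated case
reports form the 2×2 table with cells a = N<sub>ij</sub> (drug and
event), b = N<sub>j</sub> − N<sub>ij</sub>, c = N<sub>i</sub> −
N<sub>ij</sub>, d = N − N<sub>i</sub> − N<sub>j</sub> + N<sub>ij</sub>:

- **ROR** = ad / bc, with SE(ln ROR) = √(1/a + 1/b + 1/c + 1/d) and a
  95% CI of exp(ln ROR ± 1.96·SE);
- **PRR** = [a/(a+b)] / [c/(c+d)], with SE(ln PRR) = √(1/a − 1/(a+b) +
  1/c − 1/(c+d)) and the analogous CI;
- **chi-squared**, Yates-corrected by default:
  n·(|ad−bc| − n/2)² / ((a+b)(c+d)(a+c)(b+d));
- **IC** = log₂((N<sub>ij</sub> + 0.5)/(E + 0.5)) with
  E = N<sub>i</sub>N<sub>j</sub>/N and SD = 1/(ln2·√(N<sub>ij</sub> + 0.5))
  (an unshrunk variant is available by flag).

A pair is **overall positive** when all three criteria hold:
PRR ≥ 2 with chi-squared ≥ 4 and N<sub>ij</sub> ≥ 3; IC − 2·SD > 0; and
ROR − 1.96·SE > 1 (i.e. the CI lower bound exceeds 1, strictly).

When any cell is zero, 0.5 is added to all four cells (flagged in the
output); nonzero tables are never corrected.

## Worked example

`examples/run_full_analysis.py` generates four synthetic quarters
(10,000 cases, 10% duplicated as second case versions, one association
planted at rate ratio 6 between LEVONORGESTREL and "Menstruation
delayed") and runs the full analysis:

```
analysis run report
quarters analysed: 4 (2012Q2..2013Q1)
parsed case versions: 11000
deduplicated cases: 10000
collapsed duplicate versions: 1000
query-matched cases: 888
preferred terms analysed: 6
...
                  pt  n_ij  n_j     n   ror  ror_low   prr    chi2     ic  ic_low  overall
   unevaluable event   420  888 10000 0.809    0.704 0.899   8.909 -0.140  -0.281    False
            headache   159  888 10000 0.824    0.689 0.856   4.329 -0.206  -0.434    False
              nausea   144  888 10000 1.084    0.899 1.071   0.638  0.089  -0.151    False
menstruation delayed   122  888 10000 7.771    6.109 6.841 372.578  2.151   1.890    True
                rash    88  888 10000 0.918    0.729 0.926   0.452 -0.101  -0.407    False
           dizziness    84  888 10000 0.965    0.763 0.968   0.056 -0.042  -0.356    False
```

The funnel shows 11,000 parsed case versions collapsing to 10,000
distinct cases, of which 888 carry the query drug as a primary or
secondary suspect. Only the planted term passes all three signal rules
(ROR 7.77 with CI lower bound 6.11, PRR 6.84, chi-squared 373, IC − 2SD
= 1.89 > 0); background terms hover at the null. The other examples
cover the generator and its closed-form expectations
(`generate_synthetic_quarters.py`), classification of published point
values from a levonorgestrel screen (`classify_published_values.py`,
10 of 15 terms positive), and interval calibration
(`interval_calibration.py`, ~95% CI coverage at rate ratios 1, 2, 4).

A thin CLI wraps the same functions:

```
pvsignal synth    --config synth.yaml --out data/
pvsignal run      --config run.yaml
pvsignal fixtures
```

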