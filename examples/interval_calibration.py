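"""Frequentist calibration of the ROR interval on synthetic replicates.

Draws 500 count-level replicates (50,000 cases each) at rate ratios
1, 2 and 4, and reports how often the 95% ROR interval covers the
model's true odds ratio, plus the false-signal rate at the null.
"""

import numpy as np

from pvsignal import ContingencyTable, classify, compute_metrics, compute_ror
from pvsignal.synth import simulate_pair_tables, true_odds_ratio

N, P_DRUG, P_EVENT, P_ROLE, REPS = 50_000, 0.1, 0.01, 0.9, 500

for rate_ratio in (1.0, 2.0, 4.0):
    rng = np.random.default_rng([2026, int(rate_ratio)])
    tables = simulate_pair_tables(
        N, P_DRUG, P_EVENT, rate_ratio, rng, P_ROLE, size=REPS
    )
    truth = true_odds_ratio(P_DRUG, P_EVENT, rate_ratio, P_ROLE)
    covered = flagged = 0
    for a, b, c, d in tables:
        t = ContingencyTable.from_cells(int(a), int(b), int(c), int(d))
        est = compute_ror(t)
        covered += est.low <= truth <= est.high
        flagged += classify(compute_metrics(t)).overall
    print(
        f"rate ratio {rate_ratio:g}: true OR {truth:.3f}, "
        f"CI coverage {100 * covered / REPS:.1f}%, "
        f"overall-positive rate {100 * flagged / REPS:.1f}%"
    )
# Coverage near 95% at every rate ratio says the Woolf interval is
# honest under this generative model; a near-zero positive rate at
# rate ratio 1 says the three-way rule rarely cries wolf on null pairs.
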