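"""Re-derive the index weights from a cohort by the regression procedure.

The four weights of the aggression index are not arbitrary: they are the
normalized coefficients of an ordinary least-squares regression of the
aggression frequency (acts per second) on the three category durations and
the transformed first-attack latency. This script builds a synthetic
200-individual cohort whose frequency follows the default weight ratios,
adds 5% measurement noise, and shows that the procedure recovers the
weights.
"""

import numpy as np

from crabtai import TaiWeights, derive_weights
from crabtai.synthetic import SimParams, simulate_summary_cohort

rng = np.random.default_rng(0)
truth = TaiWeights()  # (0.14, 0.21, 0.35, 0.30)

summaries = simulate_summary_cohort(SimParams(n=200, rng_seed=0))
responses = [
    (truth.w_anxious * s.d_anxious
     + truth.w_demonstration * s.d_demonstration
     + truth.w_fighting * s.d_fighting
     + truth.w_latency * (s.t_total - s.t_first)) / s.t_total
    for s in summaries
]
sd = 0.05 * np.std(responses)
cohort = [(s, y + rng.normal(0.0, sd)) for s, y in zip(summaries, responses)]

recovered = derive_weights(cohort)
print(f"{'component':>15} {'true':>6} {'recovered':>10}")
for name, t, r in zip(
    ("anxious", "demonstration", "fighting", "latency"),
    truth.as_tuple(), recovered.as_tuple(),
):
    print(f"{name:>15} {t:6.2f} {r:10.4f}")
# With zero noise the recovery is exact; at 5% noise each weight lands
# within about +/-0.01 of the truth for a 200-individual cohort.
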