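"""Cross-group pairing trials: does the stratification predict contests?

Simulates attack counts for dyadic pairings drawn from the aggression
groups (H-H, M-M, L-L and mixed H-L) with the assay's trial numbers
(25/25/25/50), then tests for context differences with Kruskal-Wallis and
Dunn's Bonferroni-corrected post hoc comparisons.
"""

from crabtai import pairing_analysis
from crabtai.synthetic import SimParams, simulate_pairing_trials

params = SimParams(rng_seed=2)
counts = simulate_pairing_trials(
    {"H-H": 25, "M-M": 25, "L-L": 25, "H-L": 50}, params
)

report = pairing_analysis(counts)
for ctx in report.contexts:
    zeros = (counts[ctx] == 0).mean()
    print(f"{ctx}: n = {report.n_per_context[ctx]:2d}, "
          f"mean = {report.mean_per_context[ctx]:5.2f} "
          f"+/- {report.sd_per_context[ctx]:4.2f}, "
          f"{100 * zeros:.0f}% zero-attack trials")
print(f"Kruskal-Wallis H = {report.h_statistic:.2f}, df = {report.df}, "
      f"p = {report.pvalue:.2e}")
for pair, p in sorted(report.dunn_p_adjusted.items(), key=lambda kv: kv[1]):
    print(f"  Dunn {pair[0]} vs {pair[1]}: adjusted p = {p:.4f}")
# High-aggression pairings fight the most, low-aggression pairings often
# record no attacks at all, and mixed pairings sit near the medium level.
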