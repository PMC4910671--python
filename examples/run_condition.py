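"""A desk-scale Monte Carlo condition run.

Runs 50 replications of the (n=500, continuous) design cell and prints the
five outcome percentages that one row-cell of the full results table
aggregates.  The full study uses 1000 replications per cell
(``validity-sim table2`` or ``run_grid``).
"""

from validitysim import mc_harness as mh

cond = mh.ConditionSpec(n=500, categories="continuous")
summary = mh.run_condition(cond, reps=50, base_seed=2024)

print(f"condition: {cond.label}, {summary.n_converged}/"
      f"{summary.n_attempted} replications converged")
print(f"% accepted H0, Model 1:   {summary.pct_accept_m1:5.1f}")
print(f"% accepted H0, Model 2:   {summary.pct_accept_m2:5.1f}")
print(f"% delta-chi2 significant: {summary.pct_delta_sig:5.1f}")
print(f"% RMSEA < 0.08, Model 1:  {summary.pct_rmsea_m1:5.1f}")
print(f"% RMSEA < 0.08, Model 2:  {summary.pct_rmsea_m2:5.1f}")

print()
print("With continuous indicators and n=500 the correctly specified")
print("Model 2 is accepted ~95% of the time, Model 1 essentially never,")
print("and the difference test flags the threat in every replication.")
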