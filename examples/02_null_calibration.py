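"""Check the false-positive guarantee on trees with no response structure.

Simulates random trees whose leaf responses are i.i.d. coin flips, so any
detected segment is a false positive.  At alpha = 0.1 the method may report
a spurious clade in at most ~10% of runs; in practice it is far more
conservative (a no-association rate around 98-99%).
"""

import treeseg as ts

table = ts.simulate_M(grid_size=512, n_draws=2000, seed=0)
design = ts.SimulationDesign(n_leaves=200, k_true=0, probs=(0.5,),
                             n_reps=100, seed=1, alpha=0.1)
report = ts.run_study(design, quantile_table=table, progress=True)

agg = report.aggregates
print(f"runs:                {agg['n_reps']}")
print(f"no-association rate: {agg['no_association_rate']:.3f}")
print(f"false-positive rate: {agg['overestimation_rate']:.3f} "
      f"(guaranteed <= {design.alpha})")
print()
print("The no-association rate is the fraction of runs with k_hat = 0; the")
print("guarantee bounds its complement by alpha, and the multiscale")
print("calibration typically leaves it far below that bound.")
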