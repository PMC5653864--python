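"""Detect a planted burst of morphological evolution.

Simulates a clade whose change rate is multiplied by 2.5 in one late time
bin (an isolated rate spike — the full preset plants it in bin10), analyses
25 posterior-like trees with the ML ancestral-state / per-bin likelihood-
ratio pipeline, and prints the per-bin verdicts.  A HIGH call marks a bin
where >55% of trees found a significantly elevated pooled rate at
alpha = 0.01.  Detection is not guaranteed on every simulated dataset (the
planted contrast is attenuated by branch-level change counting); this seed
shows a successful recovery.
"""

import paleotempo as pt

scenario = pt.palaeozoic_scenario(seed=401)  # spike already planted in bin10
tree = pt.simulate_tree(scenario)
matrix, ledger = pt.simulate_characters(tree, scenario)
matrix = pt.inject_missing(matrix, scenario.p_miss, seed=1)
trees = pt.make_posterior_like(tree, n_trees=25, age_jitter_sd=2.0, seed=1)

result = pt.rates_over_trees(trees, matrix, scenario.timescale, extend_edges=True)
print(f"{tree.n_tips} taxa, {matrix.n_characters} characters, 25 trees\n")
print(result.summary[["bin", "mean_rate_per_char", "frac_high", "frac_low", "class"]]
      .to_string(index=False))

trend = pt.rate_trend(result.summary["mean_rate"].to_numpy(),
                      scenario.timescale.midpoints())
print(f"\nSpearman trend of mean rate vs time: rho = {trend['rho']:.2f}, "
      f"p = {trend['p']:.3f} (n = {trend['n']} bins)")
print("mean_rate_per_char is in changes/character/Myr; frac_high is the share "
      "of trees calling the bin significantly fast. The planted bin is bin10.")
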