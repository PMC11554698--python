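"""The two-stage identification + verification pipeline on a synthetic cohort.

Generates a reduced cohort (60 nodes) with hypo-assortativity planted at
three nodes for MCI/ADD subjects, ranks nodes by Welch p-value for the
SCI-vs-MCI task, and verifies the selected set with leave-one-out linear-SVM
accuracy against the full-connectome baseline.
"""

from assortnet import (
    SyntheticConfig,
    direction_summary,
    feature_matrix,
    generate_cohort,
    loo_accuracy,
    rank_nodes,
    selected_loo,
)

cfg = SyntheticConfig(seed=7, node_count=60, group_sizes=(20, 28, 14),
                      hypo_nodes=(3, 12, 21), hyper_nodes=(7, 16, 25),
                      base_density=0.2, modalities=("structural",))
cohort = generate_cohort(cfg)
na = feature_matrix(cohort, "NA", "structural")

rk = rank_nodes(na, "SCI-vs-MCI", k=3)
print(f"planted hypo nodes: {sorted(cfg.hypo_nodes)}")
print(f"top-3 selected:     {sorted(rk.selected.tolist())} "
      f"(p = {[f'{p:.2g}' for p in rk.p_values[rk.selected]]})")
print(f"direction of change at selected nodes (MCI - SCI): "
      f"{direction_summary(na, rk)}  (-1 = decrease, as planted)")

top = selected_loo(na, rk).accuracy
X, y, _ = na.task_rows("SCI-vs-MCI")
full = loo_accuracy(X, y).accuracy
print(f"\nLOO linear-SVM accuracy, top-3 nodal assortativity: {top:.3f}")
print(f"LOO linear-SVM accuracy, all {cfg.node_count} nodes:          {full:.3f}")
print("the low-dimensional selected representation matches or beats the full")
print("connectome: few well-chosen local measures carry the discriminative signal.")
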