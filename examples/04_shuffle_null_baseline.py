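"""Label-shuffle null: how accurate is the pipeline when there is nothing to find?

Permutes the group labels, re-runs node selection inside every LOO training
fold, and collects the accuracy distribution. The true-label accuracy must
clear this baseline — not 50% nominal chance — before the selected nodes can
be called discriminative.
"""

import numpy as np

from assortnet import (
    SyntheticConfig,
    feature_matrix,
    generate_cohort,
    rank_nodes,
    selected_loo,
    shuffle_null,
)

cfg = SyntheticConfig(seed=7, node_count=60, group_sizes=(20, 28, 14),
                      hypo_nodes=(3, 12, 21), hyper_nodes=(7, 16, 25),
                      base_density=0.2, modalities=("structural",))
cohort = generate_cohort(cfg)
na = feature_matrix(cohort, "NA", "structural")

rk = rank_nodes(na, "SCI-vs-MCI", k=3)
true_acc = selected_loo(na, rk).accuracy
null = shuffle_null(na, "SCI-vs-MCI", k=3, n_shuffles=50, seed=0)

print(f"true-label top-3 LOO accuracy:    {true_acc:.3f}")
print(f"shuffled-label baseline (n=50):   mean {null.mean_accuracy:.3f}, "
      f"sd {null.accuracies.std():.3f}")
print(f"quantile of true accuracy in the null: "
      f"{np.mean(null.accuracies < true_acc):.2f}")
print("a true-label accuracy far above the shuffled mean indicates the selected")
print("nodes carry group structure, not an artifact of reusing data for selection.")
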