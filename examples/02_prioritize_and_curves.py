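"""Rank a landscape with the additive benefit function and inspect the
performance curves.

The greedy ranking iteratively discards the cell whose removal loses the
least summed benefit sum_j w_j [R_j^z - (R_j - p_ij)^z] (z = 0.25).
Species and habitat groups each carry aggregate weight 1; built-up layers
carry a cumulative weight of -1 and are pushed to the lowest ranks.
"""

import numpy as np

from conplan import (
    RunConfig,
    assign_aggregate_weights,
    build_synthetic_stack,
    curve_auc,
    performance_curves,
    range_vs_auc,
    rank_abf,
)

cfg = RunConfig(seed=8)
_, stack = build_synthetic_stack(cfg)
stack = assign_aggregate_weights(stack, {"species": 1.0, "habitat": 1.0})

rank = rank_abf(stack)
curve = performance_curves(rank, stack)
auc = curve_auc(curve)

print(f"ranked {stack.n_valid} cells; mean feature AUC = {auc.mean_auc:.3f}")

builtup = stack.group_members("builtup")
mean_bu_rank = np.mean([rank.rank[stack.data[stack.index(n)] > 0.5].mean()
                        for n in builtup])
print(f"mean rank inside built-up cells: {mean_bu_rank:.3f} (pushed to the bottom)")

table = range_vs_auc(stack, auc, "species", stack.group_members("species"))
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"Spearman rho(range size, AUC) = {table.attrs['spearman_rho']:.3f}")
# Negative rho: range-restricted species are retained longest, because a
# large fraction of the landscape can be removed before their cells are
# touched — provided they co-occur with other features in rich hotspots.
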