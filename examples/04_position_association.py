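"""Position-association analysis with exact tree-Shapley attribution.

Plants a causal residue (one position where a trigger residue adds a
full ln-unit to the rate) and checks that the resampled depth-3 tree +
Shapley procedure finds it, then compares rates between residue groups
at that position with Kruskal-Wallis and Dunn tests.
"""

import numpy as np

from rubiscope import (
    AssociationConfig,
    CausalSite,
    SimConfig,
    fit_position_association,
    map_alignment_to_reference,
    one_hot_encode,
    residue_rate_comparison,
    simulate_dataset,
)

cfg = SimConfig(
    n_leaves=80, length=150, seed=3, sigma2=0.0, sigma_obs=0.1,
    frac_characterized=0.6,
    causal_sites=[CausalSite(position=60, delta=1.0)],
)
ds = simulate_dataset(cfg)
char = ds.aln.subset_ids(ds.characterized_ids)
y = np.array([ds.true_ln_rates[v] for v in char.ids])

ref_map = map_alignment_to_reference(char, char.ids[0])
assoc = fit_position_association(
    one_hot_encode(char), y,
    AssociationConfig(n_iterations=100, seed=1),
    reference_map=ref_map,
)
site = ds.truth["causal_sites"][0]
top = assoc.ranked().head(5)
print("top 5 positions by mean |Shapley| attribution (ln-rate units):")
print(top.to_string(index=False))
print(f"\nplanted site: column {site['position']} (residue {site['residue']}, "
      f"delta {site['delta']}); recovered at rank "
      f"{assoc.rank_of_column(site['position'])}")

rates = {v: float(np.exp(ds.true_ln_rates[v])) for v in char.ids}
cmp = residue_rate_comparison(char, site["position"], rates, min_group_size=3)
print(f"\nrates by residue at the planted column: "
      f"Kruskal-Wallis H = {cmp.h_statistic:.2f}, p = {cmp.p_value:.2e}")
print(cmp.pairwise.round(4).to_string(index=False))
print("\nSmall adjusted p-values mark residue pairs with clearly different rates.")
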