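"""Gene-network overlap profile between two gene lists.

Builds a planted-partition network of 2,000 genes in two communities,
samples a reference list and a query seed from the same community, and runs
the interaction-score ranking + greedy expansion + preranked GSEA profile.
"""

import numpy as np

from ranklap.network_enrichment import overlap_profile
from ranklap.synthetic import SimulationConfig, simulate_network

cfg = SimulationConfig(n_genes=2000, n_communities=2)
network, communities = simulate_network(cfg, seed=2)

community0 = sorted(g for g, c in communities.items() if c == 0)
rng = np.random.default_rng(2)
picks = rng.choice(community0, size=200, replace=False)
reference, query_seed = list(picks[:100]), list(picks[100:])

profile = overlap_profile(
    network, reference, query_seed,
    sizes=range(100, 1001, 100), n_perm=500, seed=2,
)
print(profile.df.to_string(index=False))
print(
    "\nEach row expands the query set by 100 genes through the network and\n"
    "tests whether the expanded set is enriched near the top of the\n"
    "interaction-score ranking against the reference genes.  A significant\n"
    "row (ES > 0, BH-adjusted p < 0.05) at size s that persists to 1000\n"
    "is the signature of a genuinely shared gene neighborhood."
)
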