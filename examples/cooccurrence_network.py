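"""Niche-stratified co-occurrence network and its attack robustness.

Builds the Spearman network (|ρ| > 0.6, BH-adjusted exact-permutation
p < 0.05 at n = 8 samples), extracts the generalist and specialist
induced subgraphs, reports topology, and runs the random-node attack
simulation tracking natural connectivity λ̄ = ln(mean eᵞ) of the
adjacency spectrum.
"""

import numpy as np

from phyconiche.network import (
    attack_robustness,
    induced_subgraph,
    spearman_edges,
    topology,
)
from phyconiche.niche import classify
from phyconiche.synthetic import generate_community

table = generate_community(seed=11, with_tree=False).otu_table
profiles = classify(table, "bacteria")
kept = profiles.index[profiles["niche_class"] != "filtered"]

graph = spearman_edges(
    table.relative_abundance().loc[kept],
    r_min=0.6, alpha=0.05, node_attrs=profiles[["niche_class"]],
)

for name, g in [
    ("whole", graph),
    ("generalist", induced_subgraph(graph, niche_class="generalist")),
    ("specialist", induced_subgraph(graph, niche_class="specialist")),
]:
    stats = topology(g)
    print(f"{name:>10}: {stats['nodes']} nodes, {stats['edges']} edges, "
          f"avg degree {stats['avg_degree']:.2f}, "
          f"modularity {stats['modularity']:.2f}, "
          f"positive edges {stats['positive_edge_fraction']:.0%}")

sub = induced_subgraph(graph, niche_class="generalist")
curve = attack_robustness(sub, proportions=np.arange(0, 0.81, 0.1),
                          n_reps=50, seed=0)
print(f"\ngeneralist subnetwork attack: slope = {curve.fit.slope:.2f}, "
      f"r² = {curve.fit.r_squared:.3f}")
print("A steeper (more negative) slope means connectivity collapses faster")
print("under random node loss — a less robust subnetwork.")
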