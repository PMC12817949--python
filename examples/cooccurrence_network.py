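"""Build a thresholded Spearman co-occurrence network and group subnetworks.

Restricts the table to its most abundant taxa, keeps edges with |r| > 0.75
and p < 0.001, extracts a per-group subnetwork, and prints topology metrics.
"""

from ecoassembly import (
    SimulationScenario,
    build_global_network,
    extract_subnetwork,
    simulate_scenario,
    topology_metrics,
)

scenario = SimulationScenario(
    "dispersal_limitation", n_taxa=120, n_samples=27, reads_per_sample=3000, seed=5,
)
table, meta, *_ = simulate_scenario(scenario)

global_net = build_global_network(table, k=400)
print(f"global network: {global_net.n_nodes} nodes, {global_net.n_edges} edges")
for group in meta.group_labels:
    sub = extract_subnetwork(global_net, table, meta, group)
    m = topology_metrics(sub)
    print(
        f"{group:6s} nodes={m.n_nodes:3d} edges={m.n_edges:3d} "
        f"density={m.edge_density:.3f} mean_degree={m.mean_degree:.2f} "
        f"negative={100 * m.proportion_negative:.1f}%"
    )
# Denser, more clustered subnetworks suggest tighter putative interactions
# within that group's communities; negative edges mark exclusion patterns.
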