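"""Exchange network: from per-cell fluxes to donor->acceptor edges.

Builds the weighted directed network for one frame of a dipole experiment,
thresholds it at the 0.5 mmol/gdw/h sensitivity, and prints the topology
summary plus the strongest exchange pairs.
"""
import numpy as np

import protonflux as pf

exp = pf.generate_experiment("dipoles", n_cells=30, n_probes=30,
                             n_frames=1, noise_sigma=0.02, seed=3)
cells = exp.cell_frames[0]
flux = exp.ground_truth[0]

g = pf.pairwise_fluxes(flux, cells, exp.params)
gt = pf.threshold_graph(g, 0.5)
s = pf.graph_summary(gt)

print(f"nodes {s.n_nodes}, edges above 0.5 mmol/gdw/h: {s.n_edges}")
print(f"average degree {s.average_degree:.2f}, max degree {s.max_degree}, "
      f"largest component {s.lcc_size}")
print(f"leakage (export - import): {s.leakage:+.2f} mmol/gdw/h")
print()
print("strongest exchanges:")
edges = sorted(gt.edges(data=True), key=lambda e: -e[2]["F"])[:5]
for a, b, d in edges:
    print(f"  {a} -> {b}   F = {d['F']:6.2f} mmol/gdw/h")
print()
print("Every donor's pre-threshold out-edges sum exactly to its flux u_i;")
print("the planted dipole pairs dominate the top of the edge list.")
planted = {frozenset(p) for p in exp.dipole_pairs}
hits = sum(frozenset((a, b)) in planted for a, b, _ in edges)
print(f"top-5 edges that are planted dipole pairs: {hits}/5")
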