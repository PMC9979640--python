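"""End-to-end pipeline on the crossover scenario.

Simulates a hub-to-dipole crossover, writes the CSV tables, runs
simulate -> infer -> network -> summary through run_pipeline, and prints
the per-frame topology trend (the networked phase dissolving into sparse
dipoles as the hubs fade).
"""
import tempfile
from pathlib import Path

import pandas as pd

import protonflux as pf
from protonflux import io as pio

tmp = Path(tempfile.mkdtemp())
exp = pf.generate_experiment("crossover", n_cells=50, n_probes=50,
                             n_frames=10, noise_sigma=0.02, seed=11)
paths = pio.write_experiment(tmp / "sim", exp, pf.make_bulk_series(exp))

cfg = pf.RunConfig(
    physical=pf.PhysicalParams(background_concentration_c0=exp.c0),
    hyper=pf.Hyperparams(lambda1=0.02, lambda2=100.0, seed=11,
                         n_samples=300, burn_in=200),
    cells_path=str(paths["cells"]), probes_path=str(paths["probes"]),
    outdir=str(tmp / "out"), threshold=0.5)
result = pf.run_pipeline(cfg)

summary = pd.read_csv(result.outputs["summary"])
print("frame  max_degree  lcc_size  n_edges")
for _, row in summary.iterrows():
    print(f"{int(row.frame_index):5d}  {int(row.max_degree):10d}  "
          f"{int(row.lcc_size):8d}  {int(row.n_edges):7d}")
print()
print(f"outputs in {tmp/'out'} (fluxes.csv, edges.csv, GraphML, manifest.json)")
print("Max degree and largest-component size decay across frames: the")
print("hub-sustained network dissolves into isolated dipole motifs.")
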