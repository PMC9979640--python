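"""Synthetic experiments: the four generator scenarios.

Generates a small experiment per scenario and prints the statistics that
distinguish them: flux scale, sign balance, and tail weight relative to a
Gaussian fit (the hub scenarios are strongly heavy-tailed).
"""
import numpy as np

import protonflux as pf

for scenario in ("uniform", "dipoles", "hubs", "crossover"):
    exp = pf.generate_experiment(scenario, n_cells=60, n_probes=60,
                                 n_frames=6, noise_sigma=0.02, seed=42)
    pooled = np.concatenate([fv.values for fv in exp.ground_truth])
    d = pf.flux_distribution(pooled)
    print(f"{scenario:10s}  mean {d.mean:+7.2f}  sd {d.sd:7.2f}  "
          f"|u| range [{np.abs(pooled).min():.3f}, {np.abs(pooled).max():.1f}] "
          f"mmol/gdw/h   tail excess x{d.excess_tail_fraction / d.gaussian_tail_expectation:5.1f}")

print()
print("uniform: zero-mean Gaussian fluxes; dipoles: +-a pairs at short range;")
print("hubs: 5% exporters at ~100x; crossover: hubs decaying into dipoles.")
print("Probe pH readouts are the forward model plus N(0, 0.02) noise, and")
print("regenerating with the same seed reproduces every table exactly.")
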