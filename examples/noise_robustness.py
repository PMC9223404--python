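"""Quantify how segmentation jitter propagates into the estimates.

Adds Gaussian noise to 10% of the vertex coordinates of a synthetic
equilibrium tissue (sd = 2% of the typical cell linear size), refits, and
repeats: the median relative deviation of each parameter and the
correlation between original and noised predicted tensions summarize the
robustness of the method to image-processing error.
"""

from epimech.experiments import reference_sim_config, run_noise_test
from epimech.robustness import NoiseConfig
from epimech.simulator import simulate_dataset

config = reference_sim_config("A", tile=(10, 10), t_end=2000.0, seed=3)
sim = simulate_dataset(config)
report = run_noise_test(sim, NoiseConfig(n_rep=20, seed=7))

print("median |dq| over 20 replicates (relative deviation from truth):")
for name, med in report.median_abs_deviation.items():
    print(f"  {name:8s} {med:6.1%}")
print(f"predicted-tension correlation r: min {report.min_r:.4f}, "
      f"median {report.median_r:.4f}")
print("high r means the per-junction tension map is insensitive to jitter "
      "even when individual parameters move")
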