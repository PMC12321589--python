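"""Run a reduced dose x algorithm x iteration sweep and tabulate the metrics.

A desk-scale version of the phantom protocol: every reconstruction
snapshot is scored (CRC, COV, tissue contrasts) and collected into one
table, one row per (dose, algorithm, iteration).
"""

from mrgpet.experiment import ExperimentConfig, run_experiment

config = ExperimentConfig(
    size=(64, 64),
    n_angles=48,
    n_radial_bins=64,
    total_counts=5.0e5,
    dose_fractions=(1.0, 0.125),
    algorithms=(
        ("OSEM", None, 0.0),
        ("OSEM_GF", None, 3.0),
        ("MRg_b2", 2.0, 0.0),
    ),
    n_subsets=8,
    n_iterations=4,
    out_dir="scratch/example_sweep",
    save_images=False,
)
report = run_experiment(config)

cols = ["dose", "algorithm", "iteration", "crc", "cov", "gm_wm_contrast"]
last = report[report["iteration"] == 4][cols]
print(last.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(
    "\nEach row is one reconstruction snapshot; at 12.5% dose the penalized "
    "method keeps contrast with a fraction of the OSEM noise (COV)."
)
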