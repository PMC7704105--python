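"""End-to-end analysis: simulate, clean, compute effects, meta-analyse,
condense correlated traits, aggregate by functional group.

Every stage writes a CSV into the output directory and the manifest
records seeds, config hash and per-stage counts; the run is byte-for-byte
reproducible from the seed.
"""

import pandas as pd

from dimorph import PipelineConfig, run_pipeline

config = PipelineConfig(
    outdir="scratch/example_run",
    seed=42,
    simulation=dict(n_traits=12, n_mean=120, n_sd=40,
                    true_lnrr=0.1, true_lncvr=0.05),
)
manifest = run_pipeline(config)

for stage, info in manifest["stages"].items():
    print(f"{stage:12s} {info}")

second = pd.read_csv("scratch/example_run/second_order_results.csv")
print("\noverall (second-order) estimates, truth lnRR = 0.10, lnCVR = 0.05:")
cols = ["es_type", "k_traits", "mean", "ci_low", "ci_high", "n_male_biased", "n_female_biased"]
print(second.loc[second["group"] == "All", cols].to_string(index=False))
print("\nPositive means are male-biased; the CIs should cover the configured")
print("truths, and with a positive true lnRR most traits fall on the male side.")
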