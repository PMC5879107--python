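"""Generate a synthetic longitudinal OTU study and write it to disk.

Builds a count table, a covariate table with a missing-value mask, and the
ground-truth parameters used to generate them, then prints a few summary
numbers.  The files written here are the inputs the fitting example reads.
"""

import json
import os

import numpy as np
import pandas as pd

from otubayes import SimConfig, save_count_table, simulate_dataset

OUT = os.path.join(os.path.dirname(__file__), "output")
os.makedirs(OUT, exist_ok=True)

cfg = SimConfig(
    J=30, n_times=20, years=1.5, replicates=(2,),
    P_continuous=4, categorical_levels=(2, 2), missing_prob=0.15,
)
data, covars, truth = simulate_dataset(cfg, seed=11)

save_count_table(data, os.path.join(OUT, "counts.tsv"))
pd.DataFrame(
    {"sample": data.sample_ids, "time": data.time_of_sample,
     "replicate": data.replicate_index}
).to_csv(os.path.join(OUT, "metadata.tsv"), sep="\t", index=False)
cov_df = pd.DataFrame({"time": covars.times})
for k, name in enumerate(covars.continuous_names):
    cov_df[name] = covars.continuous[:, k]
for q, name in enumerate(covars.categorical_names):
    cov_df[name] = covars.categorical[:, q]
cov_df.to_csv(os.path.join(OUT, "covariates.tsv"), sep="\t", index=False)
with open(os.path.join(OUT, "truth.json"), "w") as fh:
    json.dump(
        {"beta_true": truth.beta_true.tolist(),
         "s_true": truth.s_true.tolist(),
         "alpha0_true": truth.alpha0_true.tolist(),
         "r_true": truth.r_true.tolist()},
        fh,
    )

nonzero = int((truth.beta_true != 0).sum())
print(f"wrote counts ({data.N} samples x {data.J} OTUs), covariates and truth to {OUT}/")
print(f"mean count per cell: {data.counts.mean():.1f}  (sequencing-depth spread "
      f"{data.counts.sum(axis=1).min()}..{data.counts.sum(axis=1).max()} reads)")
print(f"true nonzero effects: {nonzero}/{truth.beta_true.size} coefficients "
      f"({100 * nonzero / truth.beta_true.size:.0f}%; the rest are exact zeros)")
print(f"missing covariate cells: {covars.missing_mask.sum()} "
      "(code -1 in covariates.tsv, imputed during fitting)")
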