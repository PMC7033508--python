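"""Genome-wide prediction: single- and multi-kernel GBLUP abilities.

Cross-validated (random 80/20 partitions, paired across models) Pearson
correlation between predicted genetic values and across-environment BLUEs.
Array and GBS kernels perform comparably; the 19-locus SSR kernel trails;
kernel combinations track the best single kernel.
"""

import pandas as pd

from genebankgp.pipeline import run_pipeline

OUT = "results/pipeline"

run_pipeline({}, output_dir=OUT, seed=1, only=["qc", "phenotypes", "prediction"])

table = pd.read_csv(f"{OUT}/prediction_ability.tsv", sep="\t")
print(table.round(3).to_string(index=False))
best = table.loc[table.groupby("trait")["mean_ability"].idxmax()]
for _, row in best.iterrows():
    print(f"best model for {row['trait']}: {row['model']} "
          f"(ability {row['mean_ability']:.3f} ± {row['sd_ability']:.3f})")
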