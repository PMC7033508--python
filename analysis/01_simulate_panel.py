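"""Simulate the elite/PGR panel with array, GBS, and SSR marker sets.

Writes the truth-derived platform tables (dosage matrices, SSR calls, plot
phenotypes, true breeding values) under results/pipeline/ and prints the
panel dimensions.
"""

import pandas as pd

from genebankgp.pipeline import run_pipeline

OUT = "results/pipeline"
SEED = 1

manifest = run_pipeline({}, output_dir=OUT, seed=SEED, only=[])
sim = manifest["stages"]["simulate"]["params"]
labels = pd.read_csv(f"{OUT}/labels.tsv", sep="\t")

print(f"panel: {len(labels)} individuals "
      f"({(labels['population'] == 'elite').sum()} elite, "
      f"{(labels['population'] == 'pgr').sum()} PGR), seed {SEED}")
print(f"array markers ascertained: {sim['n_array_markers']}")
print(f"GBS markers sampled:       {sim['n_gbs_markers']}")
print(f"SSR allele columns:        {sim['n_ssr_columns']}")
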