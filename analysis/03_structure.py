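"""Population structure: PCoA per platform and Mantel concordance.

All three platforms separate elite lines from PGR on the first principal
coordinate; array- and GBS-based distance matrices agree closely (highest
Mantel r), the 19-locus SSR set only moderately.
"""

import pandas as pd

from genebankgp.pipeline import run_pipeline

OUT = "results/pipeline"

run_pipeline({}, output_dir=OUT, seed=1, only=["qc", "diversity", "structure"])

eigen = pd.read_csv(f"{OUT}/pcoa_eigenvalues.tsv", sep="\t")
print("explained fraction of molecular variation (PC1..PC3):")
for platform, sub in eigen.groupby("platform"):
    fr = (100 * sub.sort_values("axis")["explained_fraction"]).round(2).tolist()
    print(f"  {platform}: {fr}")

coords = pd.read_csv(f"{OUT}/pcoa_coordinates.tsv", sep="\t")
labels = pd.read_csv(f"{OUT}/labels.tsv", sep="\t")
merged = coords.merge(labels, on="individual")
for platform, sub in merged.groupby("platform"):
    g = sub.groupby("population")["PC1"]
    gap = abs(g.mean()["elite"] - g.mean()["pgr"])
    spread = g.std().max()
    print(f"  {platform}: PC1 elite/PGR separation = {gap / spread:.1f} within-group SDs")

print("\nMantel correlations between platform distance matrices:")
print(pd.read_csv(f"{OUT}/mantel.tsv", sep="\t").round(3).to_string(index=False))
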