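# Demonstration profile: 190 elite + 188 PGR lines, three marker platforms,
# two traits in 8 environments x 2 replicates.  Values omitted here fall back
# to the package defaults (genebankgp.pipeline.DEFAULT_CONFIG).
output_dir: results/paper_like
seed: 1
simulation:
  n_elite: 190
  n_pgr: 188
  n_loci: 4000
  n_ssr_loci: 19
  traits:
    - name: yield_like
      causal_fraction: 0.1
      rare_enriched: false
    - name: height_like
      causal_fraction: 0.05
      rare_enriched: false
diversity:
  bootstrap_rounds: 1000
prediction:
  cv_rounds: 50
experiments:
  cv_rounds: 50
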