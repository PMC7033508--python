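# Methods

`genebankgp` compares three marker platforms — ascertained SNP arrays,
genotyping-by-sequencing (GBS), and multi-allelic SSRs — for fingerprinting a
panel that mixes an elite breeding pool with genebank accessions (plant
genetic resources, PGR).  Because such panels are rarely redistributable, the
package pairs every analysis stage with a synthetic-data generator that
reproduces the statistical structure the comparison rests on, with known
ground truth.  This note records the models, the defaults and why they were
chosen, and what the synthetic experiments can and cannot show.

## Population and marker simulation

Founder alternate-allele frequencies are drawn from a U-shaped
Beta(0.2, 0.2), so rare variants are plentiful.  Two lineages then drift
independently by generational binomial resampling of allele frequencies at an
effective size Ne: the elite lineage at Ne = 30 for 10 generations (the
magnitude estimated for European elite wheat pools) and the PGR lineage at
Ne = 300 for 10 generations.  The smaller elite Ne makes the elite pool
genuinely less diverse — the fact the platform comparison must be able to
detect.  Within each lineage, individuals belong to one of 15 families that
drift further at Ne = 10 for 3 generations; this family layer supplies the
within-pool relatedness variation (full-sib-like clusters) that real breeding
panels carry and that genomic prediction exploits.  Genotypes are drawn from
inbreeding-adjusted Hardy–Weinberg proportions with F = s/(2 − s) at a
selfing level s = 0.95, so lines are almost fully homozygous, as inbred wheat
lines are.  Loci are simulated independently by default; an optional
near-duplicate block mode exists solely to exercise LD pruning.  The truth
genome is 4,000 loci — a deliberate desk-scale choice; counts that are
structural rather than scale-dependent (190/188 individuals, 19 SSR loci,
~9 alleles per locus, 8 environments, 2 replicates) follow the study design
the package emulates.

The three platforms derive from one truth genome:

* **Array**: loci are retained only if polymorphic, with minor allele
  frequency (MAF) ≥ 0.05, in a 30-individual discovery panel that is 80%
  elite.  This is the ascertainment-bias mechanism itself: rare alleles and
  alleles private to the PGR pool are invisible to the panel, so the retained
  set has a flattened MAF spectrum and understates PGR diversity.
* **GBS**: a frequency-blind random sample of loci (default 3,500 of 4,000,
  echoing a GBS set ~2.5× the array's marker count), keeping the rare-allele
  excess, with 2% missing calls and 30% of heterozygous calls collapsed to a
  random homozygote.  The heterozygote undercall stands in for low-coverage
  genotype calling; read-level simulation is out of scope.  Missingness is
  injected uniformly, i.e. the generator models the post-filter regime; real
  GBS concentrates missingness in specific markers, which the 5% missingness
  filter then removes.
* **SSR**: 19 multi-allelic loci with Poisson(9) alleles each (≈170 allele
  columns in total), simulated by Dirichlet founder frequencies with the same
  lineage/family multinomial drift, and coded as binary allele presence
  ("each allele is a marker").

## Marker coding and quality control

Bi-allelic genotypes are dosage-coded 0/1/2 with NA for missing; SSR alleles
are binary presence columns, a heterozygote scoring 1 in both its columns and
an uncalled locus contributing NA to all of that locus's columns.  QC runs in
the stated order: first remove markers with *strictly more than* 5% missing
calls, then remove monomorphic markers (allele frequency 0 or 1 among the
remaining calls).  Diversity is computed on the filtered but **unimputed**
matrix; prediction inputs are imputed by seeded random draws from
Hardy–Weinberg proportions at the observed allele frequency (a sampling
imputation, which preserves the frequency spectrum in expectation; the
per-marker HW draw is a recorded choice — genotype-frequency imputation would
be the alternative).

## Diversity statistics

Per locus with allele frequencies p_i:

* MAF = min(p, 1 − p) for bi-allelic markers; for a multi-allelic locus the
  frequency of the rarest allele.  Because a ~9-allele locus makes the
  rarest-allele MAF nearly zero by construction, the per-allele-column MAF
  (treating each binary column as a marker) is also computed and reported as
  the variant comparable to array/GBS MAF.
* Gene diversity (expected heterozygosity) H = 1 − Σ p_i²; "population
  heterozygosity" here is gene diversity, not the observed heterozygote
  fraction — on inbred material the observed fraction is ≈ 0 and carries no
  information, whereas gene diversity of a multi-allelic locus can reach
  ~0.7, the magnitude SSR panels show.
* Polymorphism information content, Botstein form:
  PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j².
* Rogers' distance between two individuals: per locus the individuals'
  allele-frequency vectors (entries 0, ½, 1 from the genotype) are compared
  by √(½ Σ_a (f1a − f2a)²), and the per-locus values are averaged over loci
  scored in both individuals (pairwise-complete, denominator adjusted per
  pair — missing data never imputed here).  For a bi-allelic locus this
  reduces to |x1 − x2| / 2 on dosages.

SSR H/PIC/MAF are locus-level quantities averaged over loci; the binary
coding is used for distances and kernels.  Uncertainty: MAF/H/PIC get
bootstrap SDs by resampling markers (loci) with replacement, 1,000 rounds by
default; mean Rogers' distance gets an SD from repeated subsampling of
genotypes *without* replacement (default fraction 0.8, a recorded choice).

## Population structure

PCoA is classical (Gower) scaling: square the distances, double-center,
eigendecompose; coordinates are eigenvectors scaled by √λ.  Averaged Rogers'
matrices need not be Euclidean, so negative eigenvalues occur: they are
dropped from the coordinates and from the explained-variance denominator and
their count is reported.  Axis signs are fixed by forcing the
largest-magnitude loading positive.  The Mantel statistic is the Pearson
correlation of strictly-lower-triangle entries of two id-aligned distance
matrices; the optional permutation p-value relabels one matrix's individuals
(one-sided, "greater").

## Two-stage phenotype analysis

Plot records are screened by BH-MADR: residuals from the stage-1 model,
standardized by 1.4826 × MAD, two-sided normal p-values, Bonferroni–Holm at
α = 0.05.  A zero MAD is an error (degenerate residuals), reported with the
trait name.

Stage 1, per environment: plot value = μ + genotype (fixed) + replicate +
incomplete block + error (random, independent, homoscedastic), fitted by
REML; the genotype BLUEs feed stage 2 unweighted (no stage-1 precision
weighting — a recorded choice).  Stage 2 with genotype fixed and environment
random yields across-environment BLUEs.  For variance components all terms
are random.  With one BLUE per genotype–environment cell the G×E and error
design matrices coincide, so σ²_G×E and σ²_e are estimable only as a sum;
`fit_stage2` therefore reports the cell-level residual as σ²_G×E (flagged as
confounded) when given BLUEs alone, and fits the plot-level all-random model
(genotype, environment, G×E, replicate-within-environment, block, error) when
the plot records are supplied, separating the two.  Heritability is
unaffected by the choice, because (σ²_G×E + σ²_e/r)/n̄ equals
σ²_G×E/n̄ + σ²_e/(r·n̄) in the entry-mean formula

    H² = σ²_G / (σ²_G + σ²_G×E/n̄ + σ²_e/(r·n̄)),

with n̄ the average number of environments per genotype and r the average
number of replicates, both computed from the post-outlier data.

### REML implementation

Variance components for factor models are estimated by direct maximization
of the profiled REML criterion in the penalized-least-squares form: with
variance ratios γ_k = σ²_k/σ²_e the mixed-model equations become an ordinary
penalized system whose Cholesky factor supplies the two log-determinants and
the penalized residual sum of squares; σ²_e is profiled out in closed form
and the deviance is minimized over θ_k = √γ_k ≥ 0 by bounded quasi-Newton
(finite-difference gradients, ftol 1e-12), with a Nelder-Mead polish if a
line search fails on a flat ridge.  This reaches the REML optimum
deterministically, handles boundary estimates (σ² = 0) without truncation
heuristics, and is checked against closed-form balanced-ANOVA estimators and
an independent mixed-model implementation in the tests.  For speed, the
random factor with the most levels (the G×E interaction in stage 2) is
absorbed by Schur complement before the dense Cholesky — its block in the
system is diagonal — so a 200 × 8 × 2 trial fits in about a second.
Iterative EM-REML was considered and rejected: it converges too slowly at
these problem sizes for routine resampling studies.

## Genomic prediction

The relationship kernel is the VanRaden numerator relationship
K = WW′ / (2 Σ p(1 − p)) with W the dosages centered by 2p, plus a recorded
1e-6 diagonal inflation for numerical positive-definiteness; the SSR kernel
applies the same construction to the binary allele columns (center by the
column frequency q, scale by Σ q(1 − q)).  GBLUP,

    y = 1μ + Σ_k g_k + e,   g_k ~ N(0, A_k σ²_k),   e ~ N(0, I σ²_e),

is fitted by REML on the profiled deviance over the γ_k: one Cholesky of
H = I + Σ γ_k A_k per evaluation, or, for a single kernel, one
eigendecomposition up front and O(n) per evaluation.  BLUPs are
g_k = γ_k A_k H⁻¹(y − μ̂) and test-set genetic values follow from the
train/test kernel cross-blocks — equivalent to BLUP on the joint kernel with
unobserved phenotypes.

Prediction ability is the Pearson correlation between predicted genetic
values and the observed values — the across-environment BLUEs the model was
fitted to — in the test set.  The default cross-validation draws ONE random
80/20 partition per round ("fivefold" in the resampling sense); a strict
disjoint-5-fold mode is available behind a flag.  Partitions depend only on
(seed, round, n), so models compared under one seed see identical partitions:
a paired design, which is what model-versus-model statements require.
Variance components are re-estimated on every training set.  Rounds with a
constant test response have no defined correlation; they are dropped and
counted.

The marker-set experiments reuse this machinery: random 158-marker kernels
(marker-density control), cumulative or interval MAF windows (rare-marker
contribution), cross-platform LD pruning (every GBS marker whose squared
dosage correlation with any array marker exceeds 0.95 is removed), and the
merged single-kernel "CGS" set compared against the two-kernel model on the
same inputs.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that the *mechanisms* behave as the theory says
under the simulated conditions: elite-biased ascertainment shrinks the
measured PGR-versus-elite diversity excess and flattens the MAF spectrum;
platform choice barely moves population structure or prediction ability;
sparse kernels and rare-marker removal cost ability; LD pruning is nearly
free.  The simulator draws loci independently (no genetic map, no LD decay),
models GBS artefacts phenomenologically rather than from reads, uses a
single additive trait architecture, and runs at reduced marker density, so
absolute values — diversity levels, ability around 0.5 rather than 0.8,
pruning fractions — are properties of the synthetic conditions, not
estimates for any real panel.  Directional and structural conclusions are
the transferable ones.

## Numerical and reproducibility choices

Degenerate inputs fail loudly: empty post-filter matrices, markers with no
observed calls, pairs of individuals sharing no scored loci, disconnected
genotype-by-environment incidence, non-PSD kernels, MAD = 0.  Non-converged
REML fits are flagged on the result object, never silent.  All randomness
flows through seeded NumPy generators; cross-validation derives per-round
seeds from a seed sequence, and the pipeline writes a manifest with SHA-256
checksums of every table — reruns with the same config and seed are
byte-identical.  The pipeline's declarative config rejects unknown keys
before any computation.

## Known limitations

No coalescent or recombination-map realism; no selection; no read-level GBS
model; single-trait, additive-only phenotypes; unweighted two-stage analysis
(stage-1 precision is not propagated); independent-effects variance
structures only (no spatial field models); PCoA and Mantel only for
structure (no model-based ancestry).  The per-locus SSR MAF is near zero by
construction for high-allele-count loci — use the per-allele-column variant
when comparing against bi-allelic MAF.
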