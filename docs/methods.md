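# Methods

`beavissim` quantifies the winner's curse ("Beavis effect") in quantitative
trait locus mapping: when the percent of phenotypic variance explained (PVE)
by a locus is estimated only for loci that reached genome-wide significance,
the estimate is upwardly biased, severely so when power is low.  The package
simulates this end to end in two panel designs modeled on the major
*Drosophila melanogaster* community resources: a GWAS-style panel of
resequenced inbred lines and an 8-founder multiparent panel (MPP) of
recombinant inbred lines (RILs) mapped through founder-haplotype
probabilities.

## Phenotype model

Each simulated phenotype carries exactly one causative locus.  For a
biallelic QTL at SNP *s* with line dosages `x_i ∈ {0, 2}` (inbred lines
scored as homozygous diploids), the phenotype is

    y_i = x_i + e_i,     e_i ~ N(0, Ve),     Ve = (1 − z)/z · σ²_G,

where `z` is the target PVE and `σ²_G = Var(x)` is the empirical variance of
the realized genetic values in the simulated sample.  With this scaling the
expected realized PVE equals `z` at any sample size (verified by a
regression property test).  The noise argument is a *variance*: treating it
as a standard deviation would not give `z` the stated meaning.  Gene-based
multiallelic QTL sum the alternative-allele counts of three SNPs inside a
2 kb gene window ± 1 kb flanks (values 0–3) and add noise the same way.
In the MPP, genotypes at the causative SNP are first *realized* by a
Bernoulli draw per RIL from the imputed reference-allele probability

    Prob(REF)_r = Σ_{i=1..8} F_i · P_{r,i},

with `F_i` the founder's allele and `P_{r,i}` the RIL's founder probability
at the nearest genotyped position.

Cross-panel transfer holds `Ve` fixed at the source panel's value, so the
realized PVE in a second panel follows the allele frequency there — higher
frequency, higher PVE — and a SNP absent from the target cannot validate.

## Mapping model

At each tested position the mixed model is `y = Xb + g + e`, `g ~ N(0,
σ²_g K)`, `e ~ N(0, σ²_e I)`.  `X` is the dosage (1-df test, GWAS design) or
all eight founder-probability columns (MPP design; the columns sum to the
intercept, so the test has 7 df and the null model is nested).  The full
8-column design is fit even where some founders have little or no in-sample
representation — rank deficiency is resolved by a pseudoinverse
(`rcond = 1e-9`), *not* by dropping columns, because that overfitting is
part of the phenomenon under study.

Kinship is leave-one-chromosome-out (LOCO): the matrix used for arm A is
built from all other arms' markers, which avoids the conservativeness of
letting the tested locus contribute to its own relatedness correction (a
property test confirms the causative-SNP LOD is not depressed relative to a
global-kinship fit).  The GWAS kinship is a VanRaden genomic relationship
matrix, `K = ZZ′ / (4 Σ p(1−p))` with column-centered dosages; any fixed
rescaling is absorbed by the variance components.  The MPP kinship is the
expected genome-wide identity-by-descent share, `K_ab = (1/n) Σ_j Σ_i
P_{a,i,j} P_{b,i,j}` over the genotyped grid, using the probabilities as
produced (no renormalization).

Fitting follows the eigendecomposition strategy: each LOCO kinship is
diagonalized once per panel; for each phenotype the variance ratio is
estimated once per arm by REML under the null (profiled over the
heritability on [0, 1); flat likelihoods resolve to the better boundary) and
held fixed across positions; each position then reduces to weighted least
squares in the rotated basis.  The LOD is the profiled likelihood ratio

    LOD = (n/2) · log10(RSS₀ / RSS₁)

on the whitened scale, which makes the PVE estimator

    PVE = 1 − 10^(−(2/n)·LOD)

*identically* the model-vs-null R².  This exact finite-sample form is what a
brute-force regression oracle computes in the K = I limit (the engine
matches it to 1e-6); the χ²/(2 ln 10) form is its first-order expansion.

Scans are localized to ±5 Mb around the causative site (clipped at arm
ends): with a single simulated QTL only the surrounding region carries
information, and localized scans make the threshold/power loop tractable. A
QTL is "mapped" when the peak LOD in this window *strictly* exceeds the
threshold; tied peaks report the leftmost position.

## Significance thresholds

Family-wise error is controlled empirically at 5%: phenotypes with no
causative locus (i.i.d. standard normal) are scanned genome-wide and the
threshold is the type-7 95th percentile of the per-scan maximum LOD.
Because an i.i.d. phenotype null and a permutation null coincide for
exchangeable lines, the random-phenotype version is used.  The local-region
threshold for validation scans takes the maximum within a ±5 Mb window at a
random position instead, and is therefore never larger.  Null peaks are
collapsed into independent signals before false-positive counting: a strict
local maximum (plateaus collapse to their leftmost point; endpoints count)
within a fixed genetic radius of a higher retained peak is eliminated —
2 cM for the MPP design, 0.5 cM for the GWAS design, reflecting their very
different LD ranges.  False-positive-rate curves report the mean number of
retained null peaks exceeding each threshold per scan.

## Synthetic panels: what they emulate

Both generators are deterministic functions of one integer seed, and
`SeedSequence` spawn keys give every experiment cell and replicate its own
named stream, so any row of a summary is reproducible in isolation.

**Genome.** Five arms (X, 2L, 2R, 3L, 3R) of 22 Mb at 2.5 cM/Mb — ~110 Mb
and ~275 cM, matching the scale of the emulated genome.  The genetic map is
linear per arm; coordinates are 1-based bp, half-open internally.

**GWAS panel.** 220,000 SNP sites (2 per kb; positions jittered around even
spacing).  Lines copy segments from a pool of 32 ancestral haplotypes with a
per-step switch probability `1 − exp(−Δbp / 500 bp)`, so marker-to-marker LD
decays to background within a few kb — the emulated panel's LD dies within
hundreds of bp, i.e. essentially between adjacent markers at this density.
Per-*arm* Dirichlet preferences over the pool (concentration 2 per
haplotype) create mild background relatedness while leaving each arm's
genotypes independent of the kinship built from the other arms; a shared
*genome-wide* preference would make every single SNP predictive of kinship
and the LOCO correction would absorb a third of any causative signal, a
pathology the coancestry-filtered panel being emulated does not have.
Site frequencies follow a density ∝ 1/q on [0.025, 0.5] (many rare
variants); realized MAF < 2.5% is filtered.

**MPP panel.** 8 fully genotyped founders; founder SNP alleles are Bernoulli
draws at 1/q-spectrum frequencies over 110,000 sites (1 per kb).  Each RIL
is a founder mosaic with Poisson breakpoints at 0.2 per cM (mean intact
segment ~5 cM ≈ 2 Mb, so imputed-SNP LD reaches background within roughly
2 Mb).  Segment founders are drawn from per-arm Dirichlet frequencies
(concentration 4 per founder), injecting drift-like dispersion around the
expected 1/8 share; the realized dispersion of the emulated resource is not
published, so the concentration is an exposed free parameter.  Founder
probabilities sit on a regular 10 kb grid (11,000 positions genome-wide, the
resource's test count); they encode the true mosaic exactly except at a 4%
random subset of (RIL, position) entries, where the one-hot vector is
blended with the uniform vector (blend weight U(0.3, 0.9)), calibrated so
~4% of Prob(REF) inferences land in (0.025, 0.975).  SNPs outside the grid
span are excluded; expected RIL MAF < 2.5% is filtered.

**Shared SNP pool.** For cross-panel validation, both panels can be drawn
from one ancestral catalog: each site is panel-private or shared
(59% / 34% / 7% by default), and shared sites' frequencies are perturbed by
logit-normal noise (sd 0.75), giving correlated but unequal MAFs.  This
emulates the qualitative sharing structure; it does not fit the real
resources' empirical sharing statistics.

**What the generators do not emulate.** Coalescent-exact genealogies,
demographic history, inversion polymorphism, sequencing error or missing
genotypes, selection during panel construction, dominance/epistasis, and
multiple simultaneous QTL.  Passing tests therefore show that the *method*
behaves as described on panels with the right first-order structure (allele
frequencies, LD range, relatedness, test multiplicity), not that any
specific real panel would give identical numbers.

## Experiments and desk-scale study sizes

Each experiment cell (design × sample size × true PVE) simulates one QTL per
replicate at a random filtered SNP, scans ±5 Mb, and calls significance at
the genome-wide threshold derived *on the same panel*.  The inflation factor
is `mean(peak PVE | mapped) / z`.  When fewer than 30 replicates are mapped,
batches are escalated up to a cap (default six batches), and a still-short
cell is flagged low-confidence.  Within-panel validation redraws phenotypes
at each mapped locus (subsampling to 100 loci when more were mapped) and
judges success at the local-region threshold; between-panel validation
transfers the locus effect as described above.

The acceptance script (`scripts/acceptance.py`) runs: MPP panels of 878 and
500 RILs and GWAS panels of 100, 185 and 200 lines; 200 null scans per panel
for thresholds; 200 replicates per cell escalated to at most 1,200 (MPP),
6,000 (200 lines) or 12,000 (100 lines, where power is ~0.5%).  These sizes
keep the full run under ~15 minutes on one CPU while leaving Monte-Carlo
errors small relative to the quantities compared.  Because the thresholds
are re-derived on the synthetic genome, the GWAS testing burden (220k tests
vs millions in the real resource) makes the desk-scale GWAS thresholds
somewhat lower and power correspondingly a few points higher than the
reference values; the MPP burden matches the real resource's ~11,000
positions.

## Numerical choices

- Large studies run the scan engine in float32 (half the memory, roughly
  double the throughput).  Dosage columns are centered before rotation and
  per-SNP moments are combined in float64: without this, float32
  cancellation in the 2×2 normal equations corrupts LODs by ~30%.  The
  float32 and float64 paths agree to ~3e-6 LOD.
- Collinear (e.g. zero-variance) SNPs fall back to the null fit and score
  LOD 0 rather than raising.
- Kinship eigenvalues are clipped at zero; matrices failing PSD by more than
  1e-6 (relative) are rejected.
- REML uses bounded scalar minimization (`xatol = 1e-6`) of the profiled
  restricted likelihood; the boundary h = 0 is always evaluated explicitly.
- Empirical quantiles use type-7 (linear interpolation) throughout.
- Monomorphic realized genotypes at a chosen locus are resampled (MPP
  binomial draws) or the locus is redrawn; gene windows with fewer than
  three eligible SNPs are rejected and a new gene is drawn.

## Known limitations

- The unconditional PVE estimator at the true position carries the usual
  finite-sample offset (≈ df/n), visible for the 7-df haplotype model at
  small n; tests allow for it explicitly.  This offset is a property of the
  estimator, not a bug, and is itself part of the small extra bias of the
  haplotype design.
- Validation subsampling ("re-test at most 100 mapped loci") uses a
  dedicated named seed stream; a different stream yields a different random
  subset, though the same configured run is always bit-reproducible.
- The real-data path is limited to a VCF adapter for GWAS-style panels and
  directory serialization; parsers for the real resources' release formats
  are out of scope here.
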