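# beavissim

Winner's-curse (Beavis effect) simulation for modern QTL mapping panels.

When the percent of phenotypic variance explained (PVE) by a locus is
reported only for loci that reached genome-wide significance, the estimate
is biased upward — often severely when power is low.  `beavissim` measures
this bias end to end for two mapping designs used in *Drosophila* genetics
and beyond:

* a **GWAS-style panel**: hundreds of resequenced inbred lines, single-SNP
  association with dosages `x ∈ {0, 2}`, many rare alleles, LD that dies
  within hundreds of base pairs;
* a **multiparent panel (MPP)**: recombinant inbred lines descending from 8
  founders, association through founder-haplotype probabilities (a 7-df
  test), LD extending ~2 Mb.

The package is aimed at people who map QTL in line panels and want to know
how much to trust an estimated effect size, how large a panel must be to
estimate PVE accurately, and what the realistic odds are of validating a hit
within the same panel or in the other design.

## Model

At each tested position a linear mixed model is fit:

    y_i = x_i b + g_i + e_i                      (SNP dosage test, 1 df)
    y_i = Σ_{j=1..8} p_ij b_j + g_i + e_i        (founder haplotype test, 7 df)

with `g ~ N(0, σ²_g K)` for a leave-one-chromosome-out (LOCO) kinship `K`
and `e ~ N(0, σ²_e I)`.  Variance components are REML-estimated once per
phenotype and arm (EMMA-style eigendecomposition, cached per panel), and the
LOD at each position is the profiled likelihood ratio
`(n/2)·log10(RSS₀/RSS₁)`.  The PVE of a peak is estimated as

    PVE = 1 − 10^(−(2/n)·LOD).

Phenotypes carry one simulated QTL with environmental variance
`Ve = (1−z)/z · σ²_G`, so the true PVE is `z`.  Significance uses empirical
FWER-5% thresholds: the 95th percentile of max LOD over null genome scans
(or over random ±5 Mb windows, for focused validation scans).  The
winner's-curse summary is the **inflation factor**
`mean(estimated PVE | significant) / z`.

See `docs/methods.md` for the full model, generator design and numerical
choices.

## Worked example

```python
import beavissim as bs

# 150-RIL multiparent panel on a two-arm 8 Mb toy genome
ctx = bs.build_context("mpp", 150, seed=42, n_snps=8_000,
                       arms={"2L": 4_000_000, "2R": 4_000_000})
nulls = bs.null_scans(ctx, 100, seed=1)
thr = bs.ThresholdSet.from_null_scans(nulls)
print(f"FWER-5% thresholds: genome-wide LOD {thr.genome_wide:.2f}, "
      f"local (+/-5 Mb) LOD {thr.local:.2f}")

cell = bs.run_power_bias(ctx, thr.genome_wide, z=0.05, seed=2,
                         base_replicates=200, min_detections=30)
print(f"true PVE 5%: mapped {cell.n_mapped}/{cell.n_simulated} "
      f"({cell.power_pct:.1f}% power)")
print(f"mean estimated PVE among hits: {cell.mean_peak_pve_mapped:.3f} "
      f"-> inflation factor {cell.inflation:.1f}x")
```

Output:

```
FWER-5% thresholds: genome-wide LOD 5.79, local (+/-5 Mb) LOD 5.29
true PVE 5%: mapped 41/200 (20.5% power)
mean estimated PVE among hits: 0.189 -> inflation factor 3.8x
```

Read it as: a locus that truly explains 5% of the trait variance is found in
only a fifth of experiments with 150 lines — and when it *is* found, its
estimated contribution averages 19%, almost four times the truth.  The
conditioning is the whole story: estimating at the true position for **all**
replicates (significant or not) gives a mean near the simulated value plus
the small finite-sample offset of the 7-df estimator.

A thin CLI wraps the same pipeline (`beavissim simulate-panel`,
`beavissim experiment power-bias|validate-within|validate-between`) with
YAML run configurations; every command is bit-reproducible from its config
and seed.

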