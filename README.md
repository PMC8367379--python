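# asedyn

Tools for studying **cis-acting variation in gene expression dynamics**:
allele-specific expression (ASE) testing over a timecourse, trajectory
clustering, variant-burden association, massively parallel reporter
(CRE-seq) library design and analysis, and variant annotation — together
with seeded synthetic-data generators that emulate the structure of a
yeast diauxic-shift ASE study.

In a hybrid diploid, the two parental alleles of a gene share one nucleus
and one trans-acting environment, so any expression difference between
them isolates cis-acting regulatory variation. Sampling RNA across an
environmental transition (here, the shift from glucose fermentation to
respiration) separates two kinds of cis effects:

* **ASE levels** — one allele is consistently higher;
* **ASE dynamics** — the allelic ratio changes over time (a delayed,
  faster/slower, or condition-specific response of one allele).

## The statistics

For each gene, let `f_i` be the (depth-normalized) frequency of the
reference allele at timepoint `i` and `w_i = ref_i + alt_i` the raw read
total. Levels are tested with a weighted intercept model

```
f_i = 0.5 + β0 + e_i ,    weights w_i
```

where `β0 = Σ w_i (f_i − 0.5) / Σ w_i` and a two-sided t test asks whether
`β0 = 0`. Dynamics are tested with a weighted Durbin–Watson statistic on
the residuals `e_i` of that model,

```
dw = Σ_{i=1}^{T−1} (w_{i+1} e_{i+1} − w_i e_i)² / Σ_{i=1}^{T} (w_i e_i)²
```

whose null distribution is obtained by permuting the timepoint order
(1000 seeded permutations by default; exact under exchangeability).
Both p-value sets are controlled with Benjamini–Hochberg FDR
(default cutoffs: 0.01 for ASE, 0.05 for CRE-seq), and the cutoffs are
validated by permutation: allele labels swapped independently at each
timepoint (levels null) and timepoint labels reshuffled (dynamics null).

Downstream stages: counts are normalized with median-of-ratios size
factors; burdens of SNPs/InDels in upstream, coding and downstream (80 bp)
regions predict ASE status via logistic regression `logit p = b0 + b1 x`
with Bonferroni control over the 6 × 10 = 60 regressions; promoters are
tiled with five 130 bp windows (30 bp step) across the 250 bp upstream of
the TSS into 200 bp barcoded reporter oligos, including single-variant
swap alleles and half-promoter chimeras; reporter activity is the ratio
of RNA to DNA barcode counts; and variants are annotated with PhastCons
conservation and the maximum across 196-motif-style PWM sets of the
binding-score change between alleles (log2-odds scan against a 36% GC
background, negative scores floored at zero).

## Worked example

Simulate a 500-gene timecourse in which 10% of genes carry a 2-fold
level effect and 10% a 3-timepoint delay, then run both ASE tests:

```python
from asedyn import synthetic, ase

cfg = synthetic.SimulationConfig(
    n_genes=500, n_timepoints=19, depth=2000, dispersion=0.01,
    effect_mix={"level": 0.1, "delay": 0.1},
    effect_magnitude={"level": 1.0, "delay": 3.0}, seed=42,
)
matrix, truth = synthetic.simulate_ase_counts(cfg)
table = ase.ase_test_table(matrix, n_perm=2000, seed=1).set_index("gene")

truth = truth.set_index("gene")
print("kind      n  sig_levels  sig_dynamics   (BH q < 0.01)")
for kind in ("none", "level", "delay"):
    sub = table.loc[truth.index[truth["kind"] == kind]]
    print(f"{kind:8s}{len(sub):4d}{(sub['q_levels']<0.01).sum():8d}"
          f"{(sub['q_dyn']<0.01).sum():12d}")
```

prints

```
kind      n  sig_levels  sig_dynamics   (BH q < 0.01)
none     400       1           2
level     50      50           0
delay     50       5          23
```

Every constant 2-fold imbalance is caught by the levels test and none by
the dynamics test; delayed responses — which have *no* allelic imbalance
at the first and last timepoints — are caught almost exclusively by the
dynamics test; false positives among the 400 effect-free genes are at the
per-mille level. The `beta0` column of `table` estimates the deviation of
the allele frequency from 0.5, and `dw < 2` indicates positively
autocorrelated residuals, i.e. a smooth trend in the allelic ratio.

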