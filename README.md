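# nbmmseq

Differential expression testing for **time-course RNA-seq** experiments with
a negative binomial mixed-effect model on exon-level counts.

Static DE tools compare mean expression between conditions irrespective of
time and miss genes whose *profiles* diverge, cross, or cycle differently
between treatments.  `nbmmseq` models each gene's exon counts over time and
condition jointly, and classifies genes into three types:

- **NPDE** (non-parallel DE): the time x treatment interaction is
  significant — profiles change shape between conditions;
- **PDE** (parallel DE): a treatment main effect with no interaction —
  profiles shifted by a constant;
- **NDE**: neither.

It works with or without replicates, at any (possibly unequally spaced) time
grid, and ships the count-level simulator used for its own validation.

## Model

Counts on exon *k* at time *t* in condition *g* follow a negative binomial,

```
Y_tgk ~ NegBin(nu, p(t, g, k)),          P(Y = y) ∝ p^nu (1 - p)^y,
logit p(t, g, k) = log beta_t + eta(t, g) + z_k b_k,
```

with `beta_t` an effective library-size offset, `z_k` the exon length (kb),
`b_k ~ N(0, sigma^2)` an exon random effect, and `eta` a smooth surface with
the functional-ANOVA decomposition

```
eta(t, g) = eta_0 + eta_1(t) + eta_2(g) + eta_12(t, g),
```

identified by the side conditions `∫ eta_1 = 0`, `Σ_g eta_2 = 0`,
`∫ eta_12(., g) = 0` and `Σ_g eta_12(t, .) = 0`.  Fitting minimizes the
penalized Henderson likelihood

```
Σ (nu + Y) log(1 + e^zeta) - nu zeta  +  Σ_k b_k^2 / sigma^2  +  N λ J(eta),
```

where `J` is the cubic-spline curvature penalty on `eta_1` and `eta_12`
(reproducing-kernel construction with Bernoulli polynomials).  The inner
loop is iterated weighted least squares; the outer loop selects the
smoothing parameters by a GML (REML-type) score and profiles the dispersion
`nu`.

Significance comes from the **Kullback-Leibler distance ratio**

```
KLR = KL(eta_F, eta_R) / KL(eta_F, eta_C),
```

comparing the full model F against the reduced model R without the tested
term, normalized by the distance to a constant fit C.  P-values are obtained
by permutation: shuffling time labels within condition (NPDE) or condition
labels within time points (PDE) and re-running the entire fitting pipeline.
Gene sets are scored by the mean KLR of their members (GMT input) with a
per-set permutation p-value.  All p-values are Benjamini-Hochberg adjusted.

## Worked example

Simulate six genes — three NPDE genes with cyclic profiles that are phase-
reversed between the two conditions, three NDE genes with the same cyclic
profile in both — and classify them:

```python
from nbmmseq import (SimulationDesign, simulate_dataset, classify_genes,
                     results_to_frame)

design = SimulationDesign(setting="cyclic", scenario=1, replicates=3,
                          n_genes_de=3, n_genes_nde=3, seed=42)
sim = simulate_dataset(design)
results = classify_genes(sim.datasets, alpha=0.05, B=50, seed=0)
table = results_to_frame(results)
print(table[["gene_id", "klr_npde", "pvalue_npde", "pvalue_npde_adj", "label"]]
      .to_string(index=False))
```

```
gene_id  klr_npde  pvalue_npde  pvalue_npde_adj label
 gene_1  0.812348         0.00             0.00  NPDE
 gene_2  0.818764         0.00             0.00  NPDE
 gene_3  0.837944         0.00             0.00  NPDE
 gene_4  0.000321         0.68             0.68   NDE
 gene_5  0.000803         0.60             0.68   NDE
 gene_6  0.000429         0.66             0.68   NDE
```

The three phase-reversed genes carry ~81-84% of their fitted structure in
the interaction component (`klr_npde ≈ 0.82`) and beat all 50 permutations
(`p = 0`, reported as 0, i.e. p < 1/B); the shared-profile genes have
interaction shares below 0.1% and large p-values, so they are NDE (the
subsequent treatment-effect test is also negative).

## Command line

```sh
nbmmseq simulate --setting 3 --scenario 1 --reps 3 --seed 7 -o sim/
nbmmseq test -i sim/counts.tsv --alpha 0.05 -B 100 --seed 7 -o results.tsv
nbmmseq genesets -i counts.tsv --gmt sets.gmt -B 100 --min-size 15 \
    --max-size 30 --min-present 5 -o sets.tsv
```

Input is a long-format TSV with columns
`gene exon exon_length condition time replicate count`; gene sets use the
GMT format.  Outputs are TSVs with a comment header recording the version,
seed and permutation count.

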