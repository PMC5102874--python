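# gpamds

Pleiotropy testing from GWAS summary p-values, and two-dimensional maps of
shared genetic architecture across many phenotypes.

Genome-wide association studies routinely report, for each SNP, a p-value
for association with one phenotype. When two diseases share part of their
genetic basis (pleiotropy), the SNPs driving both show up as jointly small
p-values across the two studies. `gpamds` quantifies that sharing from
nothing more than per-SNP p-value tables — no genotypes, no effect sizes —
and turns all-pairs sharing evidence into a 2-D "map" of phenotypes in
which genetically related traits sit close together. It is aimed at
statistical geneticists and epidemiologists working with public consortium
summary statistics.

## The model

For a pair of GWAS over a common set of M SNPs, each SNP t carries a latent
association state Z_t ∈ {00, 10, 01, 11} (null for both, first only,
second only, both), with mixing proportions π = (π00, π10, π01, π11).
Conditional on the state, p-values are independent with

    P_tk | null      ~  Uniform(0, 1)
    P_tk | non-null  ~  Beta(α_k, 1),   f(p) = α_k p^(α_k − 1),  0 < α_k < 1,

so non-null p-values pile up near zero. All parameters are estimated by EM;
both steps are closed-form (proportions update to responsibility means,
each α to the weighted Beta(α,1) MLE −Σw / Σ w·log p).

Three inference tools sit on top of the fitted mixture:

* **Local FDR / risk-SNP calls.** The local FDR of SNP t for a target
  hypothesis is its posterior null probability (e.g. 1 − post11 for
  "associated with both"); the *direct posterior approach* controls the
  global FDR at τ by selecting all SNPs whose local FDR falls below the
  largest threshold κ at which the running mean of sorted local FDRs stays
  ≤ τ.
* **Pleiotropy LRT.** Independence of the two genetic bases means
  π11 = π1✻·π✻1 (with π1✻ = π10 + π11, π✻1 = π01 + π11). The test compares
  the unconstrained fit against the independence-constrained fit (which
  factorizes into two marginal Uniform+Beta two-group models);
  −2 log λ is referred to χ²(1).
* **MDS map.** For K phenotypes, all K(K−1)/2 pairwise test p-values are
  log10-transformed (s_ij) and converted to distances
  d_ij = s_ij − 2·min_{k<l} s_kl, which classical (Torgerson) MDS — the
  algorithm behind R's `cmdscale` — projects to the plane. An alternative
  distance built from shared risk-SNP counts,
  d′_ij = 2·max n_kl − n_ij with n_ij = log10(count + 1), is provided for
  comparison.

A seeded simulator generates benchmark studies with exactly realized risk
fractions and pairwise sharing, so every claim above is testable against
known truth.

## Worked example

Simulate the five-phenotype benchmark (10,000 SNPs; 20% risk SNPs per
phenotype; 75% of risk shared within pairs (1,2) and (3,4); phenotype 5
isolated; risk p-values from Beta(0.4, 1)), fit the mixture to phenotypes
1–2, test pleiotropy, call risk SNPs, and map all five phenotypes:

```python
from gpamds import (GPAModel, five_phenotype_design, simulate_study,
                    test_pleiotropy, pairwise_tests, pleiotropy_distance,
                    classical_mds)

study = simulate_study(five_phenotype_design(seed=7))

res = GPAModel.from_matrix(study.matrix, cols=(0, 1)).fit()
print(res.summary())
```

```
          Four-state Beta/Uniform mixture (GPA) — EM fit
==================================================================
No. SNPs:             10000    model: unconstrained
Log-likelihood:       1007.8329    iterations: 132    converged: True
------------------------------------------------------------------
state       proportion
pi00            0.7418
pi10            0.0649
pi01            0.0652
pi11            0.1281
------------------------------------------------------------------
alpha1 (pheno1): 0.4061    alpha2 (pheno2): 0.3954
pi1* = 0.1930    pi*1 = 0.1933    pi11 - pi1*xpi*1 = +0.0908
shared fraction pi11/pi1* = 0.6637
==================================================================
```

The fit recovers the generating conditions: α̂ ≈ 0.40 (truth 0.4), an
estimated 19.3% of SNPs associated with phenotype 1 (truth 20%), and a
positive independence gap π̂11 − π̂1✻π̂✻1 = 0.09 signalling pleiotropy
(66% estimated sharing at this seed; the single-fit spread of that ratio
is about ±10 points around the designed 75%).

```python
lrt = test_pleiotropy(study.matrix.pair(0, 1))
print(lrt.summary())
sel = res.select_snps(tau=0.1)
print(sel.n_selected, sel.realized_fdr)
```

```
Pleiotropy LRT: pheno1 vs pheno2
  -2 log lambda = 75.9843  (chi2 df=1 p = 2.86e-18)
  llf alt  = 1007.8329  llf null = 969.8407
  pi11 = 0.1281  pi1*xpi*1 = 0.0373
  converged: True

risk SNPs for both phenotypes at global FDR 0.1: 68 (realized Fdr 0.0990)
```

```python
pw = pairwise_tests(study.matrix)
emb = classical_mds(pleiotropy_distance(pw))
print(emb.to_frame().round(2))
```

```
         dim1   dim2
pheno1  14.04 -10.56
pheno2  16.45  -1.47
pheno3 -16.09  -4.71
pheno4 -14.54  -6.44
pheno5   0.13  23.17
```

The designed structure is visible by eye: phenotypes 1–2 and 3–4 form two
tight clusters on opposite sides, and the isolated control phenotype 5
sits far from both.

The same pipeline runs from the shell on per-phenotype TSV files
(`snp`, `pvalue` columns, optionally gzipped):

```bash
gpamds simulate --design design.yaml --seed 7 --outdir sim/
gpamds run-all --input sim/pheno1.tsv --input sim/pheno2.tsv \
               --input sim/pheno3.tsv --input sim/pheno4.tsv \
               --input sim/pheno5.tsv --outdir out/
```

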