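# cd4atlas

A tested, reusable implementation of the downstream analyses behind a bulk
RNA-seq atlas of CD4+ T-cell subtypes (Naive, Th1, Th2, Th17, Treg, iTreg;
two biological replicates each): depth normalization, bimodal
expression-class calling, pairwise differential expression, identification
of subtype-upregulated genes, sample clustering and PCA, and isoform-level
transcript-switch detection.  Because the original cell material cannot be
re-sequenced at a desk, the package ships a synthetic-data generator that
plants every effect the pipeline is supposed to find — so each stage is
scored against known ground truth rather than against a frozen result file.

It is aimed at computational immunologists and RNA-seq methods developers
who want a transparent, end-to-end testable version of this analysis chain,
either to re-run it on their own count matrices or to use the planted-truth
simulator as a benchmark harness.

## Models and statistics

**Size factors** (median-of-ratios): for counts `K_gj`,
`s_j = median_g K_gj / (prod_v K_gv)^(1/m)` over genes with non-zero counts
in all `m` samples.  Normalized expression `q_gj = K_gj / (s_j * L_g)` with
`L_g` the gene length in kb (an RPKM-equivalent measure).

**Expression classes**: per subtype the log2 replicate-mean expression of
non-zero genes is fitted with a two-component Gaussian mixture
`w_LE N(mu_LE, sd_LE^2) + w_HE N(mu_HE, sd_HE^2)` by EM.  Class boundaries
come from the component posterior at contamination level alpha = 0.01:
`b_high` is where P(LE | x) drops to alpha, `b_low` where P(HE | x) rises
past alpha.  Genes are NE (zero in all replicates), LE, INT or HE.

**Differential expression**: per unordered subtype pair, a negative-binomial
Wald test on normalized group means with variance model
`Var(q_ij) = m/s_j + alpha_g m^2`.  Per-gene method-of-moments dispersions
are smoothed with a binned mean–dispersion trend (two replicates give a
2-df raw estimate, far too noisy to plug into a normal-reference test), and
`z = [log2(m_B + 0.5) − log2(m_A + 0.5)] / SE` with delta-method standard
errors evaluated at the pseudocounted means.  p-values are BH-adjusted
within each pair; a gene is DE at `padj <= 0.01`.

**SU genes**: a gene is *subtype-upregulated* for subtype *t* when it is
significantly up (padj <= 0.01, log2FC > 0) versus **every** other subtype
and in class INT or HE in *t*.  SU sets are disjoint by construction.

**Clustering / PCA**: counts are moderated with `log2(K/s + 1)`, samples and
top-variance genes are clustered with complete-linkage Euclidean
agglomeration, and samples are projected with gene-centered PCA.

**Isoform switching**: per sample and gene, isoform proportions Psi (PSI,
percent spliced in) are estimated by EM over read–isoform compatibility
classes (responsibilities proportional to Psi; read fractions converted to
transcript fractions by dividing by isoform length).  A subtype's *major
isoform* must agree across replicates; a *switch* between subtypes A and B
requires differing major isoforms, no significant DE in that pair, and
INT/HE class in both subtypes.  Its fold change is
`min(Psi_A(major_A)/Psi_A(major_B), Psi_B(major_B)/Psi_B(major_A))`.

## Worked example

The `analysis/` scripts run the whole chain on the default synthetic atlas
(2000 genes, 6 subtypes x 2 replicates, 50 planted SU genes per subtype at
+3 log2 units, 30 planted isoform switches):

```sh
python analysis/01_simulate_atlas.py
python analysis/02_normalize_and_classify.py
python analysis/03_differential_expression.py
python analysis/04_subtype_upregulated.py
python analysis/05_clustering_pca.py
python analysis/06_isoform_switching.py
```

Selected output (seed 11):

```
 Naive: LE N(0.90, 1.09) | HE N(8.06, 1.22) w=0.52 | boundaries [3.41, 5.12]
...
 Naive:  50 SU genes (50 of 50 planted recovered)
overall recall 1.000, precision 1.000
replicates whose nearest leaf is their sister: 12/12
Rand index of 6-way cut vs subtype labels: 1.000
600 multi-isoform genes; median major-isoform PSI 0.79
switch events: 150 across 15 pairs (mean 10.0 per pair); 150 with fold >= 2
planted-switch recovery: recall 1.000, precision 1.000
```

The mixture fit recovers the planted LE/HE components (means 1 and 8 on the
log2 scale) and places the FDR-0.01 boundaries between them; every planted
SU gene is recalled with no false calls; replicate pairs cluster together
for all six subtypes; and each planted switch gene (PSI 0.8/0.2 flipped in
one subtype) is detected in all five of its subtype pairs with a fold
change near the planted value of 4.

The same pipeline runs from files or a config via the `cd4atlas` CLI
(`simulate`, `normalize`, `classify`, `de`, `su`, `cluster`, `psi`,
`switches`, `run-all`); see `cd4atlas --help`.

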