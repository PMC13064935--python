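# coexkit

Transcriptome analysis toolkit for nominating candidate regulators of
expression programs in bulk RNA-seq cohorts — built around the workflow
used to characterize basal / stem-cell-like programs in prostate cancer:
convert expression to TPM, score gene-set activities per sample, rank
every detectable gene against those activities ("snake plots"), compare
gene *behavior* with the ALAN network statistic, and stratify the cohort
on one gene's expression quartiles to test alteration-frequency and
annotation differences between extremes.

It is a library first (`import coexkit`), with narrative scripts in
`examples/` and a thin `coexkit` CLI for the config-driven pipeline. A
seeded synthetic-cohort generator with planted ground truth makes every
stage testable end to end without any external download.

## Methods at a glance

- **TPM preprocessing.** FPKM → TPM by per-sample renormalization
  (`tpm_ij = fpkm_ij / Σ_i fpkm_ij × 10⁶`) or counts → TPM via gene
  lengths (`rate_ij = count_ij / len_i`, then renormalized); genes that
  are zero in *all* samples are dropped, duplicate gene names are made
  unique (`TP53, TP53 → TP53, TP53.1`), and values are natural-log
  transformed as `ln(x + 1)`.
- **Activity scores.** For gene set *S*, the per-sample activity is the
  mean z-score `(1/|S|) Σ_{g∈S} z_gj` of member genes' log-TPM. Every
  gene is Spearman-correlated with the activity; genome-wide BH-adjusted
  rankings sorted by ρ are the snake plots.
- **ALAN.** The behavior matrix **B** holds Spearman ρ of log-TPM for
  every gene pair (G² potential interactions; 20,000 genes → 4×10⁸).
  The ALAN score of genes *a*, *b* is the Pearson correlation of rows
  `B[a,·]` and `B[b,·]` with the two self-entries removed — a value in
  [−1, 1] measuring whether two genes occupy the same network, even
  when their direct correlation is modest. Cross-profile concordance is
  summarized by OLS R².
- **Quartile stratification.** Top/bottom `floor(n/4)` samples by one
  gene's expression (208 samples → 52 + 52 = 104 retained). Numeric
  features are compared with two-sided Mann-Whitney U; mutation and
  discrete copy-number categories (−2 HOMODEL, −1 HETERODEL, 0 NEUTRAL,
  1 GAIN, 2 AMP, mutation+CNA → MULTIPLE) are collapsed to
  altered/not-altered 2×2 tables tested with Fisher's exact test,
  BH-FDR corrected and star-annotated.
- **Bench quantities.** ΔΔCT fold change `2^(−ΔΔCT)` and the xenograft
  ellipsoid tumor volume `L × W² / 2`.

## Worked example

```python
import coexkit as ck

spec = ck.default_demo_spec(seed=1)              # 208 samples, 1000 genes,
matrix, alts, ann, truth = ck.generate_cohort(spec)  # basal vs luminal programs
logm = ck.log_transform(matrix)

score = ck.score_signature(logm, ck.GeneSet("basal", truth.modules["basal"]))
ranking = ck.correlate_genes_to_score(logm, score)
print(ck.snake_ranking(ranking, highlight=["BAS001", "LUM001"]).head())
```

Running `python examples/02_signature_snake.py` prints:

```
 rank   gene      rho  highlight  percentile
    1 BAS009 0.912003      False       100.0
    2 BAS006 0.908056      False        99.9
    3 BAS001 0.907337       True        99.8
    4 BAS008 0.905592      False        99.7
    5 BAS004 0.899418      False        99.6
BAS001: rank 3 of 1000 (rho +0.907, percentile 99.8)
LUM001: rank 991 of 1000 (rho -0.583, percentile 1.0)
```

The planted basal-module gene ranks in the top 1% of 1000 genes against
its own signature (ρ ≈ 0.91), while a gene from the anti-correlated
luminal program falls to the bottom with negative ρ — the pattern the
snake ranking is designed to expose. `examples/03_alan_network.py`
shows the network-level view (ALAN ≈ +0.94 within a program, ≈ −0.87
across opposed programs, profile R² ≈ 0.89 for co-regulated genes), and
`examples/04_quartile_stratification.py` recovers a planted deletion
enriched in program-high samples (Fisher q ≈ 8×10⁻⁴) while leaving an
equal-frequency mutation non-significant.

The same chain runs end to end from a YAML config:

```bash
coexkit run-all --config config.yaml --seed 1
```

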