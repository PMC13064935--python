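# Methods

## Synthetic cohort model

The generator produces gene × sample TPM matrices with planted latent
co-expression programs. Each module *m* has a standard-normal latent
factor `Z_m` per sample; inter-module dependence is a latent correlation
matrix validated positive semi-definite at spec construction (the error
names the most strongly coupled module pair). A member gene's
natural-log expression is

    log x_gs = b_g + λ_m · Z_m[s] + ε_gs,    ε ~ N(0, σ²)

with per-gene baselines `b_g ~ Uniform(lo, hi)` on the natural-log
scale. Columns are exponentiated and rescaled to sum to 10⁶, giving
heavy-tailed (log-uniform × log-normal) TPM magnitudes. Defaults: 208
samples (a mid-size clinical cohort), 1000 genes, two 10-gene programs
("basal", "luminal") with latent correlation −0.7 (mirroring the
mutually exclusive epithelial identity programs seen in prostate
cohorts), loading λ = 1.0, noise σ = 0.5, baselines on (0, 6). Under
this factor model the expected pairwise Pearson correlation of two
same-module genes' log-expression is λ²/(λ²+σ²) = 0.8, which the tests
verify by Monte-Carlo.

Alteration events are independent Bernoulli draws per sample and spec
entry, with separate probabilities for a "high" and "low" sample group.
`generate_cohort` anchors these groups to the top/bottom quartile of the
*first* module's latent factor, so stratifying downstream on a
first-module gene exposes the planted enrichment. The per-sample scalar
annotation (`variant_srpm`) is log-normal with a 0.8 loading on the
anchor factor, emulating a splice-variant abundance that tracks a
program. Ground truth (module membership, latent factors, planted
groups) is written as a separate artifact that no analysis stage reads.

What the generator does **not** emulate: read-level sampling noise,
batch effects, gene-length biases, co-occurrence structure between
alterations, or realistic gene-gene correlation beyond the planted
block factors. Passing recovery tests therefore demonstrates
correctness of the statistics under a known factor model, not
performance on real cohorts.

## Preprocessing

Both TPM conversion paths renormalize per sample to 10⁶ (relative
tolerance 1e-6 in tests); FPKM → TPM is idempotent on already-normalized
columns. Zero-gene removal drops only genes that are zero in *every*
sample. Duplicate gene labels get suffixes `.1, .2, …` (first occurrence
unchanged), the make-unique convention of the surrounding ecosystem, so
outputs are portable. The log transform is `ln(x + 1)`: a pseudocount is
required because genes zero in *some* samples survive filtering, and +1
is the field convention. Since `ln(x+1)` is strictly increasing, every
rank-based statistic downstream is invariant to it (property-tested).
Protein-coding subsetting is a plain allowlist filter; no annotation
database is bundled.

## Activity scores and rankings

The single-sample activity of a gene set is the mean z-score of member
genes' log-TPM — the simplest scorer consistent with correlation-based
downstream use; alternative scorers are out of scope. Zero-variance
members are excluded with a logged warning. Genome-wide rankings use
Spearman ρ with average ranks for ties; two-sided p-values use the
t-approximation, switching to the exact permutation null (full
enumeration, cached per n) below 10 tie-free samples. BH adjustment is
applied across all genes of one ranking (one family per signature).
Signature members are *not* excluded from their own ranking; they are
flagged via the snake table's highlight column instead. Ranking order is
deterministic: ρ descending, ties broken by gene label.

## ALAN

Two levels of association are deliberately distinct: the behavior
matrix uses Spearman on log-TPM (robust, transform-invariant,
consistent with the rest of the toolkit), while behavior-vector
comparison uses Pearson on the raw correlation vectors, which yields
the [−1, 1] output range. Self-entries (identically 1) are removed
before comparing two behavior vectors to avoid artifactual inflation;
the pair is put in canonical order first so the score is exactly
symmetric in floating point. The behavior matrix is accumulated in row
blocks (default 512) over a single rank-standardized copy of the data,
keeping ~20,000-gene cohorts feasible; tests run at ≤ 2,000 genes.
Cross-profile concordance is simple OLS of one profile on the other
(R², slope, intercept), computed on the intersection of gene universes
after removing both focal self-entries.

## Stratification

Quartile groups are the top and bottom `floor(n/4)` samples, sorted by
(expression, sample id) — the deterministic tie-break makes membership
invariant under strictly increasing transforms and reproducible across
runs. Both the cohort n and the retained n are reported, since public
cohort figures sometimes quote the former for a quartile comparison.

Mann-Whitney U uses the exact null when both groups have ≤ 8 tie-free
observations (chosen for test determinism), otherwise the tie-corrected
normal approximation without continuity correction, so identical group
multisets give p = 1 exactly; an all-constant feature short-circuits to
p = 1. Alteration collapsing maps discrete codes −2/−1/0/1/2 to
HOMODEL/HETERODEL/NEUTRAL/GAIN/AMP; mutation plus non-NEUTRAL CNA is
MULTIPLE, mutation alone MUT_ONLY. Samples absent from the alteration
data are NA and removed; an optional `profiled_samples` list marks
event-only tables (such as the generator's) as fully profiled, making
record-less samples NEUTRAL instead. Fisher's exact test runs on the
collapsed altered/not-altered 2×2 table; per-category counts are
attached as a descriptive table for stacked-bar output. A zero-margin
table is degenerate and reported as p = 1 with a flag rather than an
error. Star tiers follow the standard 4-tier scheme (ns > 0.05 ≥ * >
0.01 ≥ ** > 0.001 ≥ *** > 0.0001 ≥ ****); published tier definitions of
this annotation are frequently typographically inconsistent, so the
conventional scheme is fixed here and documented.

## Bench quantifications

ΔΔCT subtracts the *mean* control ΔCT (so the control group's geometric
mean fold is exactly 1); fold change is 2^(−ΔΔCT). The ellipsoid tumor
volume uses the common xenograft convention V = L·W²/2; the formula is
isolated in one function so the π/6·L·W·H variant can be substituted if
a study used calipers in three dimensions.

## Pipeline

`run_pipeline` executes simulate/load → preprocess → signatures → alan →
stratify in fixed order, writing TSVs plus a machine-readable run log
(config echo, versions, per-stage row counts) and a manifest. All
randomness derives from the single run seed via CRC32-hashed per-stage
seeds, and identical config + seed reproduces every result table
byte-for-byte (tested). Errors carry the failing stage name in the
message.

## Problem sizes and numerical choices

Tests and the acceptance script run on cohorts of 30–500 samples and
50–1000 genes: large enough that the factor-model asymptotics hold
(recovery checks use 20 seeds at n = 300, 1000 genes), small enough to
iterate quickly. Correlations are clipped to [−1, 1] against rounding;
expression TSVs are written at `%.17g` so text round-trips are exact.
Calibration checks (Fisher type-I ≤ 0.06 at α = 0.05 over 1,000 null
replicates; power ≥ 0.95 at q ≤ 0.05 with event probabilities 0.6 vs
0.1 at 50 per group) run through the same planting → categorization →
testing path users take.

## Known limitations

- Real signature gene lists (luminal/basal/club/hillock, subtype
  transcription-factor panels) are user-supplied; the generator plants
  its own modules, so published cohort correlations are reproducible
  only with the corresponding public downloads.
- The ALAN score's two association levels (Spearman inside the behavior
  matrix, Pearson between behavior vectors, self-entries excluded) are
  one explicit configuration point; other published variants of the
  statistic may differ in either choice.
- Alteration planting is marginal only — no mutual exclusivity or
  co-occurrence structure — matching what the frequency tests measure.
- No plot rendering: all outputs are plot-ready tables.
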