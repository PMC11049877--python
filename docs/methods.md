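# Methods

## The model

`rossig` treats 28-day sepsis survival prediction as a weighted linear
scoring problem on z-standardized log2 expression. For a signature of *n*
genes with weights W_i ∈ {−1, +1},

    score_j = Σ_{i=1..n} W_i (e_ij − μ_i) / S_i ,

where e_ij is sample *j*'s log2 expression of gene *i* and μ_i, S_i are the
gene's mean and standard deviation across all samples of the dataset being
scored. The weights come from the discovery cohort only: W_i is the sign of
gene *i*'s survivor-minus-non-survivor mean difference on the log2 scale.
With that orientation survivors score *higher*; a lower score predicts a
worse prognosis.

Key properties (all enforced by tests): the score is invariant to any
positive affine rescaling of a gene's expression row (standardization
absorbs it); the scores of a fully-scored dataset sum to zero; flipping all
weights negates every score.

### Choices the formula leaves open

- **SD denominator**: n−1 (sample SD).
- **Standardization scope**: μ_i, S_i are recomputed within each dataset
  being scored, so the validation cohort needs nothing from discovery.
  `survival_score(..., frozen_params=...)` supports deployment-style
  scoring with fixed parameters instead.
- **Stratification ties**: samples exactly at the mean score go to the
  low-score group ("above the mean" read strictly).
- **Missing signature genes** are dropped with a warning, and the score is
  *not* renormalized by the number of genes used — the formula is a plain
  sum.

## Differential expression

Survivors vs non-survivors are compared per gene with a two-sided Welch
t-test on log2 intensities; q-values are Benjamini–Hochberg across all
testable genes; the significance filter is two-sided and strict:
|log2 FC| > log2 1.5 ≈ 0.585 and q < 0.05. Genes constant within both
groups are flagged degenerate, assigned p = 1 and excluded from the BH
adjustment. A moderated-variance (empirical Bayes) test would differ for
very small cohorts; at the 265-sample discovery scale the plain Welch test
is an adequate, self-contained choice, and the package's guarantees are
parameter-recovery guarantees on synthetic data, not concordance with any
specific microarray pipeline. Fold changes are interpreted in log2 units
(`filter_deg(log_base=...)` parameterizes this; the packaged signature's
smallest magnitude, 0.596, sits just above log2 1.5, which is what pins the
default).

## Packaged fixtures

- `data/table1_signature.tsv` — the 37-gene free-radical survival
  signature (26 genes up in survivors, 11 down), with its log2 fold changes
  and ±1 weights.
- `data/ros_list_synthetic.txt` — a 137-gene curated ROS-style list. This
  file is a **synthetic stand-in**: it contains the 37 signature symbols
  plus 100 well-known oxidative-stress genes. Only its size and its 37-gene
  overlap with the signature carry information; no computation depends on
  the identity of the filler genes.

## Synthetic cohorts

`simdata` generates the world the analysis assumes: gene *g*, sample *j*

    x_gj = baseline_g + s_j d_g Δ/2 + ε_gj ,   ε_gj ~ N(0, σ_g²),

with s_j = ±1 for survivor/non-survivor, d_g ∈ {−1, 0, +1} the planted
direction and Δ the planted log2 effect. Defaults state the emulated
design: 2,000 genes; 265 discovery + 106 validation samples; survivor
fraction 0.7 (typical severe-sepsis 28-day survival; the emulated cohorts
never published their split); 150 planted survival genes (a plausible
DEG-pool size, also unpublished); Δ = 1 log2 unit; per-gene noise SD
uniform on (0.2, 0.6) and baselines uniform on (4, 12), microarray-like
after normalization; up-fraction 26/37 matching the packaged signature's
split; a 137-gene curated list sharing 37 genes with the planted set.

What the generator deliberately does **not** emulate: gene–gene
correlation, batch effects, missing values, probe-level artifacts, or any
relationship between expression level and variance. A green test therefore
establishes that the pipeline's statistics behave as specified under the
stated independence assumptions — not that real-cohort performance (e.g.
the AUC printed on any particular clinical dataset) is reproduced. At the
default effect size the planted signal is strong: the filter recovers the
planted genes essentially exactly and score AUCs saturate at 1.0, which is
intended — acceptance is about recovery, and weaker worlds are one
`effect_log2fc` away.

## Evaluation

AUC is the Mann–Whitney rank statistic (ties half-credited), computed
independently from the trapezoidal area under the full threshold-sweep ROC
curve; the two agree to 1e−10 and the rank value is reported. The positive
class is pinned to survivors with ascending scores — no automatic
orientation flipping, so a mis-oriented signature honestly shows AUC < 0.5.
The group test is the two-sided Wilcoxon rank-sum (exact enumeration for
combined n ≤ 20 without ties, otherwise normal approximation with tie
correction). PCA centers genes but does not scale them by default, since
the score already standardizes; `scale=True` offers the alternative.

## Random-signature null benchmark

Each of 10,000 draws (default) samples `size` genes without replacement
from a pool (whole genome, or the survival-related filtered-DEG pool),
weights them by the sign of their *discovery* log2 fold change — mirroring
how the real signature's weights arise, the single most consequential
interpretation in this module — scores both cohorts with per-dataset
standardization, and records the summed AUC. The percentile uses
strictly-below counting, so ties with the observed value count against the
signature (conservative). Draws are exhaustively enumerable for tiny pools
(`exhaustive=True`), which the tests use as an exact oracle.

Known saturation behavior: on the default synthetic world the observed
signature and most survival-related-pool draws all reach summed AUC 2.0, so
the conservative tie rule reports percentile 0 against that pool. This is
an honest property of a saturated world, not a defect; the whole-genome
benchmark (the acceptance property) is unaffected.

## Enrichment

ORA is the upper-tail hypergeometric probability of the observed overlap
within a stated universe, BH-adjusted across sets (sharing the DEG module's
BH implementation); the EASE variant (overlap − 1) is available behind a
flag. It is a functional stand-in for web-service annotation tools, not a
replication of any of them. GSEA uses the classical weighted running sum:
hits add |w|^exponent normalized over set hits, misses subtract
1/(N − N_hits); ES is the signed maximum deviation. The null is gene-label
permutation (default 1,000; phenotype permutation would require
per-permutation re-ranking and is not implemented); NES divides ES by the
mean |null ES| of matching sign, and results with fewer than 10 same-sign
permutations are flagged unstable. The default ranking metric in the
pipeline is the signed t-statistic.

## Deconvolution

Fractions solve min‖A f − b‖₂ subject to f ≥ 0 per sample (scipy NNLS),
then rescale to sum to one; expression is exponentiated from log2 to the
linear scale first, since reference matrices are linear-scale by
convention. This is a simplified stand-in for nu-SVR-based methods: its
guarantee is parameter recovery (exact for noiseless in-span mixtures, mean
absolute error ≤ 0.05 under 5% multiplicative noise), not concordance with
any published immune-profiling tool. `synthetic_reference` builds the
marker-block test matrix (6 cell types × 60 genes by default).

## Pipeline determinism

All stage randomness derives from one master seed via
`stage_seed(master, name)` — the stage name hashed (SHA-256) with the seed —
so enabling, disabling or reordering stages never reshuffles another
stage's draws. Files are written with fixed float formatting (`%.10g`), and
the run manifest records a SHA-256 checksum per artifact; two runs with the
same config and seed are byte-identical.

## Limitations

- No time-to-event modelling: the outcome is binary 28-day survival.
- Gene matching is exact string match on identifiers; no alias resolution.
- The synthetic generator's independence assumptions overstate effective
  sample size relative to correlated real transcriptomes.
- The bundled curated list is a synthetic stand-in (above); analyses of
  real data should supply the real curated list and real gene-set
  collections (GMT) in its place.
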