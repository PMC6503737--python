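# Methods

`omnimeta` implements a late-stage integration workflow for multi-study
two-arm transcriptomics: each study is analyzed on its own, and only
per-gene summary statistics (p-values, directions, standardized effect
sizes) cross study boundaries. This note documents the statistical
model behind each stage, the defaults and why, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Per-study differential expression

For gene *g* in one study with arms of size *n1* (case) and *n0*
(control), the penalized t-statistic is

    t_pen(g) = (mean_case − mean_control) / (se_g + s0),

with `se_g` the pooled two-sample standard error. The penalty `s0`
stabilizes genes whose sampled variance is near zero; by default it is
the **median of `se_g` over genes** — a robust, parameter-free choice
in the spirit of variance-penalized statistics (a percentile search
over candidate penalties would add a tuning loop for little gain at
these sample sizes). `s0=0` recovers the classical pooled t exactly.

Two-sided p-values come from **label permutations**: the case/control
labels are shuffled `B` times (default **B = 1000**) and

    p(g) = (1 + #{b : |t_pen^(b)(g)| ≥ |t_pen(g)|}) / (B + 1).

The same permutation is applied to all genes within a replicate — this
is forced by the design (labels belong to samples, not genes) and is
what preserves the co-expression structure of the null, which the
permutation FDR mode relies on. When the design admits at most `B`
distinct label assignments the full enumeration is used instead and the
p-value is the exact fraction. A consequence of sharing permutations is
that the per-gene p-values are weakly dependent conditional on the
drawn permutations; with small `B` this makes independence-based
goodness-of-fit tests (e.g. Kolmogorov–Smirnov) anticonservative on the
combined p-values even though each p-value is marginally valid. The
average rejection rate stays calibrated (fraction of null p < 0.05 is
5% ± binomial noise in our checks).

Effect sizes are bias-corrected standardized mean differences
(Hedges' g):

    d = (mean_case − mean_control)/s_pooled,
    g = d · (1 − 3/(4n − 9)),  n = n1 + n0,
    v = n/(n1·n0) + g²/(2n).

## Combining evidence across K studies

Each method targets a hypothesis setting: genes perturbed in **all**
studies (HS_A), in **one or more** (HS_B), or in **most** (HS_r).

| method   | HS  | statistic / reference distribution |
|----------|-----|------------------------------------|
| Fisher   | B   | −2Σ ln p_k ~ χ²(2K) |
| Stouffer | B   | Σ Φ⁻¹(1−p_k)/√K ~ N(0,1), equal weights |
| maxP     | A   | max p_k ~ Beta(K, 1) |
| rOP      | r   | r-th smallest p_k ~ Beta(r, K−r+1) |
| PR / SR  | A   | Σ ln(rank) / Σ rank vs column-shuffled null |
| FEM      | B   | inverse-variance pooled g, z = μ̂/se |
| REM      | r   | DerSimonian–Laird, weights 1/(v_k + τ̂²) |

Conventions that matter:

* **rOP's order index** defaults to r = ⌈0.7·K⌉ ("most studies");
  exposed as `--rop-r`. maxP is computed through the identical Beta CDF
  code path with r = K, so the identity rOP(r=K) ≡ maxP is bit-exact.
* **One-sided correction (OC).** Two-sided p's are split by the
  observed direction into p_up = p/2 (up) or 1 − p/2 (down) and
  p_down = 1 − p_up; each side is combined separately and
  p_meta = min(1, 2·min(P_up, P_down)), direction = winning side. The
  doubled-minimum (rather than max-of-sides) rule was chosen because it
  is the usual two-sided correction of a pair of one-sided tests; it
  guarantees that direction-concordant genes never score worse than the
  same p magnitudes with mixed directions (property-tested). On data
  dominated by null genes, OC p-values are driven by chance directional
  agreement and therefore correlate only weakly with their two-sided
  counterparts; with real disease signal the two track closely.
* **DerSimonian–Laird τ²**: τ̂² = max(0, (Q − (K−1))/C) with
  C = Σw − Σw²/Σw; when Q ≤ K−1 the estimate clamps to zero and REM
  coincides with FEM exactly. Cross-checked against R `metafor`
  (method="DL") to <1e-6. REM/FEM p-values are normal-theory by
  default; permutation-based FDR is available through the FDR stage.
* **PR/SR** rank genes ascending by p within each study (rank 1 = most
  significant, average ties); PR works in log space to avoid overflow.
  The null pools the statistic over all genes after shuffling each
  study's rank column independently, with the +1-corrected p; an exact
  enumeration mode exists for tiny inputs.
* **FDR**: Benjamini–Hochberg by default (deterministic, fast);
  permutation FDR q(p) = median over replicates of #{null ≤ p} divided
  by #{observed ≤ p}, monotonized and clipped to [0,1], available when
  a permuted null is supplied.
* **Consensus signature**: genes with q below the threshold in *every*
  supplied method and the same nonzero direction in all of them;
  direction conflicts drop the gene (counted, logged, never an error).
  Signed z-scores (|z| = Φ⁻¹(1 − p/2)) are taken from the first
  effect-size method if one is present, since μ̂/se carries magnitude
  information the p-value-only methods lack.
* p = 0 inputs are clamped to machine minimum, p = 1 to 1 − 1e−16
  before Φ⁻¹; direction ties (sum of study signs = 0) yield direction 0
  and exclusion from signatures.

## Sample-level QC (inter-array correlation)

The IAC of two samples is the Pearson correlation of their full
expression vectors over all genes (no variance filter). A sample is
flagged when its mean IAC falls below `overall_mean − c·overall_sd`
with **c = 3** by default. Flagging is single-pass — one cutoff
computed once, no re-computation after removal — and a degenerate zero
SD yields no flags. Classical-MDS coordinates of 1 − IAC are exported
for visual inspection only; no decision rule is attached to them.

## Study-level QC (six measures, SMR, exclusion)

Six measures are computed per study, each expressed as −log10 of a
permutation or hypergeometric p so that larger is always better:

* **IQC** — Spearman correlation between the study's gene–gene
  correlations (upper triangle over the `n_top_genes = 200` highest
  pooled-variance common genes) and the element-wise mean of the other
  studies', referred to a gene-identity permutation null.
* **EQC** — mean within-set |correlation| over a gene-set collection
  versus size-matched random sets.
* **AQCg / AQCp** — hypergeometric overlap p between the study's
  DE genes (p < 0.05) / enriched sets (q < 0.05) and a leave-one-out
  meta reference (Fisher-combined p over the other K−1 studies at
  BH q < 0.05, and its ORA).
* **CQCg / CQCp** — Spearman correlation between the study's −log10 p
  ranking (genes / sets) and the leave-one-out reference ranking,
  permutation p.

These definitions are a reconstruction from one-line descriptions of
each measure's intent; every threshold is a keyword argument so
alternatives can be swapped in. Inside this module DE evidence uses
analytic pooled-t p-values (not the permutation machinery) — the QC
ranking needs relative orderings, not calibrated per-gene inference,
and must stay cheap enough to permute `n_perm = 200` times. Permutation
p-values use the +1 correction, so each permutation measure is bounded
by log10(n_perm + 1). Empty overlap universes set the measure to 0 with
a logged warning. Genes and samples are put in a canonical (sorted)
order first, making the measures exactly invariant to input ordering.

The **standardized mean rank (SMR)** is the mean of the study's six
within-collection ranks (1 = best, average ties); the worst ⌈f·K⌉
studies by SMR are excluded, default f = 0.2, ties broken by study id
(logged). High SMR = poor quality, matching "low-ranking studies are
removed". The 2-D PCA biplot of the column-standardized measure matrix
is exported (scores + loadings, each loading's largest-magnitude
element made positive); zero-variance columns are dropped with a
warning.

## Downstream interpretation

**ORA** refers the overlap of a gene list with each set to the
hypergeometric upper tail. The universe is the harmonized common-gene
space — the genes that were actually tested — not the whole genome; BH
q-values are computed within a collection. **Compound prioritization**
scores every perturbation instance (compound × cell line × dose) in
both reversal directions (disease-up vs compound-down, disease-down vs
compound-up), BH-adjusts across all instances and directions jointly
(the adjustment scope is configurable), counts instances with adjusted
p < 0.01 per compound and direction, and reports compounds with total
count strictly greater than `min_sum = 5`, sorted by total then name.

## Synthetic data: what it emulates, what it does not

The generator produces K studies over a shared gene space: per-gene
baselines ~ Normal(7, 1.5) on the log2 scale (typical normalized
microarray magnitudes; downstream statistics are location-invariant),
residual noise ~ Normal(0, σ) with **σ = 1**, and for each DE gene a
direction sign (Bernoulli ½, shared across studies) and per-study
standardized effects δ ~ Normal(±μ, τ²) added to the case arm as δ·σ in
the scenario-selected studies (all / ⌈r_frac·K⌉ random / 1..K random).
Defaults: K = 6, G = 2000, 15/arm, π_DE = 0.1, μ = 1, **τ² = 0.1** —
the heterogeneity magnitude is an implementer choice (no published
estimate exists for this setting); 0.1 puts the between-study SD at
roughly a third of the mean effect, which is what the HS_r methods are
designed to tolerate. Planted defects: outlier samples are replaced by
independent noise matching the sample's own marginal mean/SD (this
destroys inter-sample correlation, which is precisely what IAC
detects — a mean shift would not move a correlation); corrupted studies
have every sample's gene values independently permuted, destroying
co-expression and DE signal while preserving marginals. Gene sets can
be enriched in true DE genes; compound libraries can contain reversal
compounds whose up/down sets overlap the disease down/up signature by a
configurable fraction.

Not emulated: raw reads or probe intensities, platform-specific
distributions, batch/surrogate-variable structure, gene–gene
co-expression beyond the shared baseline, and realistic library-size
effects. Passing tests therefore demonstrate the statistical machinery
under the model's own assumptions — independent genes, Gaussian noise,
honest group labels — not robustness to the full messiness of real
postmortem-brain data.

## Problem sizes and measured behavior

The test-suite and acceptance-script simulations use: null calibration
K = 5, G = 2000, 10/arm, B = 200; HS_r recovery K = 10, G = 2000,
20/arm, π_DE = 0.05, B = 1000, 10 seeds; sample QC 100 seeds at
G = 1000, 20 samples; study QC 20 seeds at K = 8, G = 400,
n_perm = 50. Under the HS_r recovery conditions the random-effects arm
is the power bottleneck: a gene carried by 7 of 10 studies at μ = 1
with τ² = 0.1 has cross-study mean 0.7 and effective between-study
variance ≈ 0.28, so the DL-REM z is ≈ 3.5 and its power at the BH 0.05
threshold is ≈ 65–75%; the measured consensus sensitivity is the
numbers the acceptance script prints, with realized FDR near 1%.

## Known limitations

* The six QC measures are reconstructions; absolute values depend on
  `n_top_genes`, `n_perm` and the internal 0.05/0.05 thresholds, so
  only their ranks (what SMR consumes) should be interpreted.
* KS-based uniformity checks on combined p-values are unreliable at
  small B because of permutation sharing (see above); use rejection
  rates or increase B for calibration audits.
* One-sided-corrected p-values are not comparable to two-sided ones
  gene-by-gene on null-dominated data.
* No covariate adjustment, paired designs, or moderated-variance
  empirical Bayes in the per-study model.
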