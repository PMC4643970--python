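# Methods

This note documents the statistical model behind each `pantcl` stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the decisions taken where the design was genuinely open.

## Synthetic cohort model

Expression is log2-normal. For probe p of gene g in sample s,

    log2 X_{p,s} = b_g + o_p + e_{g,s} + ε,   ε ~ N(0, σ²),   X = 2^{log2 X}

with gene baselines `b_g ~ N(baseline_log2_mean, baseline_log2_sd²)`
(defaults 7.0 and 1.5, a typical MAS5 log2 signal range), probe offsets
`o_p` (one designated probe per gene at 0, the rest uniform on [−2, −0.25]
so the maximal-mean probe is unambiguous and probe collapsing is
truth-checkable), and within-group noise σ = `noise_log2_sd` = 0.5. The
source study reports no within-group variances; 0.5 on the log2 scale is a
mid-range microarray value, fixed once as the study condition.

The sample effect `e_{g,s}` encodes three layers:

1. **Planted pan-signature.** 21 genes (6 up, 15 down) carry per-subtype
   signed fold-changes taken from the published pan-subtype table; a signed
   FC f contributes ±log2|f|, so at σ = 0 the generating linear-scale group
   means reproduce f exactly. One printed cell in that table is a
   typographical artifact ("6.3.8"); the generator uses 6.38, the value the
   adjacent column prints for the same gene.
2. **CAV1 mixture.** The anchor gene (CAV1 by default) is bimodal in the
   malignant samples: with per-subtype probability 0.77/0.47/0.85/0.75/0.69
   (AITL/ALCL/ATLL/HSTL/PTCL-NOS) a sample is High and receives a log2 shift
   of `cav1_high_log2_shift` = 4.0 (16-fold, the scale of the published CAV1
   fold-changes); Low samples draw from the healthy distribution. The
   mixture *replaces* a fixed subtype effect for the anchor — the two rules
   cannot hold simultaneously, and the High/Low structure is the one the
   stratification stage must recover. The anchor's marginal per-subtype
   geometric fold-change is therefore 2^(4·p_s), between ~3.7 (ALCL) and
   ~10.6 (ATLL): large enough that the anchor still lands in every
   per-subtype significant list.
3. **CAV1-coupled block.** `n_tme_genes` = 30 genes track the anchor's
   realized log2 signal across malignant samples with slope calibrated so the
   population Pearson correlation equals `tme_coupling_r` (default 0.6,
   signs random): slope = rσ / (√V_d √(1−r²)) with V_d the anchor's
   malignant log2 variance (shift²·p̄(1−p̄) + σ²). Healthy samples are left
   uncoupled so the healthy-vs-subtype contrasts stay clean; at σ = 0 the
   coupling degenerates to slope 0.

Cohort composition defaults mirror the emulated pooled study: 34 CD4 + 18 CD8
healthy controls (identical generating means — the analysis pools them) and
43/45/13/8/78 malignant samples per subtype. The gene panel written by the
generator contains the 21 planted genes plus unplanted null genes to a total
of 217. Identical configurations (including seed) reproduce byte-identical
outputs.

**What the generator does not emulate:** array batch effects, platform or
normalization artifacts, correlated co-expression modules beyond the CAV1
block, heavy-tailed or heteroscedastic noise, and clinical covariates.
Passing tests therefore demonstrate that the statistical machinery recovers
planted structure under idealized log-normal noise at the study's sample
sizes — not that it is robust to the full messiness of pooled public data.

## Class comparison

t statistics are computed on log2 signal. The default is the pooled-variance
two-sample t: the generator is homoscedastic by construction, the pooled t is
the classical microarray class-comparison statistic, and with groups as small
as 8-vs-52 the Welch degrees of freedom (~9) would make the heavy t tails,
not the data, the binding constraint. Welch is available (`equal_var=False`)
for heteroscedastic use.

The permutation test is multivariate: one label permutation is applied to all
genes simultaneously, preserving gene–gene correlation. With B random
permutations, `p = (1 + #{|t*| ≥ |t_obs|}) / (B + 1)` (the +1 smoothing
avoids p = 0); when the number of distinct label assignments is ≤ B the
distribution is enumerated exhaustively and p = #{|t*| ≥ |t_obs|}/total with
the observed assignment included. Comparisons use a relative tolerance of
1e-9 so permutations equal to the observed statistic up to rounding count as
exceedances. Random permutations are drawn without duplicate tracking — the
bias is negligible at B = 1000 for the assignment spaces involved. A gene
constant across all samples gets t = 0, p = 1, and a `constant` flag.

**False-discovery control.** Two modes mirror the two criteria used in this
kind of analysis:

* `p_and_fdr` — significant iff permutation p < α_p (0.001) *and* BH q <
  α_fdr (0.001), where the q enters on the t-distribution p-values. This is
  a deliberate choice: with B = 1000 the permutation p cannot fall below
  1/1001, so its BH transform over a few hundred genes is bounded below by
  roughly (1/1001)·G/r and a q < 10⁻³ cut would be unsatisfiable *by
  construction*, regardless of effect size. The t-based q is how microarray
  class-comparison tools report their FDR column, and it is the only reading
  under which the dual criterion can select genes at all at B = 1000. Both
  q columns (`q_bh` over permutation p, `q_t` over t p-values) are reported.
* `korn` — significant iff permutation p < α_p and the gene is in the Korn
  step-down reject set. The step-down visits genes in decreasing |t| order;
  at candidate rejection count r it allows u(r) = ⌊γ·r⌋ false discoveries
  and compares the r-th statistic to the `confidence` quantile (the
  ⌈confidence·B⌉-th order statistic over permutations) of the (u+1)-th
  largest permuted |t*| among genes ranked r−u and below, stopping at the
  first failure. With probability ≥ confidence the realized false-discovery
  proportion among rejections is ≤ γ. Defaults γ = 1%, confidence = 99%.

Signed fold-changes use linear-scale geometric means: m/h when the malignant
mean is larger, −(h/m) otherwise, +1.0 at equality, so |FC| ≥ 1 always.

## Signature intersection

A gene joins the pan-up list iff it is significant with FC > 1 in every
subtype (pan-down analogously); relaxed membership needs a consistent
direction in ≥ `min_support` (default 3) subtypes. Genes significant in
opposite directions in different subtypes are excluded from both lists and
reported as direction-conflicted. This deterministic intersection replaces
the manual compilation step of the original workflow — the only reproducible
reading. `min_support = n` reproduces the pan lists exactly, and relaxing
the per-subtype criteria can only grow the lists.

## Top-scoring pairs

Single top pair (k = 1), matching the analysis being reproduced, which
reports exactly one pair. Δ ties break to the larger secondary score Γ (the
between-class gap in mean within-sample rank difference of the two genes),
then to the lexicographically smallest pair; within-sample signal ties count
as not(i < j) both in fitting and prediction, making every path
deterministic. Evaluation defaults to leave-one-out cross-validation with
in-fold pair reselection — the honest default in the TSP literature —
with resubstitution available; sensitivity/specificity take malignant as
the positive class. The published cohort-level 98.4%/88.5% figures depend on
the real pooled data and are a documentation note here, not a test target.

## CAV1 stratification

T = healthy mean + 2·sample SD (ddof = 1; the n-vs-n−1 choice is unstated in
the source and documented here) on the linear signal of the designated gene,
mirroring how the probe-level signal is plotted and thresholded in this kind
of analysis. Strictly greater than T means High; the boundary goes to Low
("above the threshold" read strictly). Healthy boxplot outliers use
Q3 + 1.5·IQR with linear-interpolation quartiles, recorded in the result
metadata because outlier sets differ across quartile conventions. The
threshold depends only on healthy samples, and labels are invariant to any
common positive rescaling.

Percentages are rendered whole-percent with halves rounding up (7/8 → 88%,
5/8 → 63%) — the convention that reproduces the published tables; Python's
banker's rounding would not.

## Tumor-microenvironment comparison

Correlation pre-filtering computes each gene's Pearson r against the anchor
on the log2 scale (consistent with the DE statistic) over the malignant
samples only — the High/Low contrast lives within the malignancies; the
sample set is recorded in the result and switchable. Two-sided p comes from
t = r√(n−2)/√(1−r²) on n−2 df; a gene passes iff p < 0.01 *and* |r| ≥ 0.22,
both enforced (the conservative reading of a jointly printed rule; at
n = 187 the |r| cut corresponds to p ≈ 0.0025, so the p condition is not
redundant at smaller n). The filtered submatrix then runs through the
class-comparison engine in Korn mode with Low as reference, which is exactly
equivalent to calling the engine directly on that submatrix.

## Enrichment

The primary over/under-representation test is the exact binomial (k list
members in a category of universe frequency q, two-sided by doubling the
smaller tail, capped at 1) — matching the statistic of the classical
gene-list tools — with a hypergeometric variant available. Rank enrichment
is a two-sided Mann–Whitney U of category members' fold-changes against
non-members: exhaustive enumeration of all group assignments (midranks for
ties) when both groups have ≤ 8 members, and a tie-corrected normal
approximation without continuity correction otherwise. Bonferroni correction
runs across the categories actually tested. Term-level counts and p-values
from any dated ontology release are database-version-dependent and are not
reproduction targets; categories are supplied as GMT.

## IHC summaries

A patient is lymphoid-positive for a marker iff any of their cores is scored
positive or light. Both rules are documented choices: patient-count
denominators require a core-to-patient rule (any-core chosen, all-cores
switchable), and "light" must merge into positive for the core-level
narratives to reconcile with the printed patient counts. Stromal positivity
is tabulated separately. Where a printed summary percentage is internally
inconsistent with its own counts (e.g. 29/65 printed as 46%), the module
reports the recomputed value (45%). Multi-rater inputs are accepted as one
consensus call per core; an optional majority-vote helper is provided.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeds; identical
  configurations give byte-identical serialized outputs, and the pipeline
  manifest records parameters, seeds, and sha256 checksums per stage.
* Probe-collapse ties break to the lexicographically smallest probe id;
  "average intensity across arrays" is the unweighted arithmetic mean over
  all samples on the linear scale.
* Rows with non-finite or ≤ 0 signal are rejected at load, never imputed —
  silent imputation would corrupt geometric-mean fold-changes.
* Degenerate inputs are defined, not special-cased ad hoc: zero-variance
  genes (t = 0, p = 1, flagged), equal group means (FC = +1), all-equal
  values in the Mann–Whitney (p = 1 under tie handling), σ = 0 cohorts
  (exact generating means, coupling slope 0).

## Problem sizes in tests and the acceptance script

The stochastic checks run at the study's own design sizes where that is the
point (52 + 187 samples, 217-gene panel, 1000 permutations) and at reduced
replicate counts where only Monte-Carlo resolution is at stake (e.g. 60–200
replicates for the false-discovery-proportion control, a 2000–5000-gene
global null for calibration, signature recovery averaged over a small fixed
seed panel). Recovery of the weakest planted effects (|FC| ≈ 1.5–1.7 at the
13-sample ATLL group) sits near the power boundary of the design itself, so
recovery counts are asserted seed-averaged rather than on a single draw.

## Known limitations

* The per-gene permutation p is floored at 1/(B+1); analyses needing smaller
  p must raise B or rely on the t-based q / Korn modes.
* The Korn step-down recomputes an order statistic per rejection step;
  runtime grows with the number of rejections times permutations (suffix
  maxima make the common u = 0 steps O(1)).
* The correlation filter assumes an approximately linear gene–anchor
  relation on the log2 scale.
* LOOCV refits the pair per fold; on very large cohorts k-fold would be the
  pragmatic substitute (not implemented — out of scope).
* The enrichment statistics are methodological equivalents of the classical
  web-tool tests, not replicas of any database release.
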