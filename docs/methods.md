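# Methods

This note documents the statistical models behind `mirnorm`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that were genuinely open.

## Scales and conventions

All qPCR computations run directly on Ct, the quantification cycle. Ct is
(up to sign and an efficiency factor) the log2 of input quantity, so a Ct
difference is a log2 expression ratio and one cycle is one doubling. No
conversion to linear relative quantities is performed for the stability
statistics: pairwise Ct differences already are the log-ratios those
statistics are defined on.

Multi-gene normalizers and candidate combinations are collapsed per sample
by the **geometric mean of the member Ct values**. This follows the
combination convention of reference-gene studies. It is a deliberate,
documented choice and not the geometric mean of linear abundances (which
would be the arithmetic mean of Cts); a consequence worth knowing is that
ΔCt against a multi-gene normalizer is exactly invariant to global Ct
shifts only in the single-gene case — for combinations the invariance is
approximate (to first order in shift/Ct, i.e. to ~0.1% at typical Ct
values).

Undetected reactions are carried as missing values end to end, never as a
numeric sentinel (such as 40), so detection-based rules operate on
detection status, not on magnitudes.

## qPCR preprocessing

* **Replicate collapsing.** Arithmetic mean of the detected replicates
  (median available via option); a QC flag is raised when the replicate
  sample SD (n−1) exceeds `max_sd` (default 0.5 cycles). The mean is the
  de-facto qPCR convention.
* **Detection filter.** A gene is discarded when it fails detection
  (undetected or Ct above the 40-cycle limit) in more than a fraction
  `tolerance` of samples; the default tolerance 0 implements the strict
  clinical rule "undetected in any cohort sample ⇒ discard". The
  discard log names offending samples.
* **Inter-run calibration.** Per gene, each run's Ct values are shifted by
  −(Ct_cal,run − mean over runs of Ct_cal), using the pooled inter-run
  calibrator measured on every run. Calibration is per gene (assays have
  independent efficiencies), not one global offset per run. By
  construction this removes *between-run differences* exactly; the common
  mean offset remains, which is harmless because every downstream
  statistic is invariant to a per-gene constant.
* **Stage order.** Collapse → detection filter → calibrate → ΔCt. The
  filter operates on raw detection status, so applying it before
  calibration is the conservative order.

## Stability statistics

* **geNorm.** M_j = mean over partners k of SD_s(Ct_j − Ct_k), stepwise:
  the gene with the largest M is removed and M recomputed until two genes
  remain; the procedure cannot separate the final pair, which therefore
  shares ranks 1–2 (1.5 each, consistent with the average-rank tie rule).
  The pairwise variation V(n/n+1) is the SD across samples of the
  difference between the log-scale normalization factors of the top-n and
  top-(n+1) panels. The V series is reported; the conventional V < 0.15
  panel-size heuristic is left to the user. Pairwise SDs are computed via
  the gene covariance matrix (Var(X_j − X_k) = V_j + V_k − 2C_jk), with a
  naive loop implementation serving as the test oracle.
* **NormFinder.** Model-based decomposition on the Ct scale. Per group,
  per-sample gene averages are removed; the per-gene variance is estimated
  with the finite-panel moment correction
  σ̂²_i = (s²_i − Ŝ/k²)·k/(k−2) (negative estimates clipped to 0), and the
  inter-group difference d_ig is shrunk toward zero by
  τ²/(τ² + σ̂²_ig/n_g), with τ² estimated from the spread of the d's minus
  their sampling variance. The stability value averages, with **equal
  group weights**, |d̃_ig| + sqrt(σ̂²_ig/n_g). This combination keeps the
  intra-group term alive when group differences vanish, so with identical
  groups the ordering reduces to the group-free variant (the estimated
  per-gene SD) — the behaviour one wants from a stability measure; a pure
  posterior-uncertainty combination would instead collapse to zero for
  all genes. Where the original leaves the combination weight implicit,
  equal weighting of the groups is used.
* **BestKeeper.** Per-sample index = geometric mean Ct over candidates;
  per gene: SD(Ct), CV = 100·SD/mean(Ct), Pearson r against the index. A
  constant gene has undefined r (reported as missing) but ranks best by
  SD. The single ascending ranking key is the SD, because the rank
  aggregation needs one monotone "lower = more stable" key per method.
* **Comparative ΔCt.** stability_j = mean over partners of
  SD_s(Ct_j − Ct_k); identical to a single non-iterative geNorm pass, kept
  as a separate method because the aggregation treats it as one of four
  independent votes.

All sample SDs use the n−1 denominator, matching the original
publications.

## Comprehensive ranking and selection

Within each method, candidates are ranked ascending by the method's
statistic, ties receiving the average rank; geNorm contributes its
stepwise-exclusion ranking. The comprehensive **stability value** is the
geometric mean of the four ranks — invariant to any monotone transform of
a method's statistic, bounded by the extreme ranks, and equal to 1 only
for a unanimous winner.

The **CV rule** computes, per candidate, 100·SD(ΔCt)/|mean ΔCt| over
control samples, and excludes candidates above 200%. Two readings of
"ΔCt" are implemented because the underlying convention is ambiguous when
the candidate *is* the prospective control:

* `self-vs-calibrator` (operation default): candidate Ct minus the
  candidate's Ct on the run's calibrator pool. Under the generator's model
  the calibrator pool equals the gene baseline plus the run offset, so
  this ΔCt has mean ≈ 0 for every well-behaved candidate and the CV is
  dominated by its vanishing denominator — the mode exists for real data
  where pools and cohort means need not coincide.
* `targets-vs-candidate` (pipeline default): ΔCt of a designated target
  set normalized to the candidate, pooled over targets and control
  samples. This yields the interpretable 20–60% CVs for stable candidates
  and the >200% explosions for erratic ones.

|mean| is used in the denominator because ΔCt means are legitimately
negative; candidates with |mean ΔCt| below an epsilon (default 0.05
cycles) are flagged "unstable by construction" rather than silently
inverted, and excluded. Selection takes the minimal stability value among
CV survivors, breaking ties by lower CV; survivors with stability value
< 5 form the shortlist.

Combinations default to pairs (k = 2); larger k is supported but grows
combinatorially. Note one intrinsic property of aggregating overlapping
candidates: combinations share members and are therefore correlated,
which flatters middle-of-the-road combinations in the pairwise-SD methods.
The planted-truth tests quantify that the selection still recovers a
genuinely superior pair.

## Sequencing screen

RPM = count/library total × 10⁶. Isoforms with zero counts in all samples
are discarded first. The base mean is the mean RPM over all samples (the
counts are consumed generically; no size-factor machinery). The group
log2FC adds a pseudocount of 0.5 to both group means, so zero groups stay
finite. The candidate screen discards base mean < 100 and |log2FC| > 2 —
the fold-change gate is two-sided by default since stability screening
must exclude changes in either direction — and ranks survivors by
|log2FC| ascending. The DE consensus intersects the significant sets
(padj < 0.05, or an explicit flag column) of ≥2 external DE tables and
then drops ids with first-table baseMean < 100; it is invariant to table
order.

## Relative quantification

ΔΔCt_s = ΔCt_s − mean(ΔCt over controls), so the control group's
geometric-mean relative expression is exactly 1. The group-level fold
change is 2^−(mean tumor ΔΔCt) — a geometric-mean-type summary, chosen
over the arithmetic mean of per-sample fold changes because it is the
exact inverse of the planted additive Ct shift (simulations recover a
planted K-fold change consistently); the alternative is a config choice
away. Reported fold changes use the signed convention: x ≥ 1 → x,
x < 1 → −1/x, so |FC| ≥ 1 always and down-regulation carries a minus
sign.

Group comparison: Shapiro-Wilk on each group's log-scale values at
α = 0.05; both normal → two-sided t-test, otherwise two-sided
Mann-Whitney U. Either group failing triggers the nonparametric branch
(the conservative reading). Significance requires p < 0.05 **and**
|FC| ≥ 2. Raw p-values drive the verdict, as is conventional for small
validated qPCR panels; Benjamini-Hochberg adjusted values are reported
alongside for transparency.

## Diagnostic panel

Features are per-sample log2 relative expression (−ΔΔCt) of the
significant miRNAs. The logistic fit is unpenalised maximum likelihood
(convex, hence deterministic); under perfect separation the MLE diverges,
and a lightly ridge-penalised fit is substituted and flagged in the
output rather than hidden. ROC thresholds sweep the unique fitted
probabilities; the trapezoidal AUC equals the concordance statistic
(verified exhaustively in tests). At the fixed cutoff (default 0.5,
boundary counted positive) the confusion matrix gives
sensitivity = 100·TP/(TP+FN) and specificity = 100·TN/(TN+FP).

The panel is fitted and evaluated **in-sample**, mirroring the
single-cohort design it reproduces; in-sample AUC and accuracy are
optimistic, and no cross-validation is attempted.

## Synthetic data: what it emulates, and what not

The Ct generator draws
Ct_{g,s,r} = b_g + a_s + β_g·1(tumor) + δ_run + η_{g,s} + ε_{g,s,r}
with exchangeable sample effects a_s ~ N(0, 0.25), per-gene biological
scatter η ~ N(0, gene-specific SD), run offsets δ ~ N(0, 0.5) (round-robin
run assignment), and triplicate noise ε ~ N(0, 0.2 cycles). Values beyond
the 40-cycle detection limit become undetected; listed dropout genes are
forced undetected in at least one sample. The calibrator pool per run is
the gene baseline plus the run offset. The count generator draws NB counts
with mean base_mean/10⁶ · 2^(lfc·tumor) · library size and dispersion α
(Var = μ + αμ²); planted |log2FC| ≥ 1 counts as true DE in the truth
table, smaller shifts model biological drift. Mock DE tables flag true DE
with a stated per-method sensitivity and non-DE with 1 − specificity.

The default study scenario emulates a cervical-cancer FFPE cohort: 66
tumor / 30 control samples, triplicates on 3 runs, 8 control candidates
(two planted stable at 0.15-cycle scatter and zero group effect; the rest
at 0.35–0.8 cycles with group drifts of ±0.3–1.2 cycles in *both*
directions, as imperfect "recommended" controls show; three forced
dropouts), and 5 targets with 1.5-cycle biological scatter, three of them
carrying planted fold changes of 4.145, 4.778 and 1/11.144. The
sequencing layer has 2730 isoforms, 2523 silent, 8 planted DE miRNAs (3
below the base-mean floor), candidates highly expressed with near-zero
fold change, and 6+6 libraries of 2 million reads at dispersion 0.05.

Not emulated: amplification-efficiency differences between assays,
primer-specific biases, FASTQ-level read structure and sequencing error,
isomiR collapsing, batch structure beyond additive run offsets, and
non-Gaussian biological scatter. Passing planted-truth tests therefore
demonstrates that the *algorithms* recover structure under the stated
additive/NB model — not that any particular real cohort satisfies that
model.

Problem sizes in the test and acceptance runs (100 seeds × 60-sample
cohorts for recovery rates, 2000 null simulations for test calibration,
one full 96-sample pipeline run) were chosen to make Monte-Carlo rates
stable to a couple of percentage points while keeping a full run in the
tens of seconds.

## Known limitations

* The CV criterion inherits the ambiguity of its field convention; both
  implemented modes are defensible and can disagree. The exclusion
  threshold (200%) is coarse by design.
* Aggregating overlapping combination candidates biases the pairwise-SD
  methods toward correlated combinations (see above).
* BestKeeper's regression p-values and geNorm's automatic panel-size
  decision are intentionally out of scope.
* The group-free NormFinder variant ranks by estimated per-gene SD only;
  it is a fallback when no grouping exists, not a substitute for the
  grouped analysis.
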