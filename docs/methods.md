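# Methods

## Study design and data model

The screen compares three *E. coli* strains — AW3110 (ΔarsRBC, no ArsR),
an *arsR*-complemented AW3110 (constitutive ArsR), and wild-type K-12 —
under control and arsenite stress. AW3110 and the complement tolerate
100 µM As(III), which is their "high" stress; K-12 additionally receives
1 mM, so its 100 µM condition is "low" stress. That yields seven groups
(AW control/high, complement control/high, K-12 control/low/high) in
triplicate, 21 samples. Stress level is a pure function of (strain,
dose) and the sample → group mapping lives only in the design table;
sample names are never parsed for metadata.

Intensities are raw label-free protein quantities with exactly 0 (or a
blank cell) meaning "not detected", the convention of MaxQuant/Scaffold
exports. ArsR protein is treated as present in four groups: both
complement groups and the two arsenite-treated K-12 groups. K-12 control
occasionally shows trace ArsR in single replicates at orders of magnitude
lower intensity; the package treats that as absence, and the group set is
a parameter for sensitivity analyses.

## Normalization

Order: impute → sum-normalize → log₁₀ → autoscale. The chain follows the
fixed normalization → transformation → scaling order of standard
metabolomics/proteomics preprocessing tools; the step list is
configurable for users who need a different order. Choices:

* **Imputation**: each 0 becomes ⅕ of the protein's minimum positive
  intensity across all samples — a conservative below-detection-limit
  value and the common default of MetaboAnalyst-style pipelines.
  Proteins never detected anywhere are dropped and reported. With
  imputation disabled, proteins containing zeros are dropped instead
  (log₁₀ 0 is undefined).
* **Sum normalization** removes loading/depth differences; it makes the
  pipeline invariant to scaling any sample column by a positive constant
  (asserted by test).
* **Autoscaling** uses the sample standard deviation (n−1). Constant
  rows have no defined scale and are dropped with a report entry (or
  raise, if configured). Constancy is detected on the values
  (max = min), not on a computed sd, which can be a nonzero rounding
  residue for exactly constant rows.

The non-detect mask is carried through so downstream stages can audit
which cells were imputed.

## Univariate statistics

One classical equal-variance one-way ANOVA per protein across all seven
groups, vectorized over proteins. Degenerate proteins are resolved by
convention instead of NaN: all observations identical → (F, p) = (0, 1);
zero within-group variance with separated means → (F, p) = (∞, 0).
Proteins lacking two groups with ≥ 2 observations are skipped with a
recorded reason but retained in the output. Benjamini–Hochberg
adjustment runs over tested proteins; both working thresholds (0.05,
0.001) are exposed as flags of the same test — the statistic cannot
differ between "two ANOVAs", only the cutoff does.

Tukey HSD uses the Tukey–Kramer statistic
q = |x̄_i − x̄_j| / √(MSW·(1/n_i + 1/n_j)/2) with p-values from the
studentized-range distribution on (k, N−k); it is validated against
scipy's independent implementation. Paired t-tests pair by replicate
index; since replicates are independent cultures with no natural pairing
unit, Welch is the recommended default and the paired mode exists to
reproduce the published choice. Group summaries use linear-interpolation
quartiles (the numpy default), matching standard boxplot conventions.

## Pattern classification

Comparisons use group means of autoscaled abundances. Autoscaling is a
per-protein affine map, so within-protein ordering of group means is
preserved from the (monotone) normalized scale, making the calls
scale-robust. The "K-12 low/high" clause of the arsenite branch is a
disjunction (either K-12 arsenite group exceeding the mutant suffices).
Strict inequality with zero margin is the default; an optional margin δ
(in autoscaled units) supports robustness analyses. The ANOVA
prerequisite defaults to the stringent q < 0.001 set, with 0.05
selectable.

Under exchangeable group means the rule alone fires with probability
11/18: the control branch requires the AW3110 control mean to be the
minimum of three iid means (1/3); the arsenite branch holds in 10 of the
24 orderings of four iid means (5/12); the branches use disjoint groups
and combine as 1 − (2/3)(7/12). This is verified by enumeration and
Monte Carlo in the tests, and quantifies why the rule is only meaningful
downstream of the ANOVA prefilter.

Screen output ordering is deterministic: branch (both, control,
arsenite), then descending minimum firing margin, then accession.

## PCA and clustering

Samples are observations, proteins variables. Protein columns are
centered across the selected samples before SVD — a no-op on the full
autoscaled matrix (already centered) but required for subsets such as the
K-12-excluded analysis. All components up to min(n_samples − 1,
n_proteins) are retained, so variance fractions sum to 1. Signs follow a
fixed convention (largest-magnitude loading positive), making results
deterministic and order-invariant.

K-means runs on the full score matrix by default (an option restricts it
to PC1/PC2), with k-means++ seeding, best of 10 restarts, and a fixed
seed. k defaults to 3, the cluster count reported for this design; a
silhouette scan over k = 2..6 is available as a diagnostic but drives no
decision automatically.

## Regulatory networks

Networks are built from a local curated snapshot CSV (RegulonDB/EcoCyc
style), never live queries, for reproducibility. A TF with both
activation and repression rows on the same target is collapsed to a
single dual edge, expanded into both halves at sign-split time; the
split therefore satisfies union = all edges, intersection = dual edges
exactly. Target-degree summaries count first-level (gene_level) edges
only and count each (TF, gene) pair once regardless of sign variants.
Gene-level edges onto genes outside the query list are retained but
flagged, since snapshots may be broader than a given screen. Reproducing
any published TF/gene counts depends on the snapshot's curation state;
the package ships no snapshot of record.

## Synthetic experiments

The generator emulates the 7 × 3 design with per-protein log-normal
baselines (log₁₀ mean 7, sd 1 — raw intensities spanning roughly
10⁴–10¹⁰, the heavy-tailed range typical of shotgun proteomics),
multiplicative planted effects applied to group means, mean-one
log-normal replicate noise with a configured CV (default 0.2, tight
technical-replicate-level variation), and non-detection applied last.

Planted classes: *arsr_dependent* (fold in the four ArsR-present
groups), *arsenite_responsive* (fold in the four arsenite-treated
groups), *inverse* (fold only in the AW3110 groups — a compensatory,
mutant-elevated profile that the screen must reject), and *null*.
Default folds are 4 / 3 / 3: large enough to be real biology, small
enough that noise and non-detection matter.

Non-detection defaults to **detection-limit censoring**: a logistic on
log₁₀ intensity whose midpoint is calibrated by bisection so the overall
zero fraction equals `dropout_rate` (default 5%), with slope 25 per
decade — the detection probability transitions across ~±0.1 decade,
narrow relative to planted folds, so non-detection is near-deterministic
at the limit while proteins whose noise straddles it still show the
sporadic single-replicate dropouts familiar from real data. An
intensity-blind uniform Bernoulli mode exists for stress-testing; note
that under uniform dropout, ⅕-minimum imputation turns every dropped
high-abundance cell into a gross outlier and per-protein power collapses
— a property of the imputation scheme worth knowing when applying the
pipeline to data with non-ignorable missingness.

What the generator does **not** emulate: peptide-level roll-up,
correlated protein co-regulation, batch effects, or abundance-dependent
CV. Passing recovery tests therefore demonstrates the pipeline's
correctness and calibration under idealized independence, not its field
performance on any particular instrument.

## Problem sizes and determinism

Calibration and recovery analyses use 2000-protein experiments (20
replicate experiments for the global-null FDR check, a 10,000-protein
Monte Carlo for the null rule rate); these sizes give standard errors
well inside the decision margins while keeping any run in seconds. All
randomness flows from explicit integer seeds; deterministic stages are
bit-reproducible from the run manifest (config hash + seeds + version).

## Known limitations

* The imputation/normalization choices materially affect how many
  proteins pass a stringent FDR cutoff; published counts from any
  specific dataset can only be reproduced with the same choices and the
  same export.
* The inclusion rule compares means without uncertainty; its error
  control is inherited entirely from the ANOVA prefilter.
* Tukey p-values assume equal within-group variances; with n = 3 per
  group this is untestable and taken on faith, as in the source
  workflow.
* K-means with fixed k = 3 partitions any geometry into three clusters;
  cluster membership is reported, not validated against a model.
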