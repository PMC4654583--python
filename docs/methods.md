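# Methods

## The two models

**Germline (SNP) model.** Let a *feature combination* be the bitmask of
binary genome features present at a position. The analyzed genome (all
non-coding, non-excluded bp) is partitioned into maximal runs of constant
bitmask; each distinct bitmask contributes one row with its aggregate size,
SNP count and rare-SNP count (rare: allele frequency < 0.01). Rows smaller
than `min_size` (default 10 kb) or without SNPs are excluded from fitting.
A random forest regresses `rare_ratio = n_rare/n_snp` on the 0/1 feature
indicators. Rows are weighted by `n_snp` by default — a ratio estimated
from 12 SNPs is binomially far noisier than one from 12,000; unweighted
fitting is available (`weighted=False`). Predictions are clamped to [0, 1].
The SNP score of a position is a pure function of its bitmask.

**Somatic (SOM) model.** The response is the pooled somatic mutation count
per retained non-overlapping 1 Mb window; windows overlapping excluded
regions and trailing partial windows are dropped. Predictors are feature
coverage in bp (binary tracks) or length-weighted window means (value
tracks, with zero-coverage windows imputed at the track's genome-wide
mean), all transformed `x → ln(x+1)` (natural log; configurable). One model
is fitted per cancer label; no cross-cancer pooling. Genome-wide scoring
slides the window at 1 kb offsets (windows never extend past a chromosome
end; a sliding window is valid under the same exclusion rules as training),
predicts each valid window, and averages all valid covering windows onto
1 kb bins; bins covered by no valid window are missing. Per-patient
normalization (divide by patient count) is applied at reporting time only —
the fitted response stays a pooled count.

**Feature selection** (both models) is a two-phase procedure standing in
for heavier wrapper-selection algorithms: (1) the design matrix is
augmented with shuffled decoy copies of real columns; over repeated forests
(default 5), features whose mean permutation importance does not exceed the
largest mean decoy importance are discarded; (2) survivors are ranked by
importance and nested head subsets refitted; the smallest subset whose
out-of-bag weighted MSE is within one standard error of the best is kept.
Reported importances of the final fit are node-purity decreases
(scikit-learn's mean decrease in impurity).

**Dual classification.** The SNP cutoff is the score at the target-area
rank of the scored bins (default target: fraction 100/3100 of the scored
area, the 100 Mb of a ~3100 Mb analyzed human genome, so the rule scales to
miniature genomes; absolute targets can be passed). The SOM cutoff is the
value at which the area with `snp ≥ snp_cutoff AND som ≤ c` reaches the
hypomutated target (56/3100). Labels: *hypomutated* (`snp ≥`, `som ≤`),
*hypermutated* (`snp ≥`, `som >`), *other* (`snp <`), *unscored* (either
channel missing). Ties at a cutoff are always included on the selected
side, so the realized area can overshoot the target by one tie-group; this
is deterministic and order-independent, and the overshoot is logged. All
other thresholds in the package (GC > 0.50 / < 0.30, recombination rate
> 4.0 / < 0.5, methylation > 0.7245 / < 0.4062, RPKM > 20 / < 0.25, E/L
ratio > 1 / < 1 in *every* cell line) are strict inequalities: a value
exactly at a threshold falls in no class.

**Enrichment.** `OR = (Hf/Sf)/(Hg/Sg)` where Hf/Hg are labelled bp in the
feature/genome and Sf/Sg the feature/analyzed-genome sizes, all measured at
1 kb bin resolution within the scored area (the convention under which a
partition of the genome has area-weighted mean OR exactly 1). Significance
is non-parametric: an equal-sized region set is placed at random n_perm
times (default 1000) and the min–max of the permuted ORs forms the
envelope; only observed values strictly outside are significant — no
parametric p-value is attached. Default placement resamples contiguous
segments matching the labelled region's run-length distribution, preserving
spatial autocorrelation; a uniform-bin mode (`mode="bp"`) implements the
literal "random positions" reading but is anti-conservative for clustered
features.

## The synthetic world

The generator emulates the statistical structure the analysis assumes, not
sequence realism:

* **Tracks** are drawn by an alternating renewal process with geometric
  segment and gap lengths, hitting a requested coverage fraction in
  expectation (realized coverage fluctuates; for Mb-scale domains on small
  genomes the fluctuation is large by construction).
* **Germline SNPs**: positions Poisson-uniform at `snp_density`; each SNP
  is rare with probability `expit(logit(baseline) + Σ rare_effect[f])` over
  the features present. Allele frequencies are drawn uniform on (0, 0.01)
  for rare and [0.01, 0.5] otherwise — only the rare/common dichotomy
  matters downstream. No linkage disequilibrium, no diploid genotypes.
* **Somatic mutations**: a Poisson point process with piecewise-constant
  rate `baseline/Mb × Π multipliers × n_patients`; patient labels are
  assigned uniformly afterwards (an exact thinning of iid per-patient
  processes). Point events only — indel lengths and trinucleotide
  signatures are not modelled.
* **Disease variants**: sampling weight `bias^k` where k is the number of
  designated constrained features present. The multiplicative rule makes a
  conserved element inside a somatically protected domain the most
  enriched location — the joint structure the dual model exists to detect;
  with a single constrained feature it reduces to the simple
  inside/outside weighting (fraction inside = `b·c/(b·c + 1 − c)`).

Stage-specific substreams are spawned from one seed with fixed keys, so any
stage regenerates identically in isolation. All coordinates are 0-based
half-open (BED convention) everywhere, including the minimal variant TSV;
the VCF reader converts from 1-based on ingestion and projects to
CHROM/POS/AF only.

**What a green test establishes.** Parameter-recovery tests show the
pipeline recovers *planted* logit-additive rare-SNP effects and
multiplicative somatic rates from realistic event counts; they do not show
that real mutation rates follow those functional forms, and the synthetic
feature tracks are independent of each other whereas real annotation tracks
are strongly correlated.

Defaults mirror the real-data regime where one exists
(rare threshold 0.01; 10 kb combination filter; 1 Mb windows at 1 kb step;
100 Mb/56 Mb area fractions; patient counts of tens; aggregate somatic
densities of 20–600 mutations/Mb pooled vs >12,000 SNPs/Mb). Where they do
not, the demo world chooses values a genomicist would call realistic:
conserved-element coverage of a few percent with kb-scale segments,
replication-timing-like domains of several Mb (somatic covariates act at
domain scale — features much shorter than the 1 Mb window are invisible to
the SOM model by construction), and a 40–120 Mb genome, the smallest scale
at which the Mb-domain mosaic is statistically stable.

## Numerical and design choices

* **Interval core**: sorted merged interval arrays with prefix sums;
  coverage and weighted-mean queries are O(log n) per window and are tested
  against per-bp brute-force oracles. Binary tracks union-merge overlapping
  intervals on construction; value tracks reject overlaps (a length-weighted
  mean over self-overlap is undefined).
* **Weighted OOB R² of the SNP model can be strongly negative** even when
  the model ranks combinations well: most of the weight sits on the
  background combination, whose value cannot be predicted when it is out of
  bag. `crossval_correlation` (10-fold CV over combinations, weighted
  Pearson r between held-out predictions and observed ratios) is the
  calibration metric to quote.
* **Forest defaults**: 500 trees, ⌈K/3⌉ candidate features per split
  (regression convention), fixed `random_state`; refitting with the same
  seed is bit-identical, and combination rows are sorted canonically before
  fitting so predictions are invariant to input row order.
* **χ² quadrant test**: one-degree-of-freedom goodness-of-fit of
  disease-variant membership in the high-SNP ∩ low-SOM intersection against
  the area-fraction expectation, without continuity correction (large-sample
  genome-area test). With zero disease variants the densities are still
  reported and the test is skipped with a warning.
* **Degenerate inputs**: uniform scores make the cutoff all-or-nothing
  (warned); an all-tied rank-sum comparison reports p = 1; a high-SNP area
  smaller than the hypomutated target raises an error naming the
  inconsistent targets; chromosomes shorter than one window contribute no
  windows (warned).

## Known limitations

* The SOM model cannot see constraint at scales below its 1 Mb window; the
  1 kb SOM score is a smoothed field, not a local rate.
* Scores on synthetic worlds are piecewise constant with large tie groups
  (tens of combinations vs ~44k on the real genome), which is why tie
  handling at cutoffs is spelled out and logged.
* Feature selection is a documented lightweight procedure, not a
  re-implementation of any particular wrapper algorithm; with strongly correlated features it
  may keep either member of a duplicated pair.
* The permutation envelope is a min–max band: its implied per-feature error
  rate is ~2/(n_perm+1) per tail, so reduced n_perm widens nothing but
  makes the band's extremes noisier.
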