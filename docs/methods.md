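# Methods

This note documents the statistical procedures implemented in `vagmet`,
the design choices made where a procedure admits more than one
reasonable reading, the synthetic-cohort generator that the test suite
exercises the pipeline on, and the limits of what those tests show.

## Preprocessing

Raw untargeted LC-MS/MS measurements are per-sample, per-metabolite peak
areas; a missing cell means the metabolite was not detected in that
sample (left censoring at the platform's detection limit), never that it
was measured as zero. The pipeline is:

1. **Volume normalization** — divide each sample's observed values by its
   extraction-buffer volume (a positive per-sample scalar).
2. **log₁₀ transform** of observed values.
3. **Robust standardization** per metabolite — subtract the median of
   observed values and divide by a dispersion estimated after discarding
   the top and bottom 5% order statistics. "Clipping the top and bottom
   5%" is implemented as *trimming* (excluding ⌈0.05·n⌉ values per tail
   from the SD computation, n−1 denominator on the retained values); a
   winsorized variant is available behind the `winsorize` flag. Constant
   features (zero trimmed dispersion) are excluded with a recorded
   reason, never silently zeroed.

Standardization statistics use observed values only. Where a complete
matrix is required (distance computation for clustering; prediction
features), missing cells are filled with the per-feature minimum
observed value — the natural surrogate under left censoring. Correlation
analyses never impute. Detection summaries ("detected in over half" is
strict, > 0.5; "detected in all" means zero masked cells) depend only on
the missingness mask and are therefore invariant to any monotone
transform of the values. Because it can be ambiguous whether such
summaries should be counted over all spectral features or only the named
(identified) ones, both denominators are reported.

No batch-effect correction is applied (batch is carried as metadata
only).

## Distances, PERMANOVA, clustering

Metabolome distances use **Canberra** (Σᵢ |xᵢ−yᵢ| / (|xᵢ|+|yᵢ|), 0/0
terms contributing 0 — outlier-robust and sensitive to shared small
features), microbiome distances **Bray–Curtis**. PERMANOVA uses the
pseudo-F from the squared-distance decomposition with label-permutation
p-values, p = (1 + #{F* ≥ F}) / (1 + B); an exhaustive mode enumerates
every labelling for small n, and the permutation floor guarantees p > 0.
The implementation is cross-checked in tests against scikit-bio's
pseudo-F. Mantel tests delegate to scikit-bio (Spearman, permutation p).

**k-medoids** runs on the precomputed distance matrix: k-medoids++-style
seeding, Voronoi alternation, then a greedy PAM swap phase (replace one
medoid with one non-medoid while the total within-cluster distance
improves), best of `n_init` seeded restarts. The swap phase matters: on
planted-block data, alternation alone frequently stalls in merged/split
local optima. The within-dispersion W_k is the sum of squared distances
to assigned medoids.

**Gap statistic**: for each k in the scanned range, Gap(k) =
mean_b log W_k(ref_b) − log W_k(data) over B reference datasets drawn
uniformly over each feature's observed range and clustered by the same
procedure (warm-started from the previous k's medoids so W_k is
non-increasing). The headline k is the smallest k with
Gap(k) ≥ Gap(k+1) − s_{k+1} (one-SE rule, s_k = sd_b·√(1+1/B)); the
argmax of Gap is also reported, since combining an SSE elbow with the
gap curve admits several conventions and no single rule is privileged.

**Cluster robustness**: re-fit at the reference k on `n_subsamples`
random draws of round(fraction·n) samples without replacement; score
each refit against the reference assignment restricted to the subsample
with a maximum-overlap one-to-one label matching (Hungarian method on
the contingency table; surplus labels count as mismatches); report the
mean matched-assignment accuracy and the number of subsamples above
95%. The reference k is held fixed across subsamples (a flag could
re-select k per subsample; fixed k is the more conservative reading of
"recreating clusters de novo with the same procedure"). Each subsample
uses a dedicated seeded stream, so reports are bit-reproducible.

## Association scans

Per-metabolite two-sided Mann–Whitney U tests between outcome groups,
computed on observed values only. Metabolites detected in less than half
of the analyzed stratum are excluded before testing (the prevalence
filter is interpreted within-stratum, since each stratified scan stands
alone; a global variant is configurable). The test uses a tie-corrected
normal approximation with continuity correction, switching to exact
enumeration when n_case·n_ctrl ≤ 400 and the values are tie-free; the
two branches agree to |Δp| < 0.01 at the boundary. BH-FDR is applied
across tested features within each stratum scan. Early-PTB outcome
definitions (GAB < 32, GAB < 28) are intended for the Black-women
stratum (their high proportion among those deliveries); the comparison
group is all other pregnancies in the stratum by default, with a
term-only-controls option, since either contrast is defensible.
Features are ranked across strata by the mean signed −log₁₀ p
(direction = sign of the case-minus-control median difference).

Internally the scan is a vectorized rank-sum scanner that precomputes
per-feature midranks and tie corrections once and re-scores arbitrary
case/control splits in O(n·F). This makes permutation procedures cheap
and — more importantly — guarantees that permuted labels pass through
*exactly* the code path used for the observed labels.

## Metabolite-set enrichment

For each functional set (Metabolon super-pathway, sub-pathway, KEGG
pathway; ≥ 2 members with data, and never all tested features), the
observed statistic is a second-level Mann–Whitney p comparing in-set
per-feature association p-values against out-of-set ones. The default
sidedness is one-sided (in-set p stochastically smaller), because
"enriched for associations" is directional; a two-sided flag exists.
The null distribution re-runs the full per-feature scan under random
permutations of the outcome labels (default 10,000) and recomputes the
second-level p each time; perm_p = (1 + #{null ≤ observed}) / (1 + N).
Three structural decisions:

- the prevalence filter is applied once on the observed stratum and held
  fixed across permutations (label shuffles do not change detection
  masks, and the feature universe must not drift under the null);
- one seeded stream per stratum supplies the same null label draws to
  every set, keeping across-set results comparable;
- per-permutation per-feature p-values are computed once and reused by
  all sets, so the cost is O(N·F + sets·N).

FDR is computed separately within each set type.

## Microbe–metabolite network

Absolute abundances are relative abundances × per-sample total 16S copy
number; samples without a load measurement are excluded here (no
imputation in the network context). Spearman ρ is computed on
pairwise-complete observations: a missing metabolite value drops the
pair, while a zero taxon abundance is data (observed absence). Pairs
with fewer complete observations than the pairing threshold are recorded
as uncomputed, as are constant vectors. The threshold is
⌈fraction·n_cohort⌉ with fraction = 0.22 by default; because a 22%
fraction of 232 samples gives 52 while the explicit companion integer is
50, the exact integer is also settable and neither rule is silently
preferred. Edges are kept at BH-FDR < 0.1 and |ρ| > 0.25. Spearman
p-values use the t-approximation with midrank ties (exact enumeration
only for n ≤ 7, where it is feasible). Subgroup correlations are
compared with the Fisher r-to-z statistic using the classical 1/(n−3)
variance (the 1.06/(n−3) rank-correlation variant is behind a flag), and
feature groups are contrasted on their |ρ| distributions with a
two-sided Mann–Whitney test. Compositional-correlation corrections
(SparCC-style) are deliberately out of scope: the analysis operates on
load-scaled abundances.

## Prediction framework

Outer evaluation uses 10-fold cross-validation block-stratified on
deciles of gestational age at birth (computed on the full cohort —
outcome-adjacent information used for stratification only, never as a
feature) and, for microbiome/metabolome/combined models, on race;
members of each (decile × race) stratum are shuffled and dealt
round-robin across folds; 5 independent repeats come from seed
substreams. Composite models train a separate pipeline per race stratum
({Black, non-Black}; "Other" joins non-Black), and a sample is always
scored by its own stratum's model — pooled out-of-fold scores equal the
concatenation of per-stratum scores exactly.

Hyperparameters (feature-pipeline switches plus LightGBM parameters) are
drawn from a declared search space; candidates are evaluated on inner
folds of the outer training set, ranked by mean inner **R²** — read as
the coefficient of determination of the predicted probability against
the 0/1 outcome, 1 − Σ(y−p̂)²/Σ(y−ȳ)², since "R² for classification" is
not otherwise pinned down (a squared-Pearson alternative is a one-line
swap) — and the best mean inner auROC among the top five wins, ties to
the earlier draw. The feature pipeline (median/SD standardization →
training-minimum imputation → optional PCA → selection by sparsity,
importance, information gain or rank correlation) fits on training data
only; missing qPCR loads in microbiome features take the training-mean
load. Held-out scores are computed once; evaluation against
reclassified outcomes (GAB < 32 / GAB < 28) changes only the labels.
auROC differences use Hanley–McNeil standard errors and a two-sided
normal p. The final model refits each outer-fold-selected candidate on
the whole cohort and keeps the best *training-fit* auROC, with the
selection table explicitly flagging that metric as a training fit, not
a generalization estimate. External cohorts are scored without
retraining: overlapping features are mapped by identifier and
standardized with training statistics; absent features take the training
post-standardization median (zero under exact median centering), a
neutral fill under the standardization contract. Attributions use the
boosted-tree learner's native TreeSHAP (additive contributions plus
baseline equal the raw-margin output).

The learner sits behind a narrow fit/predict-proba contract; a
deterministic linear stub exercises the framework in tests without
boosting costs, and LightGBM is the default.

## Synthetic cohorts

The generator emulates the data structure the analyses assume, with
defaults at study scale: 232 samples, 80 cases, race mix ≈ 71% Black /
25% White / 4% Other, 60 taxa, 300 metabolite features (270 named, 30
unnamed). Components:

- **Taxa**: each sample draws a CST from (I, II, III, IV-A, IV-B) with
  probabilities (0.25, 0.07, 0.33, 0.20, 0.15); Lactobacillus-like CSTs
  use a Dirichlet profile with one strongly dominant taxon, CST-IV
  variants a diverse anaerobe profile — giving the characteristic
  heavily skewed compositions. Total loads are log-normal
  (ln-mean 15 ≈ 3×10⁶ copies, ln-sd 1.2).
- **Outcomes**: PTB history ~ Bernoulli(0.25); exactly 80 cases are
  drawn with logistic dependence on history (odds ratio 3, matching the
  observed history–sPTB association) via the Gumbel top-k device, which
  keeps the case count fixed. Gestational age at birth is uniform 38–41
  weeks for controls and triangular(21, 35, 36.9) for cases, giving a
  tail below 32 and 28 weeks for the early-PTB strata.
- **Metabolome** (log₁₀ scale, per-feature noise SD 1): six planted
  sample-cluster blocks of 30 features shifted by 3 SD; 10 case-shifted
  effect features (+0.8 SD in cases), of which 5 are taxa-independent
  "xenobiotic-like" and 5 also carry taxon couplings; 15 monotone
  taxon couplings with target correlations 0.6–0.9 (a coupling of
  strength s adds s/√(1−s²) × standardized log-load of its taxon);
  one planted enriched sub-pathway of 15 members shifted +0.8 SD.
  Raw values are 10^(log values).
- **Missingness** is purely left-censored: 60% of non-planted features
  get a detection-threshold quantile drawn uniform(0, 0.7), and a value
  is missing iff it falls below that feature-specific threshold.
  Planted-structure features stay fully detected so recovery tests have
  unambiguous truth.
- An **external cohort** variant subsamples the feature universe to a
  requested overlap and applies a global location/scale batch shift.

Everything planted is serialized in a truth record. What the generator
does *not* emulate: mass-spectral peak artifacts, batch effects beyond a
global offset, sequencing error, realistic phylogenies, missingness that
is not left-censored, and the long-tailed metabolite-class correlation
structure of real vaginal samples. Tests passing on these cohorts show
that the procedures recover the structure they target under their own
assumptions — not that those assumptions hold in any particular real
cohort; in particular the real-data prediction accuracies reported in
the literature are not reproduced here, as they require controlled-access
metadata and search budgets outside a test suite's scope.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale budgets chosen as package
defaults: gap scans over k = 1..10 with B = 15 uniform references and 3
restarts (B = 50 and k ≤ 15 are the library defaults); enrichment at
1,000 permutations (10,000 is the library default); nested CV at 12
candidates from a reduced search space, 10×2 outer and 5×1 inner folds
(the full framework is 1,000 candidates, 10×5 outer, 5×5 inner, all
config-reachable). Robustness uses the full 100 × 90% design.

Numerical conventions worth noting: permutation p-values always carry
the +1 floor and can never be 0; Canberra 0/0 coordinates contribute 0;
Mann–Whitney continuity correction is applied toward the mean; BH q
values are step-up within the declared grouping; k-medoids cluster
labels are canonicalized by first occurrence in sample order so
assignments are deterministic given a seed; all stochastic procedures
take explicit seeds, and multi-stage drivers derive per-stage seeds from
a master seed by stage name so adding a stage never perturbs another's
stream.

## Known limitations

- The k-medoids swap phase is greedy (one swap per sweep), not an
  exhaustive PAM BUILD; with `n_init` restarts this is empirically
  stable on separated data but carries no optimality guarantee.
- The gap statistic's uniform reference favours compact spherical-ish
  clusters; on strongly non-convex structure the one-SE rule can
  under-select k.
- The second-level enrichment statistic treats per-feature p-values as
  exchangeable between in-set and out-of-set groups; strong inter-set
  overlap (a feature in many KEGG pathways) induces dependence that the
  within-type FDR does not model.
- Fisher r-to-z on Spearman correlations with the 1/(n−3) variance is
  slightly anticonservative; the 1.06 variance flag exists for
  sensitivity analyses.
- External application fills absent features with a neutral constant;
  when the missing features carry most of the signal, scores degrade
  gracefully but cannot be debiased.
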