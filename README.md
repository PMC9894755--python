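# vagmet

Analysis toolkit for paired vaginal **metabolome–microbiome** studies of
**spontaneous preterm birth (sPTB)** — delivery before 37 weeks of
gestation not medically induced. It is aimed at researchers working with
untargeted LC-MS/MS vaginal metabolomics (samples × metabolite area
counts with left-censored non-detections) alongside 16S
relative-abundance profiles with qPCR total bacterial load, and per-sample
clinical metadata (outcome, gestational age at birth, self-identified
race, covariates).

The package implements, as tested reusable components:

- **Preprocessing** — volume normalization, log₁₀ transform, and robust
  standardization per metabolite: x ↦ (x − median(x)) / sd₀.₀₅(x), where
  sd₀.₀₅ trims the top and bottom 5% order statistics; detection
  summaries; per-feature minimum imputation for left-censored
  non-detections.
- **Global structure** — Canberra (metabolome) and Bray–Curtis
  (microbiome) distances; PERMANOVA (pseudo-F with permutation or
  exhaustive p); Mantel tests; PAM k-medoids clustering of metabolite
  profiles into "metabolite clusters" (MCs) with gap-statistic selection
  of k (1–15) and a 100 × 90%-subsample robustness procedure scoring
  matched-assignment accuracy via Hungarian label matching; Fisher-exact
  contingency scans among MCs, community state types (CSTs), race and
  outcome.
- **Association scans** — per-metabolite two-sided Mann–Whitney U tests
  of sPTB vs term, stratified (all / Black / White / no-progesterone /
  GAB<32 / GAB<28), restricted to metabolites detected in ≥ half of the
  stratum, with Benjamini–Hochberg FDR within each scan.
- **Metabolite-set enrichment** — a permutation test: the observed
  statistic is a second-level Mann–Whitney p comparing the per-metabolite
  association p-values inside a functional set (super-pathway,
  sub-pathway or KEGG pathway) with those outside it; its null is built
  by recomputing the full scan on (by default) 10,000 random shuffles of
  the outcome labels, so perm_p = (1 + #{null ≤ observed}) / (1 + N).
- **Microbe–metabolite network** — Spearman correlations between
  estimated absolute abundances (relative abundance × 16S copy number)
  and metabolite levels, pairwise-complete with no imputation, with a
  minimum paired-measurement threshold, FDR < 0.1 and |ρ| > 0.25 edge
  filters, Fisher r-to-z subgroup comparisons, and a Mann–Whitney
  contrast of |ρ| between feature groups (e.g. xenobiotics vs the rest).
- **Prediction** — a race-composite (Black / non-Black) nested
  cross-validation framework: 10 outer folds × 5 repeats block-stratified
  on gestational-age deciles (× race), inner 5-fold tuning of randomized
  hyperparameters for a standardize → impute → optional-PCA →
  feature-selection → LightGBM pipeline, selection by best mean inner
  auROC among the top five candidates by mean inner R², Hanley–McNeil
  auROC comparisons, reclassified-outcome evaluation (GAB<32 / GAB<28),
  training-fit final-model selection, external-cohort application under
  partial feature overlap, and TreeSHAP feature attributions.
- **Synthetic cohorts** — a generator producing paired tables with the
  structure above (CST-driven Dirichlet compositions, log-normal loads,
  clustered metabolome blocks, planted case shifts, planted
  taxon–metabolite couplings, taxa-independent xenobiotic-like features,
  planted enriched sets, left-censored missingness), with a serialized
  truth record, so every stage is testable without any data download.

## Worked example

```python
from vagmet.simulate import SimulationConfig, generate_cohort
from vagmet.preprocess import log10_transform, robust_standardize, min_impute
from vagmet.structure import compute_distance, select_k_gap, kmedoids_fit
from vagmet.associations import association_scan

matrix, taxa, metadata, annotations, truth = generate_cohort(SimulationConfig(seed=1))
std, _ = robust_standardize(log10_transform(matrix))
complete, _ = min_impute(std)
D = compute_distance(complete, "canberra")
gap = select_k_gap(complete, D, k_range=range(1, 11), B=15, seed=1, n_init=3)
print("gap-selected k:", gap.chosen_k)

records, _ = association_scan(matrix, metadata)
hits = sorted((r.q, r.feature_id) for r in records if r.q < 0.1)[:3]
for q, fid in hits:
    print(f"{fid}  q={q:.2e}")
```

prints

```
gap-selected k: 6
M0213  q=2.46e-10
M0205  q=4.79e-10
M0214  q=1.54e-07
```

— the gap statistic recovers the six planted metabolite clusters, and
the most significant associations are planted case-shifted metabolites
(here members of the planted enriched sub-pathway; `truth.effects` and
`truth.enriched_sets` list every planted feature).

The same stages are scriptable from the shell via the `vagmet` CLI
(`vagmet simulate`, `vagmet preprocess`, `vagmet cluster`,
`vagmet associate`, `vagmet enrich`, `vagmet network`, `vagmet predict`,
`vagmet run --config run.json`).

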