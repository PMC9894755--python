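"""Synthetic paired microbiome-metabolome-metadata cohorts.

The generator emulates the statistical structure the analyses assume:

* a two-group outcome (80 spontaneous preterm / 152 term by default) with
  a majority-Black race mix and a PTB-history effect on risk;
* CST-structured taxa compositions (Lactobacillus-dominated CSTs drawn
  from Dirichlet profiles with one dominant taxon; a diverse CST-IV-like
  profile) with log-normal 16S total loads;
* a metabolome on the log10 scale with planted sample-cluster block
  structure, planted case shifts (including taxa-independent
  "xenobiotic-like" features), planted monotone taxon-metabolite
  couplings, and annotation-defined metabolite sets with planted
  enrichment;
* purely left-censored missingness: a value is missing iff it falls
  below its feature's detection-threshold quantile.

Every planted effect is serialized in a truth record so recovery tests
are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import (
    CohortMetadata,
    MetaboliteAnnotation,
    MetaboliteMatrix,
    TaxaTable,
)

__all__ = ["SimulationConfig", "CohortTruth", "generate_cohort", "generate_external_cohort"]

SUPER_PATHWAYS = (
    "Amino Acid",
    "Lipid",
    "Nucleotide",
    "Carbohydrate",
    "Peptide",
    "Cofactors and Vitamins",
    "Energy",
    "Xenobiotics",
)


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults mirror the cohort the
    analyses were designed around (232 samples, 80 cases, ~71% Black)."""

    n_samples: int = 232
    n_cases: int = 80
    race_probs: tuple[float, ...] = (0.71, 0.25, 0.04)  # Black, White, Other
    n_taxa: int = 60
    n_named: int = 270
    n_unnamed: int = 30
    n_clusters: int = 6
    cluster_block_size: int = 30
    cluster_separation: float = 3.0  # log10 SD units between block centroids
    cst_probs: tuple[float, ...] = (0.25, 0.07, 0.33, 0.20, 0.15)  # I,II,III,IV-A,IV-B
    load_log_mean: float = 15.0  # ln copies
    load_log_sd: float = 1.2
    missing_fraction_features: float = 0.6  # share of features with censoring
    missing_quantile_max: float = 0.7
    n_effects: int = 10  # case-shifted metabolites ("all" stratum)
    effect_shift_sd: float = 0.8
    n_xenobiotics: int = 5  # of the effects: taxa-independent features
    n_couplings: int = 15
    coupling_strengths: tuple[float, float] = (0.6, 0.9)
    enriched_set_size: int = 15
    enriched_set_shift_sd: float = 0.8
    plant_enriched_set: bool = True
    plant_effects: bool = True
    plant_couplings: bool = True
    ptb_history_prob: float = 0.25
    ptb_history_or: float = 3.0
    progesterone_prob: float = 0.056
    n_batches: int = 2
    batch_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases >= self.n_samples:
            raise ValueError("n_cases must be below n_samples")
        n_feat = self.n_named + self.n_unnamed
        reserved = self.n_clusters * self.cluster_block_size
        planted = self.n_effects + self.n_couplings + self.enriched_set_size
        if reserved + planted > n_feat:
            raise ValueError("more planted features than features available")
        if self.n_xenobiotics > self.n_effects:
            raise ValueError("xenobiotics are a subset of the planted effects")


@dataclass
class CohortTruth:
    """Ground truth of everything the generator planted."""

    cluster_assignment: dict[str, int]
    cst_assignment: dict[str, str]
    effects: list[dict]  # feature_id, stratum, shift_sd
    xenobiotic_features: list[str]
    couplings: list[dict]  # taxon_id, feature_id, strength
    enriched_sets: list[dict]  # set_id, set_type, members, shift_sd
    seed: int


def _dirichlet_profiles(n_taxa: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-CST Dirichlet concentration vectors: one dominant Lactobacillus
    taxon for CSTs I-III, diverse anaerobes for the CST-IV variants."""
    profiles = {}
    for i, cst in enumerate(("I", "II", "III")):
        alpha = np.full(n_taxa, 0.02)
        alpha[i] = 25.0  # taxa 0..2 play L. crispatus / gasseri / iners
        profiles[cst] = alpha
    for j, cst in enumerate(("IV-A", "IV-B")):
        alpha = np.full(n_taxa, 0.02)
        anaerobes = np.arange(5 + 10 * j, 5 + 10 * j + 18)
        alpha[anaerobes % n_taxa] = 1.0
        profiles[cst] = alpha
    return profiles


def _assign_outcomes(
    cfg: SimulationConfig, history: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exactly n_cases cases, drawn with logistic dependence on PTB
    history (Gumbel top-k trick keeps the count fixed)."""
    logit = np.log(cfg.ptb_history_or) * history.astype(float)
    gumbel = rng.gumbel(size=cfg.n_samples)
    order = np.argsort(-(logit + gumbel))
    case = np.zeros(cfg.n_samples, dtype=bool)
    case[order[: cfg.n_cases]] = True
    return case


def generate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[MetaboliteMatrix, TaxaTable, CohortMetadata, MetaboliteAnnotation, CohortTruth]:
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n, n_feat = cfg.n_samples, cfg.n_named + cfg.n_unnamed
    sample_ids = [f"S{i:04d}" for i in range(n)]
    feature_ids = [f"M{j:04d}" for j in range(n_feat)]
    taxon_ids = ["Lactobacillus_crispatus", "Lactobacillus_gasseri", "Lactobacillus_iners"] + [
        f"Taxon_{t:03d}" for t in range(3, cfg.n_taxa)
    ]

    # --- metadata ------------------------------------------------------
    race = rng.choice(["Black", "White", "Other"], size=n, p=cfg.race_probs)
    history = rng.random(n) < cfg.ptb_history_prob
    case = _assign_outcomes(cfg, history, rng)
    gab = np.where(
        case,
        rng.triangular(21.0, 35.0, 36.9, size=n),
        rng.uniform(38.0, 41.0, size=n),
    )
    meta = pd.DataFrame(
        {
            "outcome": np.where(case, "sPTB", "TB"),
            "gab_weeks": np.round(gab, 2),
            "race": race,
            "age_years": np.round(rng.normal(29, 6, size=n), 1),
            "bmi": np.round(rng.normal(30, 7, size=n).clip(16, 60), 1),
            "nulliparous": rng.random(n) < 0.36,
            "ptb_history": history,
            "progesterone": rng.random(n) < cfg.progesterone_prob,
            "batch": rng.choice([f"B{b}" for b in range(cfg.n_batches)], size=n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- taxa ----------------------------------------------------------
    cst_names = ("I", "II", "III", "IV-A", "IV-B")
    cst = rng.choice(cst_names, size=n, p=cfg.cst_probs)
    profiles = _dirichlet_profiles(cfg.n_taxa, rng)
    rel = np.vstack([rng.dirichlet(profiles[c]) for c in cst])
    rel = rel / rel.sum(axis=1, keepdims=True)
    load = np.exp(rng.normal(cfg.load_log_mean, cfg.load_log_sd, size=n))
    meta["cst"] = cst
    taxa = TaxaTable(sample_ids, taxon_ids, rel, load)
    absolute = rel * load[:, None]

    # --- metabolome on the log10 scale ---------------------------------
    base = rng.normal(5.0, 1.0, size=n_feat)  # feature baselines (raw ~1e5)
    log_vals = base[None, :] + rng.normal(0.0, 1.0, size=(n, n_feat))

    # planted sample-cluster block structure on the first k*block features
    clusters = rng.integers(cfg.n_clusters, size=n)
    for c in range(cfg.n_clusters):
        block = np.arange(c * cfg.cluster_block_size, (c + 1) * cfg.cluster_block_size)
        log_vals[np.ix_(clusters == c, block)] += cfg.cluster_separation

    next_free = cfg.n_clusters * cfg.cluster_block_size

    # planted case shifts; the first n_xenobiotics stay taxa-independent
    effect_idx = np.arange(next_free, next_free + cfg.n_effects)
    next_free += cfg.n_effects
    effects: list[dict] = []
    xeno_ids: list[str] = []
    if cfg.plant_effects:
        for i, j in enumerate(effect_idx):
            log_vals[case, j] += cfg.effect_shift_sd
            effects.append(
                {"feature_id": feature_ids[j], "stratum": "all", "shift_sd": cfg.effect_shift_sd}
            )
            if i < cfg.n_xenobiotics:
                xeno_ids.append(feature_ids[j])

    # planted monotone taxon couplings; effect features beyond the
    # xenobiotics receive the first couplings so the network has
    # sPTB-associated, microbe-coupled metabolites
    couplings: list[dict] = []
    if cfg.plant_couplings:
        coupled_effect = effect_idx[cfg.n_xenobiotics :]
        extra = np.arange(next_free, next_free + cfg.n_couplings - len(coupled_effect))
        next_free += len(extra)
        coupled_idx = np.concatenate([coupled_effect, extra])
        taxa_pool = rng.choice(np.arange(3, cfg.n_taxa), size=len(coupled_idx), replace=False)
        strengths = rng.uniform(*cfg.coupling_strengths, size=len(coupled_idx))
        for j, t, s in zip(coupled_idx, taxa_pool, strengths):
            z = np.log10(absolute[:, t] + 1.0)
            z = (z - z.mean()) / max(z.std(), 1e-12)
            a = s / np.sqrt(1 - s**2)  # target correlation s against unit noise
            log_vals[:, j] += a * z
            couplings.append(
                {"taxon_id": taxon_ids[t], "feature_id": feature_ids[j], "strength": float(s)}
            )

    # planted enriched set (a dedicated sub-pathway with shifted members)
    enriched_sets: list[dict] = []
    enriched_idx = np.arange(next_free, next_free + cfg.enriched_set_size)
    next_free += cfg.enriched_set_size
    if cfg.plant_enriched_set:
        for j in enriched_idx:
            log_vals[case, j] += cfg.enriched_set_shift_sd
        enriched_sets.append(
            {
                "set_id": "planted_enriched_subpathway",
                "set_type": "sub_pathway",
                "members": [feature_ids[j] for j in enriched_idx],
                "shift_sd": cfg.enriched_set_shift_sd,
            }
        )

    if cfg.batch_offset:
        batch_codes = meta["batch"].astype("category").cat.codes.to_numpy()
        log_vals += cfg.batch_offset * (batch_codes[:, None] - batch_codes.mean())

    # --- left-censored missingness -------------------------------------
    protected = np.zeros(n_feat, dtype=bool)
    protected[: next_free] = True  # planted structure stays well detected
    q = np.zeros(n_feat)
    censorable = np.nonzero(~protected)[0]
    n_censor = int(round(cfg.missing_fraction_features * censorable.size))
    chosen = rng.choice(censorable, size=n_censor, replace=False)
    q[chosen] = rng.uniform(0.0, cfg.missing_quantile_max, size=n_censor)
    mask = np.zeros((n, n_feat), dtype=bool)
    for j in np.nonzero(q > 0)[0]:
        thresh = np.quantile(log_vals[:, j], q[j])
        mask[:, j] = log_vals[:, j] < thresh

    raw = np.power(10.0, log_vals)
    raw[mask] = np.nan
    matrix = MetaboliteMatrix(sample_ids, feature_ids, raw, mask, "raw")

    # --- annotations ----------------------------------------------------
    named = np.arange(n_feat) < cfg.n_named
    supers = rng.choice(SUPER_PATHWAYS[:-1], size=n_feat)
    supers[[feature_ids.index(f) for f in xeno_ids]] = "Xenobiotics"
    subs = np.array([f"{s} subpathway {rng.integers(4)}" for s in supers], dtype=object)
    for j in enriched_idx:
        subs[j] = "planted_enriched_subpathway"
    kegg = np.array(
        [f"ko{rng.integers(40):05d}" if named[j] and rng.random() < 0.6 else "" for j in range(n_feat)],
        dtype=object,
    )
    ann = pd.DataFrame(
        {
            "display_name": [f"metabolite-{j}" if named[j] else f"X-{j}" for j in range(n_feat)],
            "named_flag": named,
            "super_pathway": np.where(named, supers, ""),
            "sub_pathway": np.where(named, subs, ""),
            "kegg_ids": kegg,
            "platform_tag": rng.choice(["pos", "neg", "polar"], size=n_feat),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    annotations = MetaboliteAnnotation(ann)

    truth = CohortTruth(
        cluster_assignment={s: int(c) for s, c in zip(sample_ids, clusters)},
        cst_assignment={s: str(c) for s, c in zip(sample_ids, cst)},
        effects=effects,
        xenobiotic_features=xeno_ids,
        couplings=couplings,
        enriched_sets=enriched_sets,
        seed=cfg.seed,
    )
    return matrix, taxa, CohortMetadata(meta), annotations, truth


def generate_external_cohort(
    config: SimulationConfig,
    reference_features: list[str],
    overlap_fraction: float,
    seed: int | None = None,
    location_shift: float = 0.3,
    scale_shift: float = 1.1,
) -> tuple[MetaboliteMatrix, CohortMetadata]:
    """An external-validation cohort from the same generative family with
    a feature subset of the requested overlap and a global batch shift."""
    if not (0 < overlap_fraction <= 1):
        raise ValueError("overlap_fraction must be in (0, 1]")
    cfg = SimulationConfig(**{**config.__dict__, "seed": seed if seed is not None else config.seed + 1})
    matrix, _, metadata, _, _ = generate_cohort(cfg)
    rng = np.random.default_rng(cfg.seed + 7)
    k = max(1, round(overlap_fraction * len(reference_features)))
    keep = sorted(rng.choice(np.array(reference_features), size=k, replace=False).tolist())
    sub = matrix.subset_features([f for f in keep if f in matrix.feature_ids])
    shifted = np.power(10.0, np.log10(sub.values) * scale_shift + location_shift)
    return (
        MetaboliteMatrix(sub.sample_ids, sub.feature_ids, shifted, sub.missing_mask, "raw"),
        metadata,
    )
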