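"""Permutation test for metabolite-set enrichment of outcome associations.

For every functional set (Metabolon super-pathway, sub-pathway, or KEGG
pathway) the observed statistic is a second-level Mann-Whitney U p-value
comparing the per-metabolite association p-values inside the set with
those outside it (one-sided by default: in-set p-values stochastically
smaller). Significance comes from re-running the full per-metabolite
scan under random permutations of the outcome labels and recomputing the
second-level p each time; the reported perm_p is
(1 + #{null p <= observed}) / (1 + n_permutations).

The detection-prevalence filter is applied once on the observed stratum
and held fixed across permutations (label shuffles do not change
detection masks), and per-feature permutation p-values are shared across
all sets of a stratum, so the cost is
O(n_permutations x features + sets x n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .associations import (
    MWUScanner,
    bh_fdr,
    case_control_masks,
    stratum_filter,
)
from .cohort_io import CohortMetadata, MetaboliteAnnotation, MetaboliteMatrix

__all__ = [
    "MetaboliteSet",
    "EnrichmentRecord",
    "build_metabolite_sets",
    "set_enrichment_scan",
]


@dataclass
class MetaboliteSet:
    set_id: str
    set_type: str  # super_pathway | sub_pathway | kegg_pathway
    members: list[str]


@dataclass
class EnrichmentRecord:
    set_id: str
    set_type: str
    stratum: str
    observed_second_level_p: float
    perm_p: float
    q: float
    n_in: int
    n_out: int
    n_permutations: int
    seed: int | None


def build_metabolite_sets(
    annotations: MetaboliteAnnotation,
    kegg_map: dict[str, list[str]] | None = None,
) -> list[MetaboliteSet]:
    """One set per distinct super-pathway, sub-pathway and KEGG pathway
    with at least two annotated members.

    ``kegg_map`` optionally maps KEGG compound identifiers to pathway
    identifiers; without it each identifier in a feature's ``kegg_ids``
    list is treated as a pathway key directly. Features lacking KEGG
    identifiers are excluded from KEGG sets only.
    """
    table = annotations.table
    sets: list[MetaboliteSet] = []
    for col, set_type in (("super_pathway", "super_pathway"), ("sub_pathway", "sub_pathway")):
        groups: dict[str, list[str]] = {}
        for fid in sorted(table.index):
            value = table.at[fid, col]
            if isinstance(value, str) and value:
                groups.setdefault(value, []).append(fid)
        for name in sorted(groups):
            if len(groups[name]) >= 2:
                sets.append(MetaboliteSet(name, set_type, groups[name]))
    kegg_groups: dict[str, list[str]] = {}
    for fid in sorted(table.index):
        for kid in annotations.kegg_ids_for(fid):
            pathways = kegg_map.get(kid, []) if kegg_map is not None else [kid]
            for pw in pathways:
                kegg_groups.setdefault(pw, []).append(fid)
    for name in sorted(kegg_groups):
        members = sorted(set(kegg_groups[name]))
        if len(members) >= 2:
            sets.append(MetaboliteSet(name, "kegg_pathway", members))
    return sets


def _second_level_p(
    p_ranks: np.ndarray,
    tie_term: float,
    member_mask: np.ndarray,
    alternative: str,
) -> float:
    """Mann-Whitney p comparing in-set vs out-of-set association p-values,
    from precomputed midranks of the per-feature p-vector."""
    F = p_ranks.size
    m = int(member_mask.sum())
    n_out = F - m
    U1 = p_ranks[member_mask].sum() - m * (m + 1) / 2.0
    mean = m * n_out / 2.0
    var = m * n_out / 12.0 * ((F + 1) - tie_term / (F * (F - 1)))
    if var <= 0:
        return 1.0
    if alternative == "less":  # in-set p-values smaller
        z = (U1 - mean + 0.5) / np.sqrt(var)
        return float(stats.norm.cdf(z))
    if alternative == "two-sided":
        num = U1 - mean
        z = (num - np.sign(num) * 0.5) / np.sqrt(var)
        return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    raise ValueError(f"unknown alternative {alternative!r}")


def _rank_p_vector(p: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = stats.rankdata(p, method="average")
    _, counts = np.unique(p, return_counts=True)
    t = counts[counts > 1]
    tie = float(np.sum(t**3 - t))
    return ranks, tie


def set_enrichment_scan(
    matrix: MetaboliteMatrix,
    metadata: CohortMetadata,
    sets: list[MetaboliteSet],
    stratum: str = "all",
    race: str | None = None,
    exclude_progesterone: bool = False,
    outcome_definition: str = "sPTB",
    controls: str = "rest",
    min_prevalence: float = 0.5,
    n_permutations: int = 10000,
    seed: int | None = None,
    alternative: str = "less",
) -> list[EnrichmentRecord]:
    """Permutation-null enrichment test for every eligible set in a stratum.

    All sets share the same null label draws (one seeded stream per
    stratum), and the per-feature p-values under each permutation are
    computed once and reused across sets. FDR is applied separately
    within each set_type.
    """
    if matrix.sample_ids != metadata.sample_ids:
        raise ValueError("matrix and metadata sample sets must match")
    keep = stratum_filter(metadata, race=race, exclude_progesterone=exclude_progesterone)
    cases, ctrls = case_control_masks(metadata, outcome_definition, controls)
    cases, ctrls = cases & keep, ctrls & keep
    used = cases | ctrls
    if cases.sum() < 3 or ctrls.sum() < 3:
        raise ValueError(f"degenerate stratum {stratum!r}")

    values = matrix.values[used]
    case_mask = cases[used]
    detection = (~np.isnan(values)).mean(axis=0)
    tested = detection >= min_prevalence  # fixed feature universe under the null
    tested_ids = [f for f, t in zip(matrix.feature_ids, tested) if t]
    id_pos = {f: j for j, f in enumerate(tested_ids)}
    scanner = MWUScanner(values[:, tested])

    _, p_obs, _, _ = scanner.test(case_mask)
    valid = np.isfinite(p_obs)
    valid_ids = [f for f, v in zip(tested_ids, valid) if v]
    pos = {f: j for j, f in enumerate(valid_ids)}
    F = len(valid_ids)

    member_masks = {}
    eligible: list[MetaboliteSet] = []
    for s in sets:
        mask = np.zeros(F, dtype=bool)
        for f in s.members:
            if f in pos:
                mask[pos[f]] = True
        n_in = int(mask.sum())
        if n_in < 2:
            continue
        if F - n_in < 2:
            raise ValueError(f"set {s.set_id!r} covers (almost) all tested features")
        member_masks[(s.set_type, s.set_id)] = mask
        eligible.append(s)
    if not eligible:
        return []

    ranks_obs, tie_obs = _rank_p_vector(p_obs[valid])
    observed = {
        key: _second_level_p(ranks_obs, tie_obs, mask, alternative)
        for key, mask in member_masks.items()
    }

    rng = np.random.default_rng(seed)
    exceed = {key: 0 for key in member_masks}
    n_used = used.sum()
    for _ in range(n_permutations):
        perm_mask = np.zeros(n_used, dtype=bool)
        perm_mask[rng.choice(n_used, size=int(case_mask.sum()), replace=False)] = True
        _, p_null, _, _ = scanner.test(perm_mask)
        pv = p_null[valid]
        pv = np.where(np.isfinite(pv), pv, 1.0)
        ranks, tie = _rank_p_vector(pv)
        for key, mask in member_masks.items():
            if _second_level_p(ranks, tie, mask, alternative) <= observed[key]:
                exceed[key] += 1

    records = []
    for s in eligible:
        key = (s.set_type, s.set_id)
        mask = member_masks[key]
        perm_p = (1 + exceed[key]) / (1 + n_permutations)
        records.append(
            EnrichmentRecord(
                set_id=s.set_id,
                set_type=s.set_type,
                stratum=stratum,
                observed_second_level_p=observed[key],
                perm_p=perm_p,
                q=float("nan"),
                n_in=int(mask.sum()),
                n_out=F - int(mask.sum()),
                n_permutations=n_permutations,
                seed=seed,
            )
        )
    types = np.array([r.set_type for r in records])
    qs = bh_fdr(np.array([r.perm_p for r in records]), grouping=types)
    for r, q in zip(records, qs):
        r.q = float(q)
    return records
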