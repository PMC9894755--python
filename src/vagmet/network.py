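"""Microbe-metabolite Spearman correlation network on absolute abundances.

Microbial absolute abundances are estimated by multiplying each taxon's
relative abundance by the sample's total 16S rRNA copy number (qPCR).
Correlations with (typically sPTB-associated) metabolites use available
data only - metabolite non-detections drop the pair, taxon zeros are
observed absences - with a minimum paired-measurement threshold, BH-FDR
across all computed edges, and edge keeping at FDR < 0.1 and |rho| >
0.25. Subgroup correlations are compared with the Fisher r-to-z
transform, and groups of features (e.g. xenobiotics vs the rest) are
contrasted on their |rho| distributions with a Mann-Whitney test.

Note on the pairing threshold: a 22% pairing fraction of a 232-sample
cohort gives ceil(0.22 * 232) = 52, while the explicit integer quoted
alongside it is 50; both rules are supported (``min_pair_fraction`` vs
``min_pairs``) and neither is silently preferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .associations import bh_fdr
from .cohort_io import MetaboliteMatrix, TaxaTable

__all__ = [
    "NetworkEdge",
    "CorrelationComparison",
    "estimate_absolute_abundance",
    "correlation_network",
    "compare_correlation_subgroups",
    "compare_edge_strength_groups",
]


@dataclass
class NetworkEdge:
    taxon_id: str
    feature_id: str
    rho: float
    n_pairs: int
    p: float
    q: float
    kept: bool


@dataclass
class UncomputedEdge:
    taxon_id: str
    feature_id: str
    reason: str


@dataclass
class CorrelationComparison:
    edge: tuple[str, str]
    rho_a: float
    n_a: int
    rho_b: float
    n_b: int
    z: float
    p: float


def estimate_absolute_abundance(taxa: TaxaTable) -> tuple[pd.DataFrame, list[str]]:
    """Relative abundances scaled by per-sample 16S total load.

    Samples lacking a load measurement are excluded (no imputation in the
    network context) and returned as the second element.
    """
    present = ~np.isnan(taxa.total_load)
    if np.any(taxa.total_load[present] <= 0):
        raise ValueError("total load must be positive")
    excluded = [s for s, ok in zip(taxa.sample_ids, present) if not ok]
    absolute = taxa.rel_abundance[present] * taxa.total_load[present][:, None]
    kept = [s for s, ok in zip(taxa.sample_ids, present) if ok]
    return pd.DataFrame(absolute, index=kept, columns=taxa.taxon_ids), excluded


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho; exact permutation p for very small n (enumeration is
    factorial, so capped at n <= 7), t-approximation with midrank ties
    otherwise."""
    n = x.size
    if n <= 7:
        res = stats.spearmanr(x, y)
        rho = float(res.statistic)
        if not np.isfinite(rho):
            return rho, float("nan")
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        import itertools

        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx[list(perm)], ry)[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        return rho, hits / total
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_network(
    absolute: pd.DataFrame,
    metabolites: MetaboliteMatrix,
    min_pair_fraction: float = 0.22,
    min_pairs: int | None = None,
    n_cohort: int | None = None,
    q_max: float = 0.1,
    rho_min: float = 0.25,
) -> tuple[list[NetworkEdge], list[UncomputedEdge]]:
    """All taxon x metabolite Spearman edges on pairwise-complete data.

    The pairing threshold is ``min_pairs`` when given, else
    ``ceil(min_pair_fraction * n_cohort)`` with ``n_cohort`` defaulting
    to the metabolite cohort size. FDR is computed across all computed
    edges; ``kept`` requires q < q_max, |rho| > rho_min and the pairing
    threshold.
    """
    if n_cohort is None:
        n_cohort = metabolites.n_samples
    threshold = min_pairs if min_pairs is not None else math.ceil(min_pair_fraction * n_cohort)

    shared = [s for s in metabolites.sample_ids if s in absolute.index]
    if not shared:
        raise ValueError("no shared samples between taxa and metabolite tables")
    taxa_vals = absolute.loc[shared].to_numpy(dtype=float)
    met = metabolites.subset_samples(shared)

    edges: list[NetworkEdge] = []
    uncomputed: list[UncomputedEdge] = []
    for j, fid in enumerate(met.feature_ids):
        y = met.values[:, j]
        obs = ~np.isnan(y)  # metabolite non-detections drop pairs
        for t, tid in enumerate(absolute.columns):
            x = taxa_vals[obs, t]
            yy = y[obs]
            n_pairs = int(obs.sum())
            if n_pairs < threshold:
                uncomputed.append(
                    UncomputedEdge(tid, fid, f"{n_pairs} complete pairs < threshold {threshold}")
                )
                continue
            if np.all(x == x[0]) or np.all(yy == yy[0]):
                uncomputed.append(UncomputedEdge(tid, fid, "constant vector"))
                continue
            rho, p = _spearman(x, yy)
            edges.append(NetworkEdge(tid, fid, rho, n_pairs, p, float("nan"), False))
    if edges:
        qs = bh_fdr(np.array([e.p for e in edges]))
        for e, q in zip(edges, qs):
            e.q = float(q)
            e.kept = bool(q < q_max and abs(e.rho) > rho_min and e.n_pairs >= threshold)
    return edges, uncomputed


def compare_correlation_subgroups(
    x,
    y,
    group_labels,
    group_a,
    group_b,
    edge: tuple[str, str] = ("", ""),
    spearman_variance: bool = False,
) -> CorrelationComparison:
    """Fisher r-to-z comparison of a correlation between two subgroups.

    z = (atanh(rho_a) - atanh(rho_b)) / sqrt(v/(n_a-3) + v/(n_b-3)) with
    the classical v = 1 (default) or the Spearman-adjusted v = 1.06.
    Pairs with a missing value in either variable are dropped per group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(group_labels)
    v = 1.06 if spearman_variance else 1.0

    def group_rho(g):
        idx = labels == g
        xs, ys = x[idx], y[idx]
        ok = ~np.isnan(xs) & ~np.isnan(ys)
        n = int(ok.sum())
        if n < 4:
            raise ValueError(f"subgroup {g!r} has fewer than 4 complete pairs")
        rho = float(stats.spearmanr(xs[ok], ys[ok]).statistic)
        return rho, n

    rho_a, n_a = group_rho(group_a)
    rho_b, n_b = group_rho(group_b)
    if abs(rho_a) >= 1 - 1e-12 or abs(rho_b) >= 1 - 1e-12:
        raise ValueError("|rho| = 1: Fisher transform is infinite")
    z = (math.atanh(rho_a) - math.atanh(rho_b)) / math.sqrt(v / (n_a - 3) + v / (n_b - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return CorrelationComparison(edge, rho_a, n_a, rho_b, n_b, float(z), p)


def compare_edge_strength_groups(
    edges: list[NetworkEdge],
    group1_features: set[str],
    group2_features: set[str],
) -> tuple[float, float]:
    """Two-sided Mann-Whitney contrast of |rho| between the edges of two
    feature groups (e.g. xenobiotics vs all other sPTB-associated
    metabolites)."""
    g1 = [abs(e.rho) for e in edges if e.feature_id in group1_features]
    g2 = [abs(e.rho) for e in edges if e.feature_id in group2_features]
    if not g1 or not g2:
        raise ValueError("both feature groups need at least one computed edge")
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
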