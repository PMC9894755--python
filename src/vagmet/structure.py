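"""Global-structure analyses of the paired microbiome and metabolome.

Distances (Canberra for metabolome, Bray-Curtis for microbiome),
PERMANOVA with permutation or exhaustive p-values, Mantel tests,
k-medoids clustering of metabolite profiles with gap-statistic selection
of k, the subsample robustness procedure that scores cluster stability,
and one-vs-rest Fisher-exact contingency scans among categorical labels
(metabolite clusters, CSTs, race, birth outcome).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact

import skbio.stats.distance as skbio_distance

from .associations import bh_fdr
from .cohort_io import MetaboliteMatrix

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "ClusteringResult",
    "GapCurve",
    "RobustnessReport",
    "ContingencyResult",
    "compute_distance",
    "permanova",
    "mantel",
    "kmedoids_fit",
    "select_k_gap",
    "match_clusters",
    "cluster_robustness",
    "contingency_association",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    D: np.ndarray
    metric_tag: str

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.D < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    n_permutations: int
    seed: int | None


@dataclass
class ClusteringResult:
    k: int
    medoids: list[str]
    assignment: dict[str, int]
    within_dispersion: float
    seed: int | None

    def labels(self, sample_ids: list[str] | None = None) -> np.ndarray:
        ids = sample_ids if sample_ids is not None else list(self.assignment)
        return np.array([self.assignment[s] for s in ids])


@dataclass
class GapCurve:
    k_values: list[int]
    W_k: list[float]
    gap: list[float]
    s_k: list[float]
    chosen_k: int
    argmax_k: int
    B: int
    seed: int | None


@dataclass
class RobustnessReport:
    n_subsamples: int
    subsample_fraction: float
    accuracies: list[float]
    mean_accuracy: float
    n_above_95: int


@dataclass
class ContingencyResult:
    level_a: str
    level_b: str
    table: list[list[int]]
    odds_ratio: float
    p: float
    q: float = float("nan")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def compute_distance(matrix, metric: str = "canberra") -> DistanceMatrix:
    """Pairwise sample distances.

    Canberra sums |x_i - y_i| / (|x_i| + |y_i|) per coordinate with 0/0
    terms contributing 0 (keeps distances finite on sparse standardized
    data); Bray-Curtis requires non-negative input.
    """
    if isinstance(matrix, MetaboliteMatrix):
        if np.any(matrix.missing_mask):
            raise ValueError("compute_distance requires a complete (imputed) matrix")
        values = matrix.values
        sample_ids = list(matrix.sample_ids)
    else:
        df = pd.DataFrame(matrix)
        values = df.to_numpy(dtype=float)
        sample_ids = [str(i) for i in df.index]
    if metric == "canberra":
        D = squareform(pdist(values, metric="canberra"))
    elif metric == "bray_curtis":
        if np.any(values < 0):
            raise ValueError("Bray-Curtis requires non-negative input")
        D = squareform(pdist(values, metric="braycurtis"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(sample_ids, D, metric)


# ---------------------------------------------------------------------------
# PERMANOVA / Mantel
# ---------------------------------------------------------------------------


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from the squared-distance decomposition (Anderson 2001)."""
    n = len(codes)
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        ss_within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    D: DistanceMatrix,
    groups,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix.

    ``n_permutations="exhaustive"`` enumerates every labelling (feasible
    for n <= ~8) and reports the exact permutation p; otherwise p uses
    random label shuffles with the (1 + exceedances) / (1 + B) floor.
    """
    groups = np.asarray(groups)
    if len(groups) != len(D.sample_ids):
        raise ValueError("one group label per sample required")
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    counts = np.bincount(codes)
    if np.any(counts < 2):
        raise ValueError("every group needs at least two members")
    D2 = D.D**2
    f_obs = _pseudo_f(D2, codes, len(levels))

    if n_permutations == "exhaustive":
        total = 0
        hits = 0
        for perm in itertools.permutations(codes):
            total += 1
            if _pseudo_f(D2, np.array(perm), len(levels)) >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(f_obs, hits / total, total, seed)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(codes)
        if _pseudo_f(D2, perm, len(levels)) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + int(n_permutations))
    return PermanovaResult(f_obs, p, int(n_permutations), seed)


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "spearman",
) -> tuple[float, float]:
    """Mantel test of association between two distance matrices
    (delegated to scikit-bio; Spearman by default)."""
    if D1.sample_ids != D2.sample_ids:
        raise ValueError("Mantel requires identical sample sets and ordering")
    m1 = skbio_distance.DistanceMatrix(D1.D, ids=D1.sample_ids)
    m2 = skbio_distance.DistanceMatrix(D2.D, ids=D2.sample_ids)
    rng = np.random.default_rng(seed)
    np.random.seed(int(rng.integers(2**31 - 1)))  # skbio uses the global stream
    r, p, _ = skbio_distance.mantel(m1, m2, method=method, permutations=n_permutations)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# k-medoids
# ---------------------------------------------------------------------------


def _kpp_seed(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-medoids++ style seeding on a precomputed distance matrix."""
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        d_near = D[:, medoids].min(axis=1)
        w = d_near**2
        total = w.sum()
        if total <= 0:
            remaining = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(remaining)))
        else:
            medoids.append(int(rng.choice(n, p=w / total)))
    return np.array(sorted(set(medoids)))


def _alternate(D: np.ndarray, medoids: np.ndarray, max_iter: int = 100):
    """Voronoi-style alternation: assign to nearest medoid, then move each
    medoid to the member minimizing its cluster's total distance."""
    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(len(medoids)):
            members = np.nonzero(labels == c)[0]
            if members.size == 0:
                # re-seed an empty cluster at the worst-served point
                d_near = D[np.arange(D.shape[0]), medoids[labels]]
                new_medoids[c] = int(np.argmax(d_near))
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    labels = np.argmin(D[:, medoids], axis=1)
    cost = D[np.arange(D.shape[0]), medoids[labels]].sum()
    return medoids, labels, cost


def _swap_refine(D: np.ndarray, medoids: np.ndarray, max_sweeps: int = 20):
    """PAM swap phase: greedily replace one medoid with one non-medoid
    while the total within-cluster distance improves."""
    medoids = np.array(medoids)
    n = D.shape[0]
    for _ in range(max_sweeps):
        d_med = D[:, medoids]  # n x k
        best_delta, best_swap = -1e-12, None
        cost = d_med.min(axis=1).sum()
        for i in range(len(medoids)):
            others = np.delete(np.arange(len(medoids)), i)
            d_rest = d_med[:, others].min(axis=1) if others.size else np.full(n, np.inf)
            # cost after replacing medoid i with each candidate h, vectorized over h
            cand_cost = np.minimum(d_rest[:, None], D).sum(axis=0)
            h = int(np.argmin(cand_cost))
            delta = cost - cand_cost[h]
            if delta > best_delta:
                best_delta, best_swap = delta, (i, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    labels = np.argmin(D[:, medoids], axis=1)
    cost = D[np.arange(n), medoids[labels]].sum()
    return medoids, labels, cost


def kmedoids_fit(
    D: DistanceMatrix,
    k: int,
    seed: int | None = None,
    n_init: int = 10,
    init_medoids: np.ndarray | None = None,
) -> ClusteringResult:
    """PAM-style k-medoids on a precomputed distance matrix; best of
    ``n_init`` seeded restarts by total within-cluster distance."""
    n = len(D.sample_ids)
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for n={n}")
    rng = np.random.default_rng(seed)
    best = None
    inits = [_kpp_seed(D.D, k, rng) for _ in range(n_init)]
    if init_medoids is not None and len(init_medoids) == k:
        inits.append(np.asarray(init_medoids))
    for init in inits:
        if len(init) < k:  # duplicate seeds collapsed; pad randomly
            extra = rng.choice(np.setdiff1d(np.arange(n), init), k - len(init), replace=False)
            init = np.concatenate([init, extra])
        medoids, _, _ = _alternate(D.D, init)
        medoids, labels, cost = _swap_refine(D.D, medoids)
        if best is None or cost < best[2] - 1e-12:
            best = (medoids, labels, cost)
    medoids, labels, cost = best
    # canonical labels: clusters numbered by first occurrence in sample order
    order = {}
    canon = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        canon[i] = order[lab]
    medoid_ids = [D.sample_ids[m] for m in medoids]
    w = float(np.sum(D.D[np.arange(n), medoids[labels]] ** 2))
    assignment = {s: int(c) for s, c in zip(D.sample_ids, canon)}
    return ClusteringResult(k, medoid_ids, assignment, w, seed)


def select_k_gap(
    matrix,
    D: DistanceMatrix,
    k_range=range(1, 16),
    B: int = 50,
    seed: int | None = None,
    n_init: int = 10,
) -> GapCurve:
    """Gap-statistic selection of the cluster count.

    For each k, cluster the data and B reference datasets drawn uniformly
    over each feature's observed range; Gap(k) = mean_b log W_k(ref_b) -
    log W_k(data). The headline k is the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1} (one-SE rule); argmax Gap also reported.
    """
    if isinstance(matrix, MetaboliteMatrix):
        if np.any(matrix.missing_mask):
            raise ValueError("select_k_gap requires a complete matrix")
        values = matrix.values
    else:
        values = np.asarray(matrix, dtype=float)
    if B < 10:
        raise ValueError("B must be >= 10")
    if np.allclose(values, values[0]):
        raise ValueError("degenerate data: all points identical")
    k_values = list(k_range)
    rng = np.random.default_rng(seed)
    lo, hi = values.min(axis=0), values.max(axis=0)

    def w_curve(dm: DistanceMatrix, sub_seed: int) -> list[float]:
        ws = []
        prev = None
        for k in k_values:
            res = kmedoids_fit(
                dm, k, seed=sub_seed + k, n_init=n_init,
                init_medoids=None if prev is None else _extend_medoids(dm.D, prev, k),
            )
            ws.append(max(res.within_dispersion, 1e-300))
            prev = np.array([dm.sample_ids.index(m) for m in res.medoids])
        return ws

    def _extend_medoids(Dm, prev, k):
        if len(prev) >= k:
            return None
        d_near = Dm[:, prev].min(axis=1)
        extra = int(np.argmax(d_near))
        return np.concatenate([prev, [extra]])

    w_data = w_curve(D, int(rng.integers(2**31 - 1)))
    log_w_ref = np.empty((B, len(k_values)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=values.shape)
        dm = compute_distance(
            pd.DataFrame(ref, index=[f"r{i}" for i in range(ref.shape[0])]),
            D.metric_tag,
        )
        log_w_ref[b] = np.log(w_curve(dm, int(rng.integers(2**31 - 1))))

    gap = list(log_w_ref.mean(axis=0) - np.log(w_data))
    s_k = list(log_w_ref.std(axis=0, ddof=0) * math.sqrt(1 + 1 / B))
    chosen = k_values[-1]
    for i in range(len(k_values) - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            chosen = k_values[i]
            break
    argmax_k = k_values[int(np.argmax(gap))]
    return GapCurve(k_values, [float(w) for w in w_data], gap, s_k, chosen, argmax_k, B, seed)


def match_clusters(
    reference: dict[str, int], new: dict[str, int]
) -> tuple[dict[int, int], float]:
    """Optimally map new cluster labels onto reference labels and score
    the matched fraction.

    The mapping maximizes total overlap via the Hungarian method on the
    contingency table; surplus labels on either side stay unmapped and
    their samples count as mismatches.
    """
    shared = sorted(set(reference) & set(new))
    if not shared:
        raise ValueError("no shared samples between assignments")
    ref_labels = sorted({reference[s] for s in shared})
    new_labels = sorted({new[s] for s in shared})
    table = np.zeros((len(new_labels), len(ref_labels)), dtype=int)
    for s in shared:
        table[new_labels.index(new[s]), ref_labels.index(reference[s])] += 1
    rows, cols = linear_sum_assignment(-table)
    mapping = {new_labels[r]: ref_labels[c] for r, c in zip(rows, cols)}
    matched = sum(
        1 for s in shared if mapping.get(new[s], None) == reference[s]
    )
    return mapping, matched / len(shared)


def cluster_robustness(
    matrix,
    D: DistanceMatrix,
    reference: ClusteringResult,
    n_subsamples: int = 100,
    fraction: float = 0.9,
    seed: int | None = None,
    n_init: int = 10,
) -> RobustnessReport:
    """Re-cluster random subsamples (without replacement) at the reference
    k and score each against the reference assignment restricted to the
    subsample; reports mean accuracy and the count of subsets above 95%."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(D.sample_ids)
    m = round(fraction * n)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_subsamples)
    accuracies = []
    for b in range(n_subsamples):
        rng = np.random.default_rng(child_seeds[b])
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub_ids = [D.sample_ids[i] for i in idx]
        sub = DistanceMatrix(sub_ids, D.D[np.ix_(idx, idx)], D.metric_tag)
        fit = kmedoids_fit(sub, reference.k, seed=int(rng.integers(2**31 - 1)), n_init=n_init)
        ref_sub = {s: reference.assignment[s] for s in sub_ids}
        _, acc = match_clusters(ref_sub, fit.assignment)
        accuracies.append(acc)
    return RobustnessReport(
        n_subsamples,
        fraction,
        accuracies,
        float(np.mean(accuracies)),
        int(np.sum(np.asarray(accuracies) > 0.95)),
    )


# ---------------------------------------------------------------------------
# contingency enrichment
# ---------------------------------------------------------------------------


def contingency_association(
    labels_a,
    labels_b,
    scope: np.ndarray | None = None,
) -> list[ContingencyResult]:
    """One-vs-rest two-sided Fisher exact tests for every level pair of two
    categorical label vectors, BH-FDR corrected across the scan."""
    a = pd.Series(np.asarray(labels_a))
    b = pd.Series(np.asarray(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if scope is not None:
        a, b = a[np.asarray(scope)], b[np.asarray(scope)]
    results = []
    for la in sorted(a.unique().astype(str)):
        in_a = a.astype(str) == la
        if in_a.sum() == 0:
            continue
        for lb in sorted(b.unique().astype(str)):
            in_b = b.astype(str) == lb
            if in_b.sum() == 0:
                continue
            table = [
                [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
                [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
            ]
            odds, p = fisher_exact(table, alternative="two-sided")
            results.append(ContingencyResult(la, lb, table, float(odds), float(p)))
    if results:
        qs = bh_fdr(np.array([r.p for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
    return results
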