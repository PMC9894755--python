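"""Raw metabolite measurements -> the standardized scale used downstream.

The pipeline is: volume normalization (per-sample buffer volume), base-10
log transform, then robust standardization per feature (subtract the
median; divide by a standard deviation computed after trimming the top
and bottom 5% order statistics). Missingness is left-censored
(non-detection), so the optional imputation uses the per-feature minimum
observed value as a detection-limit surrogate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import MetaboliteAnnotation, MetaboliteMatrix

__all__ = [
    "DetectionSummary",
    "volume_normalize",
    "log10_transform",
    "robust_standardize",
    "trimmed_sd",
    "detection_summary",
    "min_impute",
]


@dataclass
class DetectionSummary:
    """Counts of features by detection fraction across the cohort."""

    n_features_total: int
    n_named: int
    n_unnamed: int
    detection_fraction: dict[str, float]
    n_detected_over_half: int
    n_detected_in_all: int
    #: same counts restricted to named features (ambiguous denominator)
    n_detected_over_half_named: int = 0
    n_detected_in_all_named: int = 0


@dataclass
class ExcludedFeature:
    feature_id: str
    reason: str


def volume_normalize(matrix: MetaboliteMatrix, volumes: np.ndarray) -> MetaboliteMatrix:
    """Divide each sample's observed values by its extraction-buffer volume."""
    if matrix.scale_tag != "raw":
        raise ValueError("volume_normalize expects a raw-scale matrix")
    volumes = np.asarray(volumes, dtype=float)
    if volumes.shape != (matrix.n_samples,):
        raise ValueError("one volume per sample required")
    if np.any(~np.isfinite(volumes)) or np.any(volumes <= 0):
        raise ValueError("volumes must be positive and finite")
    values = matrix.values / volumes[:, None]
    return MetaboliteMatrix(
        matrix.sample_ids, matrix.feature_ids, values, matrix.missing_mask.copy(), "raw"
    )


def log10_transform(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    if matrix.scale_tag != "raw":
        raise ValueError("log10_transform expects a raw-scale matrix")
    observed = matrix.values[~matrix.missing_mask]
    if observed.size and np.any(observed <= 0):
        raise ValueError("raw detections must be strictly positive")
    with np.errstate(invalid="ignore"):
        values = np.log10(matrix.values)
    return MetaboliteMatrix(
        matrix.sample_ids, matrix.feature_ids, values, matrix.missing_mask.copy(), "log10"
    )


def trimmed_sd(x: np.ndarray, trim: float = 0.05, winsorize: bool = False) -> float:
    """SD after removing (default) or clamping the extreme order statistics.

    ``ceil(trim * n)`` values are dropped from each tail; the n-1
    denominator is used on the retained values.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    k = math.ceil(trim * n)
    if winsorize:
        if k > 0 and n > 2 * k:
            x = np.clip(x, x[k], x[n - k - 1])
        kept = x
    else:
        kept = x[k : n - k]
    if kept.size < 2:
        return float("nan")
    return float(np.std(kept, ddof=1))


def robust_standardize(
    matrix: MetaboliteMatrix,
    trim: float = 0.05,
    winsorize: bool = False,
) -> tuple[MetaboliteMatrix, list[ExcludedFeature]]:
    """Per feature: subtract the median of observed values and divide by
    the trimmed SD. Constant features (trimmed SD of 0) are excluded with
    a reason rather than silently zeroed."""
    if matrix.scale_tag != "log10":
        raise ValueError("robust_standardize expects a log10-scale matrix")
    values = matrix.values.copy()
    keep: list[int] = []
    excluded: list[ExcludedFeature] = []
    for j, fid in enumerate(matrix.feature_ids):
        col = values[:, j]
        obs = col[~matrix.missing_mask[:, j]]
        if obs.size < 3:
            excluded.append(ExcludedFeature(fid, f"only {obs.size} observed values"))
            continue
        sd = trimmed_sd(obs, trim=trim, winsorize=winsorize)
        if not np.isfinite(sd) or sd == 0:
            excluded.append(ExcludedFeature(fid, "zero trimmed dispersion (constant feature)"))
            continue
        values[:, j] = (col - np.median(obs)) / sd
        keep.append(j)
    out = MetaboliteMatrix(
        matrix.sample_ids,
        [matrix.feature_ids[j] for j in keep],
        values[:, keep],
        matrix.missing_mask[:, keep].copy(),
        "standardized",
    )
    return out, excluded


def detection_summary(
    matrix: MetaboliteMatrix, annotations: MetaboliteAnnotation | None = None
) -> DetectionSummary:
    """Per-feature detection fractions and the headline counts.

    "Detected in over half" is strict (fraction > 0.5); "detected in all"
    means no masked entry for the feature. Depends only on the mask, so it
    is invariant to any monotone transform of the values.
    """
    n = matrix.n_samples
    frac = 1.0 - matrix.missing_mask.mean(axis=0)
    fractions = {f: float(frac[j]) for j, f in enumerate(matrix.feature_ids)}
    over_half = frac > 0.5
    in_all = frac == 1.0
    if annotations is not None:
        named = np.array(
            [
                bool(annotations.table.at[f, "named_flag"]) if f in annotations.table.index else False
                for f in matrix.feature_ids
            ]
        )
    else:
        named = np.ones(matrix.n_features, dtype=bool)
    return DetectionSummary(
        n_features_total=matrix.n_features,
        n_named=int(named.sum()),
        n_unnamed=int((~named).sum()),
        detection_fraction=fractions,
        n_detected_over_half=int(over_half.sum()),
        n_detected_in_all=int(in_all.sum()),
        n_detected_over_half_named=int((over_half & named).sum()),
        n_detected_in_all_named=int((in_all & named).sum()),
    )


def min_impute(matrix: MetaboliteMatrix) -> tuple[MetaboliteMatrix, np.ndarray]:
    """Replace each masked cell with the per-feature minimum observed value.

    Returns the completed matrix (empty mask) and the boolean provenance
    matrix marking which cells were imputed. Left-censored missingness
    makes the observed minimum a natural detection-limit surrogate.
    """
    values = matrix.values.copy()
    imputed = matrix.missing_mask.copy()
    for j in range(matrix.n_features):
        col = values[:, j]
        obs = col[~matrix.missing_mask[:, j]]
        if obs.size == 0:
            raise ValueError(
                f"feature {matrix.feature_ids[j]!r} has no observed values; cannot impute"
            )
        col[matrix.missing_mask[:, j]] = obs.min()
    out = MetaboliteMatrix(
        matrix.sample_ids,
        matrix.feature_ids,
        values,
        np.zeros_like(matrix.missing_mask),
        matrix.scale_tag,
    )
    return out, imputed
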