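"""Typed in-memory model of the cohort and delimited-text readers/writers.

The cohort couples three tables keyed by sample identifier:

* a samples x features metabolite matrix (raw LC-MS area counts, with
  left-censored missing values recorded in an explicit mask),
* a samples x taxa relative-abundance table with optional per-sample 16S
  total load (qPCR copy number), and
* per-sample clinical metadata (birth outcome, gestational age at birth,
  self-identified race, covariates, processing batch).

All I/O is plain TSV/CSV; identifiers are opaque strings and joins are
exact-match only.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteMatrix",
    "MetaboliteAnnotation",
    "TaxaTable",
    "CohortMetadata",
    "read_metabolite_matrix",
    "write_metabolite_matrix",
    "read_taxa_table",
    "write_taxa_table",
    "read_metadata",
    "write_metadata",
    "write_report",
    "read_report",
]

#: tokens that parse as missing, case-insensitively (vendor export variability)
MISSING_TOKENS = {"", "na", "nan"}

ANNOTATION_COLUMNS = (
    "display_name",
    "named_flag",
    "super_pathway",
    "sub_pathway",
    "kegg_ids",
    "platform_tag",
)

FLOAT_FORMAT = "%.10g"


@dataclass
class MetaboliteMatrix:
    """Samples x metabolite features matrix with an explicit missingness mask.

    ``values`` holds raw area counts (strictly positive where observed),
    log10 values, or robust-standardized values, as recorded by
    ``scale_tag``. ``missing_mask[i, j]`` is True iff the value is
    undefined (below detection); masked cells of ``values`` hold NaN.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    scale_tag: Literal["raw", "log10", "standardized"] = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, f = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != f:
            raise ValueError("identifier lists do not match matrix shape")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape does not match values")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.feature_ids)) != f:
            raise ValueError("duplicate feature identifiers")
        if self.scale_tag == "raw":
            observed = self.values[~self.missing_mask]
            if observed.size and not np.all(observed > 0):
                raise ValueError("raw values must be strictly positive where observed")
        # masked cells are NaN by convention
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            list(self.sample_ids),
            list(self.feature_ids),
            self.values.copy(),
            self.missing_mask.copy(),
            self.scale_tag,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MetaboliteMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MetaboliteMatrix(
            list(sample_ids),
            list(self.feature_ids),
            self.values[idx],
            self.missing_mask[idx],
            self.scale_tag,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "MetaboliteMatrix":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return MetaboliteMatrix(
            list(self.sample_ids),
            list(feature_ids),
            self.values[:, idx],
            self.missing_mask[:, idx],
            self.scale_tag,
        )


@dataclass
class MetaboliteAnnotation:
    """Per-feature annotations: display name, identification status,
    Metabolon super-/sub-pathway, and KEGG compound identifiers."""

    table: pd.DataFrame  # index: feature_id; columns: ANNOTATION_COLUMNS

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate feature_id in annotations")
        for col in ANNOTATION_COLUMNS:
            if col not in self.table.columns:
                self.table[col] = "" if col != "named_flag" else False
        self.table = self.table[list(ANNOTATION_COLUMNS)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def kegg_ids_for(self, feature_id: str) -> list[str]:
        raw = self.table.at[feature_id, "kegg_ids"]
        if not isinstance(raw, str) or not raw:
            return []
        return [k for k in raw.split(";") if k]

    @property
    def n_named(self) -> int:
        return int(self.table["named_flag"].astype(bool).sum())

    @property
    def n_unnamed(self) -> int:
        return len(self.table) - self.n_named


@dataclass
class TaxaTable:
    """Samples x taxa relative abundances with optional 16S total load."""

    sample_ids: list[str]
    taxon_ids: list[str]
    rel_abundance: np.ndarray
    total_load: np.ndarray | None = None  # NaN where missing

    def __post_init__(self) -> None:
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        n, t = self.rel_abundance.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != t:
            raise ValueError("identifier lists do not match matrix shape")
        if np.any(self.rel_abundance < 0):
            raise ValueError("relative abundances must be non-negative")
        sums = self.rel_abundance.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("rows must sum to 1 (renormalize on read)")
        if self.total_load is None:
            self.total_load = np.full(n, np.nan)
        else:
            self.total_load = np.asarray(self.total_load, dtype=float)
            present = ~np.isnan(self.total_load)
            if np.any(self.total_load[present] <= 0):
                raise ValueError("total_load must be positive where present")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rel_abundance, index=self.sample_ids, columns=self.taxon_ids)


METADATA_COLUMNS = (
    "outcome",
    "gab_weeks",
    "race",
    "age_years",
    "bmi",
    "nulliparous",
    "ptb_history",
    "progesterone",
    "batch",
    "cst",
)


@dataclass
class CohortMetadata:
    """Per-sample outcome and clinical covariates.

    Outcome is ``sPTB`` (spontaneous preterm birth, delivery before 37
    weeks) or ``TB`` (term); ``gab_weeks`` is gestational age at birth.
    """

    table: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample_id in metadata")
        missing = [c for c in ("outcome", "gab_weeks", "race") if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        bad = self.table.query("outcome == 'sPTB' and gab_weeks >= 37")
        if len(bad):
            raise ValueError(f"sPTB samples with gab_weeks >= 37: {list(bad.index[:5])}")
        bad = self.table.query("outcome == 'TB' and gab_weeks < 37")
        if len(bad):
            raise ValueError(f"TB samples with gab_weeks < 37: {list(bad.index[:5])}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def outcome_binary(self, definition: str = "sPTB") -> pd.Series:
        """0/1 labels for a birth-outcome definition.

        ``sPTB``: delivery < 37 weeks; ``GAB<32`` / ``GAB<28``: very /
        extremely preterm. Reclassification changes only the labels.
        """
        if definition == "sPTB":
            return (self.table["outcome"] == "sPTB").astype(int)
        if definition.startswith("GAB<"):
            cutoff = float(definition[4:])
            return (self.table["gab_weeks"] < cutoff).astype(int)
        raise ValueError(f"unknown outcome definition: {definition!r}")

    def subset(self, sample_ids: Sequence[str]) -> "CohortMetadata":
        return CohortMetadata(self.table.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _parse_cell(raw: str, row: str, col: str) -> float:
    token = raw.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"non-numeric cell {raw!r} at row {row!r}, column {col!r}") from None
    return value


def read_metabolite_matrix(
    path: str | Path,
    orientation: Literal["samples_in_rows", "features_in_rows"] = "samples_in_rows",
) -> tuple[MetaboliteMatrix, MetaboliteAnnotation]:
    """Read a raw metabolite table; blank/NA/NaN cells become masked entries.

    Annotation columns (``display_name``, ``named_flag``, ...) are parsed
    when present (features-in-rows orientation) and otherwise defaulted.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if len(header) != len(set(header)):
        raise ValueError(f"duplicate identifiers in header of {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate identifiers in {path}")

    ann_cols = [c for c in df.columns if c in ANNOTATION_COLUMNS]
    ann_df = df[ann_cols].copy() if ann_cols else None
    data = df.drop(columns=ann_cols)

    values = np.empty(data.shape, dtype=float)
    for j, col in enumerate(data.columns):
        for i, row in enumerate(data.index):
            values[i, j] = _parse_cell(data.iat[i, j], str(row), str(col))

    if orientation == "features_in_rows":
        values = values.T
        sample_ids = [str(c) for c in data.columns]
        feature_ids = [str(r) for r in data.index]
    else:
        sample_ids = [str(r) for r in data.index]
        feature_ids = [str(c) for c in data.columns]
        if ann_df is not None:
            raise ValueError("annotation columns require features_in_rows orientation")

    mask = np.isnan(values)
    if np.any(values[~mask] < 0):
        bad = np.argwhere((values < 0) & ~mask)[0]
        raise ValueError(
            f"negative raw value at sample {sample_ids[bad[0]]!r}, feature {feature_ids[bad[1]]!r}"
        )
    if np.any(values[~mask] == 0):
        bad = np.argwhere((values == 0) & ~mask)[0]
        raise ValueError(
            f"zero raw value at sample {sample_ids[bad[0]]!r}, feature {feature_ids[bad[1]]!r}"
            " (raw detections are strictly positive; use a blank cell for non-detection)"
        )

    if ann_df is not None:
        ann_df.index = [str(r) for r in ann_df.index]
        if "named_flag" in ann_df.columns:
            ann_df["named_flag"] = ann_df["named_flag"].str.lower().isin({"true", "1", "yes"})
        annotations = MetaboliteAnnotation(ann_df)
    else:
        annotations = MetaboliteAnnotation(
            pd.DataFrame(
                {"display_name": feature_ids, "named_flag": True},
                index=pd.Index(feature_ids, name="feature_id"),
            )
        )
    matrix = MetaboliteMatrix(sample_ids, feature_ids, values, mask, scale_tag="raw")
    return matrix, annotations


def write_metabolite_matrix(matrix: MetaboliteMatrix, path: str | Path) -> None:
    """Write samples-in-rows TSV/CSV; masked cells become blank."""
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path), na_rep="", float_format=FLOAT_FORMAT)


def write_annotations(annotations: MetaboliteAnnotation, path: str | Path) -> None:
    path = Path(path)
    table = annotations.table.copy()
    table.index.name = "feature_id"
    table.to_csv(path, sep=_sep_for(path))


def read_annotations(path: str | Path) -> MetaboliteAnnotation:
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False)
    table.index = [str(i) for i in table.index]
    if "named_flag" in table.columns:
        table["named_flag"] = table["named_flag"].str.lower().isin({"true", "1", "yes"})
    return MetaboliteAnnotation(table)


def read_taxa_table(path: str | Path, load_path: str | Path | None = None) -> TaxaTable:
    """Read relative abundances (samples in rows), renormalizing each row
    to sum 1, and join per-sample total 16S load when provided."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate identifiers in {path}")
    values = df.to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        raise ValueError("taxa table may not contain missing values")
    if np.any(values < 0):
        raise ValueError("taxa abundances must be non-negative")
    sums = values.sum(axis=1)
    zero_rows = np.nonzero(sums == 0)[0]
    if zero_rows.size:
        raise ValueError(f"all-zero abundance row for sample {df.index[zero_rows[0]]!r}")
    values = values / sums[:, None]
    sample_ids = [str(i) for i in df.index]

    total_load = np.full(len(sample_ids), np.nan)
    if load_path is not None:
        load_path = Path(load_path)
        loads = pd.read_csv(load_path, sep=_sep_for(load_path), index_col=0).iloc[:, 0]
        loads.index = [str(i) for i in loads.index]
        unmatched = set(loads.index) - set(sample_ids)
        if unmatched:
            warnings.warn(f"load file samples not in taxa table: {sorted(unmatched)[:5]}")
        for i, s in enumerate(sample_ids):
            if s in loads.index:
                total_load[i] = loads[s]
    return TaxaTable(sample_ids, [str(c) for c in df.columns], values, total_load)


def write_taxa_table(
    taxa: TaxaTable, path: str | Path, load_path: str | Path | None = None
) -> None:
    path = Path(path)
    df = taxa.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT)
    if load_path is not None:
        load_path = Path(load_path)
        loads = pd.Series(taxa.total_load, index=taxa.sample_ids, name="total_load")
        loads = loads.dropna()
        loads.index.name = "sample_id"
        loads.to_csv(load_path, sep=_sep_for(load_path), float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path) -> CohortMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = [str(i) for i in df.index]
    for col in ("nulliparous", "ptb_history", "progesterone"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().isin({"true", "1", "yes"})
    return CohortMetadata(df)


def write_metadata(metadata: CohortMetadata, path: str | Path) -> None:
    path = Path(path)
    df = metadata.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------


def _records_to_frame(results: Iterable) -> pd.DataFrame:
    rows = []
    for r in results:
        if dataclasses.is_dataclass(r):
            rows.append(dataclasses.asdict(r))
        elif isinstance(r, dict):
            rows.append(dict(r))
        else:
            raise TypeError(f"cannot serialize result of type {type(r)}")
    return pd.DataFrame(rows)


def write_report(
    results,
    path: str | Path,
    format: Literal["tsv", "json"] = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Serialize a result collection deterministically.

    ``tsv`` expects a list of records (dataclasses or dicts) and writes
    one row per record with a fixed column order; ``json`` accepts any
    JSON-encodable structure (dataclasses converted recursively).
    """
    path = Path(path)
    if format == "tsv":
        df = _records_to_frame(results)
        if columns is not None:
            for col in columns:
                if col not in df.columns:
                    df[col] = np.nan
            df = df[list(columns)]
        elif not df.empty:
            df = df[sorted(df.columns)]
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    elif format == "json":
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"cannot serialize {type(o)}")

        path.write_text(json.dumps(results, indent=1, sort_keys=True, default=default) + "\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: str | Path, format: Literal["tsv", "json"] = "tsv"):
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return json.loads(path.read_text())
    raise ValueError(f"unknown report format: {format!r}")
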