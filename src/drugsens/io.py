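"""Readers, writers and alignment helpers for the workflow's table formats.

The workflow consumes four kinds of tables:

* gene expression matrices (GCT 1.2 or plain TSV), genes x samples, on the
  TPM or log2(TPM+1) scale as used by CCLE-style exports;
* gene-set collections in GMT format (one tab-separated set per line);
* drug-response label tables in long CSV form ``sample_id,compound_id,auc``
  (CTRP-shaped; larger AUC means greater resistance);
* optional per-sample clinical metadata CSV keyed by ``sample_id``.

Gene and sample identifiers are opaque strings matched exactly and
case-sensitively; no symbol/alias mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "DrugResponseTable",
    "read_expression",
    "write_expression",
    "log_transform",
    "read_gmt",
    "write_gmt",
    "read_drug_response",
    "write_drug_response",
    "read_metadata",
    "align_training_pairs",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale tag.

    ``scale_tag`` is ``"tpm"`` for linear TPM values or ``"log2tpm1"`` for
    log2(TPM+1)-transformed values (the scale the downstream feature
    engineering expects).
    """

    values: pd.DataFrame
    scale_tag: str = "log2tpm1"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("tpm", "log2tpm1"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """An ordered mapping set name -> :class:`GeneSet`."""

    entries: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.entries[name]

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_lists(cls, sets: Mapping[str, Sequence[str]]) -> "GeneSetCollection":
        entries = {
            name: GeneSet(name, "", tuple(dict.fromkeys(genes)))
            for name, genes in sets.items()
        }
        return cls(entries)


@dataclass
class DrugResponseTable:
    """Long-form (sample, compound, AUC) records; larger AUC = more resistant."""

    records: pd.DataFrame  # columns: sample_id, compound_id, auc

    REQUIRED = ("sample_id", "compound_id", "auc")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"label table missing columns {missing}")
        self.records = self.records.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        if not np.all(np.isfinite(self.records["auc"].to_numpy(dtype=float))):
            raise ValueError("AUC labels must be finite")
        pair = self.records[["sample_id", "compound_id"]]
        if pair.duplicated().any():
            dup = pair[pair.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (sample, compound) pair: ({dup.sample_id}, {dup.compound_id})"
            )

    @property
    def compounds(self) -> list[str]:
        return list(pd.unique(self.records["compound_id"]))

    def for_compound(self, compound_id: str) -> pd.Series:
        """AUC labels for one compound, indexed by sample ID."""
        if compound_id not in set(self.records["compound_id"]):
            raise KeyError(f"compound {compound_id!r} not in catalogue")
        sub = self.records[self.records["compound_id"] == compound_id]
        return pd.Series(
            sub["auc"].to_numpy(dtype=float), index=list(sub["sample_id"]), name=compound_id
        )


# ---------------------------------------------------------------------------
# expression


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicated gene rows by keeping the highest-mean row."""
    if not df.index.has_duplicates:
        return df
    dup_names = df.index[df.index.duplicated()].unique().tolist()
    logger.warning(
        "collapsing %d duplicated gene row(s) to max-mean row: %s",
        len(dup_names),
        dup_names[:10],
    )
    means = df.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    # keep='first' on the mean-descending ordering picks the max-mean row,
    # then restore the original row order of the survivors
    kept = df.iloc[order]
    kept = kept[~kept.index.duplicated(keep="first")]
    return kept.loc[[g for g in dict.fromkeys(df.index) ], :]


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().rstrip("\n")
        if version.strip() != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().rstrip("\n").split("\t")
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dimensions line {dims!r}")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer GCT dimensions {dims!r}") from exc
        body = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    if "Description" in body.columns:
        body = body.drop(columns="Description")
    if body.shape != (n_rows, n_cols):
        raise FormatError(
            f"{path}: GCT dimensions line declares {n_rows}x{n_cols} "
            f"but body is {body.shape[0]}x{body.shape[1]}"
        )
    return body


def read_expression(path, format: str | None = None, scale_tag: str = "log2tpm1") -> ExpressionMatrix:
    """Read a genes x samples matrix from GCT 1.2 or TSV.

    ``format`` defaults to the file suffix (``.gct`` -> gct, else tsv).
    Duplicate gene rows are collapsed to the row with the highest mean
    expression (with a logged warning). Non-numeric cells raise a parse
    error naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        df = _read_gct(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        raise FormatError(f"{path}: missing expression values are not supported")
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df.astype(float), scale_tag=scale_tag)


def write_expression(m: ExpressionMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.n_genes}\t{m.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(m.sample_ids) + "\n")
            for gene, row in m.values.iterrows():
                cells = "\t".join(repr(float(v)) for v in row.to_numpy())
                fh.write(f"{gene}\tna\t{cells}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(["gene_id", *m.sample_ids]) + "\n")
            for gene, row in m.values.iterrows():
                cells = "\t".join(repr(float(v)) for v in row.to_numpy())
                fh.write(f"{gene}\t{cells}\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(v+1); requires TPM-scale input (refuses double application)."""
    if m.scale_tag != "tpm":
        raise ValueError("log_transform expects scale_tag='tpm' input (already transformed?)")
    arr = m.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative TPM values cannot be log transformed")
    out = pd.DataFrame(np.log2(arr + 1.0), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, scale_tag="log2tpm1")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set collection: ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are dropped (first occurrence kept);
    duplicate set names are an error.
    """
    path = Path(path)
    entries: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in entries:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g != ""))
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            entries[name] = GeneSet(name, description, genes)
    return GeneSetCollection(entries)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# drug-response labels


_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def read_drug_response(path) -> DrugResponseTable:
    """Read a long-form label CSV with header ``sample_id,compound_id,auc``.

    Blank or "NA" AUC cells are admitted as missing records and excluded.
    Duplicate (sample, compound) pairs with conflicting AUC raise an error;
    exact duplicates are collapsed.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "compound_id": str},
                     keep_default_na=False, float_precision="round_trip")
    missing_cols = [c for c in DrugResponseTable.REQUIRED if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: label CSV missing columns {missing_cols}")
    auc_raw = df["auc"].astype(str).str.strip()
    keep = ~auc_raw.isin(_MISSING_TOKENS)
    df = df.loc[keep].copy()
    try:
        df["auc"] = df["auc"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric AUC value ({exc})") from exc
    # collapse exact duplicates; conflicting ones trip the table invariant
    grouped = df.groupby(["sample_id", "compound_id"], sort=False)["auc"]
    spans = grouped.agg(lambda s: s.max() - s.min())
    if (spans > 0).any():
        bad = spans[spans > 0].index[0]
        raise FormatError(f"{path}: conflicting AUC values for (sample, compound) {bad}")
    df = df.drop_duplicates(subset=["sample_id", "compound_id"], keep="first")
    return DrugResponseTable(df.reset_index(drop=True))


def write_drug_response(table: DrugResponseTable, path) -> None:
    out = table.records.copy()
    out["auc"] = [repr(float(v)) for v in out["auc"]]
    out.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read a per-sample metadata CSV keyed by ``sample_id``."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata CSV needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample_id in metadata")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# training-table assembly


def align_training_pairs(
    expr_or_features, labels: DrugResponseTable, compound_id: str
) -> tuple[list[str], np.ndarray]:
    """Intersect feature samples with a compound's labelled samples.

    ``expr_or_features`` may be an :class:`ExpressionMatrix` (samples are
    columns) or any DataFrame whose columns are samples. Returns the
    overlapping sample IDs in feature order and the aligned label vector;
    zero overlap is an error.
    """
    if isinstance(expr_or_features, ExpressionMatrix):
        sample_ids = expr_or_features.sample_ids
    else:
        sample_ids = list(expr_or_features.columns)
    label_series = labels.for_compound(compound_id)
    labelled = set(label_series.index)
    paired = [s for s in sample_ids if s in labelled]
    if not paired:
        raise ValueError(
            f"no overlap between feature samples and labelled samples for {compound_id!r}"
        )
    y = label_series.loc[paired].to_numpy(dtype=float)
    return paired, y
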