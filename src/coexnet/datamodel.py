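"""Typed containers and TSV/GMT readers and writers.

The canonical on-disk dialect is tab-separated text with one header row and
one identifier column (GEO series-matrix-adjacent convention); comma
separation is accepted behind ``sep=","``. Gene identifiers are opaque:
probe IDs and symbols are both legal and no annotation mapping is
attempted.

Sample alignment between tables is always by identifier, never by
position; dropped samples are logged with counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "TraitTable",
    "SurvivalTable",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_traits",
    "write_traits",
    "read_survival",
    "write_survival",
    "read_gmt",
    "write_gmt",
    "align_samples",
]


def _check_unique(ids, kind: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {kind} identifiers: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Wraps a DataFrame whose index are gene identifiers and whose columns
    are sample identifiers. Values must be finite; identifiers unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        if self.data.shape[0] < 2:
            raise ValueError("expression matrix needs at least 2 genes")
        if self.data.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 samples")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _locate_non_numeric(self.data)
            raise ValueError(f"non-numeric expression values at {bad}")
        if not np.isfinite(values).all():
            rows, cols = np.nonzero(~np.isfinite(values))
            coords = [
                (self.data.index[i], self.data.columns[j])
                for i, j in zip(rows[:10], cols[:10])
            ]
            raise ValueError(f"missing/non-finite expression values at {coords}")

    @property
    def gene_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class TraitTable:
    """Samples x traits table with numeric encodings (ordinal grade 1-3,
    binary tumor/normal, or continuous)."""

    data: pd.DataFrame
    encoding_notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "trait")
        if not np.issubdtype(self.data.to_numpy().dtype, np.number):
            raise ValueError("trait values must be numeric")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def trait_names(self) -> list:
        return self.data.columns.tolist()


@dataclass
class SurvivalTable:
    """Per-sample follow-up time and event indicator (1 = event observed)."""

    data: pd.DataFrame  # columns: time, event

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if (self.data["time"].to_numpy() < 0).any():
            bad = self.data.index[self.data["time"] < 0].tolist()
            raise ValueError(f"negative survival times for samples {bad}")
        ev = self.data["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)


@dataclass
class GeneSetCollection:
    """Named gene sets (the substrate for over-representation tests)."""

    sets: dict  # name -> frozenset of gene ids
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]


def _locate_non_numeric(df: pd.DataFrame) -> list:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    rows, cols = np.nonzero(bad.to_numpy())
    return [(df.index[i], df.columns[j]) for i, j in zip(rows[:10], cols[:10])]


def read_expression(
    path,
    orientation: str = "genes-in-rows",
    sep: str = "\t",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load an expression TSV (one header row, one identifier column).

    ``orientation="samples-in-rows"`` transposes after load. Missing values
    are a hard error unless ``impute_missing`` enables per-gene mean
    imputation.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples-in-rows":
        df = df.T
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    nonnum = df.select_dtypes(exclude="number").columns
    if len(nonnum):
        raise ValueError(f"non-numeric expression values at {_locate_non_numeric(df)}")
    if df.isna().any().any():
        if impute_missing:
            means = df.mean(axis=1)
            df = df.apply(lambda col: col.fillna(means))
            logger.info("imputed missing values with per-gene means")
        else:
            rows, cols = np.nonzero(df.isna().to_numpy())
            coords = [(df.index[i], df.columns[j]) for i, j in zip(rows[:10], cols[:10])]
            raise ValueError(f"missing expression values at {coords}")
    return ExpressionMatrix(df.astype(float))


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    expr.data.to_csv(path, sep=sep, index_label="gene_id")


def read_traits(path, sep: str = "\t", encoding_notes: dict | None = None) -> TraitTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return TraitTable(df.astype(float), encoding_notes or {})


def write_traits(traits: TraitTable, path, sep: str = "\t") -> None:
    traits.data.to_csv(path, sep=sep, index_label="sample_id")


def read_survival(path, sep: str = "\t") -> SurvivalTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return SurvivalTable(df)


def write_survival(surv: SurvivalTable, path, sep: str = "\t") -> None:
    surv.data.to_csv(path, sep=sep, index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Parse the standard GMT dialect: name TAB description TAB members..."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            if not members:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def align_samples(expr: ExpressionMatrix, table):
    """Align an expression matrix with a trait or survival table by sample id.

    Returns ``(expr_subset, table_subset)`` on the intersection, in the
    expression matrix's sample order. Drops are logged with counts.
    """
    other_ids = table.sample_ids
    shared = [s for s in expr.sample_ids if s in set(other_ids)]
    dropped_expr = expr.n_samples - len(shared)
    dropped_other = len(other_ids) - len(shared)
    if dropped_expr or dropped_other:
        logger.info(
            "sample alignment dropped %d expression and %d table samples (%d shared)",
            dropped_expr,
            dropped_other,
            len(shared),
        )
    if not shared:
        raise ValueError("no shared samples between expression matrix and table")
    expr_sub = expr.subset_samples(shared)
    if isinstance(table, TraitTable):
        table_sub = TraitTable(table.data.loc[shared], table.encoding_notes)
    elif isinstance(table, SurvivalTable):
        table_sub = SurvivalTable(table.data.loc[shared])
    else:
        raise TypeError(f"cannot align {type(table).__name__}")
    return expr_sub, table_sub
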