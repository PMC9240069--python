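"""Tables, sets and network formats shared by every analysis stage.

The pipeline moves sample × feature intensity matrices (metabolomics,
lipidomics, expression), a two-level pathway annotation, GMT feature sets,
clinical survival tables and a subpathway→metabolite classification network
between stages.  Everything here is plain delimited UTF-8 text; delimiter is
inferred from the extension (``.tsv`` vs ``.csv``) and can be overridden.

Malformed input is rejected loudly — duplicate identifiers, ragged rows and
short GMT lines raise :class:`FormatError` naming the offender — rather than
silently coerced.  Missing values are carried as NaN in an explicit float
matrix, never as a sentinel intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("omicscore")

VALID_UNITS = ("raw", "log2")


class FormatError(ValueError):
    """A file violated the dialect this package reads or writes."""


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class FeatureMatrix:
    """Samples × features intensity table with per-sample metadata.

    ``values`` is indexed by sample id with one column per feature; the
    ``unit`` flag records whether entries are raw intensities or log2
    values.  ``sample_metadata`` (same index) carries group / time-point /
    condition labels used by the differential stages.
    """

    values: pd.DataFrame
    sample_metadata: pd.DataFrame | None = None
    unit: str = "raw"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        self.values = self.values.astype(float)
        if self.sample_metadata is None:
            self.sample_metadata = pd.DataFrame(index=self.values.index)
        elif not self.sample_metadata.index.equals(self.values.index):
            self.sample_metadata = self.sample_metadata.reindex(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self, column: str = "group") -> pd.Series:
        if column not in self.sample_metadata.columns:
            raise KeyError(f"sample metadata has no {column!r} column")
        return self.sample_metadata[column]


@dataclass
class PathwayAnnotation:
    """feature id → (super-pathway, subpathway), each feature at most once."""

    table: pd.DataFrame  # index: feature_id; columns: super_pathway, sub_pathway

    def __post_init__(self) -> None:
        required = {"super_pathway", "sub_pathway"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"annotation needs columns {sorted(required)}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"feature annotated more than once: {dup!r}")
        empty = self.table[(self.table.super_pathway == "") | (self.table.sub_pathway == "")]
        if len(empty):
            raise FormatError(f"empty pathway label for feature {empty.index[0]!r}")

    def subpathway_of(self, feature: str) -> str | None:
        if feature in self.table.index:
            return self.table.loc[feature, "sub_pathway"]
        return None

    def members(self, sub_pathway: str) -> list[str]:
        return list(self.table.index[self.table.sub_pathway == sub_pathway])

    @property
    def sub_pathways(self) -> list[str]:
        return list(pd.unique(self.table.sub_pathway))

    def as_sets(self) -> "MetaboliteSetCollection":
        sets = {
            sp: list(self.table.index[self.table.sub_pathway == sp])
            for sp in self.sub_pathways
        }
        return MetaboliteSetCollection(sets)


@dataclass
class MetaboliteSetCollection:
    """Named feature sets (subpathways used as the set reference)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))  # dedupe, keep order
            if not uniq:
                raise FormatError(f"set {name!r} has no members")
            cleaned[name] = uniq
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class SurvivalTable:
    """Per-subject follow-up: time (>0), event (1=event, 0=censored), endpoint."""

    table: pd.DataFrame  # columns: subject, time, event, endpoint
    VALID_ENDPOINTS = ("OS", "EFS", "PFS")

    def __post_init__(self) -> None:
        required = {"subject", "time", "event"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"survival table needs columns {sorted(required)}")
        if "endpoint" not in self.table.columns:
            self.table = self.table.assign(endpoint="OS")
        if (self.table.time <= 0).any():
            bad = self.table.loc[self.table.time <= 0, "subject"].iloc[0]
            raise FormatError(f"non-positive follow-up time for subject {bad!r}")
        if not self.table.event.isin([0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")


# ---------------------------------------------------------------------------
# feature matrices


def read_feature_matrix(
    path: str | Path,
    orientation: str = "samples_by_features",
    unit: str = "raw",
    delimiter: str | None = None,
    metadata_path: str | Path | None = None,
) -> FeatureMatrix:
    """Read a delimited intensity table.

    ``orientation`` must be ``samples_by_features`` or ``features_by_samples``
    (the matrix is transposed to samples × features internally); there is no
    auto-detection — a square table is ambiguous.  Non-numeric cells become
    missing.  An optional metadata table (index = sample id) supplies group
    labels.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter_for(path, delimiter)
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for name in header:  # pandas silently mangles duplicate columns
        if name in seen:
            raise FormatError(f"duplicate column id: {name!r}")
        seen.add(name)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"malformed table {path}: {exc}") from exc
    if orientation == "features_by_samples":
        df = df.T
    df = df.apply(pd.to_numeric, errors="coerce")
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep=_delimiter_for(metadata_path, delimiter), index_col=0)
    return FeatureMatrix(df, sample_metadata=meta, unit=unit)


def write_feature_matrix(
    matrix: FeatureMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    sep = _delimiter_for(path, delimiter)
    matrix.values.to_csv(path, sep=sep, na_rep="NA")


def read_annotation(path: str | Path, delimiter: str | None = None) -> PathwayAnnotation:
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str).fillna("")
    return PathwayAnnotation(df)


def write_annotation(annotation: PathwayAnnotation, path: str | Path, delimiter: str | None = None) -> None:
    annotation.table.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="feature_id")


def read_survival_table(path: str | Path, delimiter: str | None = None) -> SurvivalTable:
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    return SurvivalTable(df)


def write_survival_table(table: SurvivalTable, path: str | Path, delimiter: str | None = None) -> None:
    table.table.to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


# ---------------------------------------------------------------------------
# GMT feature sets


def read_metabolite_sets_gmt(path: str | Path) -> MetaboliteSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Members are de-duplicated within a line; a line with fewer than three
    fields (i.e. no members) is an error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need ≥3")
            name, _description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    if not sets:
        logger.warning("GMT file %s contained no sets", path)
    return MetaboliteSetCollection(sets)


def write_metabolite_sets_gmt(
    collection: MetaboliteSetCollection, path: str | Path, descriptions: Mapping[str, str] | None = None
) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection:
            desc = descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# classification network export


def write_network(network: nx.DiGraph, path: str | Path, format: str = "sif") -> None:
    """Write a subpathway→metabolite classification network.

    SIF rows are ``subpathway<TAB>contains<TAB>metabolite``; GraphML keeps
    node attributes (``size``, ``direction_class``, ``kind``).
    """
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as handle:
            for source, target, data in network.edges(data=True):
                relation = data.get("relation", "contains")
                handle.write(f"{source}\t{relation}\t{target}\n")
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unknown network format {format!r} (use 'sif' or 'graphml')")


def read_network_graphml(path: str | Path) -> nx.DiGraph:
    return nx.DiGraph(nx.read_graphml(path))


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    genes: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            token = line.strip()
            if token and not token.startswith("#"):
                genes.append(token)
    return list(dict.fromkeys(genes))
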