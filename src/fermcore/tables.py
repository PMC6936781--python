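"""Typed sample-by-feature tables and TSV readers/writers.

Two blocks flow through the pipeline: a genus-level abundance table
(the X block, counts or relative abundances for samples F1..Fn) and a
flavor-component table (the Y block, volatile-compound peak areas and
free-amino-acid concentrations) with a per-component annotation giving
each component's kind (``VF`` or ``AA``), its chemical category for
volatiles, and its taste class for amino acids.

Internally both tables are oriented samples-as-rows, always.  Genus
labels are opaque strings (forms like ``norank_o__AKYG1722`` are kept
verbatim); no taxonomy parsing is attempted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "FlavorTable",
    "TableValidationError",
    "VF_CATEGORIES",
    "AA_TASTE_CLASSES",
    "load_flavor_annotation",
    "read_abundance_table",
    "write_abundance_table",
    "read_flavor_table",
    "write_flavor_table",
    "to_relative_abundance",
    "abundance_summary",
]

VF_CATEGORIES = (
    "alcohol",
    "ester",
    "pyrazine",
    "alkane",
    "aldehyde",
    "phenol",
    "acid",
    "other",
)
AA_TASTE_CLASSES = ("umami", "sweet", "bitter", "unclassified")


class TableValidationError(ValueError):
    """A table violates a structural invariant (negative entry, duplicate label, ...)."""


def _check_frame(df: pd.DataFrame, what: str) -> None:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise TableValidationError(f"{what}: duplicate sample labels {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise TableValidationError(f"{what}: duplicate feature labels {dups}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise TableValidationError(
            f"{what}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise TableValidationError(
            f"{what}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise TableValidationError(
            f"{what}: negative value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )


@dataclass
class AbundanceTable:
    """Samples x genera matrix (counts or proportions) plus sample metadata.

    Parameters
    ----------
    data:
        Non-negative matrix, samples as rows, genera as columns.
    metadata:
        Optional per-sample frame indexed like ``data``; recognised columns
        are ``day`` (fermentation day, integer >= 1) and ``group``.
    proportions:
        Declare the values as relative abundances; each row must then sum
        to 1 within 1e-9.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None
    proportions: bool = False

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_frame(self.data, "abundance table")
        if self.proportions:
            sums = self.data.sum(axis=1)
            off = sums[(sums - 1.0).abs() > 1e-9]
            if len(off):
                raise TableValidationError(
                    f"declared as proportions but row sums deviate from 1: {off.to_dict()}"
                )
        if self.metadata is not None:
            if not self.metadata.index.equals(self.data.index):
                self.metadata = self.metadata.reindex(self.data.index)
            if "day" in self.metadata:
                days = self.metadata["day"].dropna()
                if (days < 1).any():
                    raise TableValidationError("fermentation day must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def groups(self) -> pd.Series | None:
        if self.metadata is not None and "group" in self.metadata:
            return self.metadata["group"]
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.values, other.values, atol=1e-12)
        )


@dataclass
class FlavorTable:
    """Samples x flavor-components matrix with per-component annotation.

    ``annotation`` is indexed by component id with columns ``kind``
    (VF/AA), ``category`` (for VFs) and ``taste_class`` (for AAs).
    Every component in ``data`` must be annotated.
    """

    data: pd.DataFrame
    annotation: pd.DataFrame = field(default_factory=lambda: load_flavor_annotation())

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_frame(self.data, "flavor table")
        ann = self.annotation
        missing = [c for c in self.data.columns if c not in ann.index]
        if missing:
            raise TableValidationError(f"components without annotation: {missing}")
        sub = ann.loc[list(self.data.columns)]
        bad_kind = sub[~sub["kind"].isin(["VF", "AA"])]
        if len(bad_kind):
            raise TableValidationError(
                f"components with unknown kind: {list(bad_kind.index)}"
            )
        vf = sub[sub["kind"] == "VF"]
        bad_cat = vf[~vf["category"].isin(VF_CATEGORIES)]
        if len(bad_cat):
            raise TableValidationError(
                f"VF components with missing/unknown category: {list(bad_cat.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def component_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def kinds(self) -> pd.Series:
        return self.annotation.loc[list(self.data.columns), "kind"]

    def components_of_kind(self, kind: str) -> list[str]:
        k = self.kinds()
        return list(k.index[k == kind])


def load_flavor_annotation(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged flavor-component annotation (42 VFs + 16 AAs) or a user TSV."""
    if path is None:
        ref = importlib.resources.files("fermcore") / "data" / "flavor_annotation.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.set_index("component_id")
    df["taste_class"] = df["taste_class"].replace("", "unclassified")
    aa = df[df["kind"] == "AA"]
    bad = aa[~aa["taste_class"].isin(AA_TASTE_CLASSES)]
    if len(bad):
        raise TableValidationError(f"AA with unknown taste class: {list(bad.index)}")
    return df


def _read_matrix(path: str | Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise TableValidationError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
    return df


def read_abundance_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    metadata: pd.DataFrame | None = None,
    proportions: bool = False,
    sep: str = "\t",
) -> AbundanceTable:
    """Read a genus abundance TSV (one header row, one label column).

    ``orientation='taxa_as_rows'`` transposes on read so that the returned
    table is always samples-as-rows.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_matrix(path, sep)
    if orientation == "taxa_as_rows":
        df = df.T
    return AbundanceTable(df, metadata=metadata, proportions=proportions)


def write_abundance_table(t: AbundanceTable, path: str | Path, sep: str = "\t") -> None:
    t.data.to_csv(path, sep=sep, index_label="sample_id")


def read_flavor_table(
    path: str | Path,
    annotation: pd.DataFrame | None = None,
    sep: str = "\t",
) -> FlavorTable:
    df = _read_matrix(path, sep)
    if annotation is None:
        annotation = load_flavor_annotation()
    return FlavorTable(df, annotation=annotation)


def write_flavor_table(t: FlavorTable, path: str | Path, sep: str = "\t") -> None:
    t.data.to_csv(path, sep=sep, index_label="sample_id")


def to_relative_abundance(t: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances (rows sum to 1).

    Idempotent; zeros stay zero. An all-zero sample is an error because no
    composition exists for it.
    """
    sums = t.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise TableValidationError(
            f"all-zero sample(s), cannot normalise: {list(zero.index)}"
        )
    rel = t.data.div(sums, axis=0)
    return AbundanceTable(rel, metadata=t.metadata, proportions=True)


def abundance_summary(t: AbundanceTable, threshold: float = 0.01) -> pd.DataFrame:
    """Per-taxon mean relative abundance with minor taxa pooled as ``other``.

    Taxa whose mean relative abundance is at or below ``threshold`` are
    pooled; the named columns plus ``other`` sum to 1 for every sample.
    ``threshold=0`` pools nothing.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    rel = t if t.proportions else to_relative_abundance(t)
    means = rel.data.mean(axis=0)
    major = means[means > threshold].index if threshold > 0 else means.index
    out = rel.data[list(major)].copy()
    minor = [c for c in rel.data.columns if c not in set(major)]
    if minor:
        out["other"] = rel.data[minor].sum(axis=1)
    out.loc["mean"] = out.mean(axis=0)
    return out
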