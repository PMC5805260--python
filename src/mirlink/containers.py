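"""Core data containers for paired miRNA/mRNA expression studies.

Expression values are log-intensities stored feature x sample; absent calls
and missing values are both represented as NaN in the underlying frame and
exposed through :attr:`ExpressionMatrix.missing_mask`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "ET"
CONTROL = "CTRL"

__all__ = ["CASE", "CONTROL", "ExpressionMatrix", "GroupDesign"]


@dataclass
class ExpressionMatrix:
    """A features x samples table of log-intensity expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features, columns are samples.  NaN marks a missing or
        absent measurement.
    kind : str
        Feature kind, ``"miRNA"`` or ``"mRNA"``.
    """

    data: pd.DataFrame
    kind: str = "miRNA"

    def __post_init__(self) -> None:
        if self.kind not in ("miRNA", "mRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature identifiers")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        self.data = self.data.astype(float)

    # -- basic views -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean features x samples array, True where the value is missing."""
        return self.data.isna().to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, features=None, samples=None) -> "ExpressionMatrix":
        """Return a copy restricted to the given features and/or samples."""
        df = self.data
        if features is not None:
            df = df.loc[list(features)]
        if samples is not None:
            df = df[list(samples)]
        return ExpressionMatrix(df.copy(), kind=self.kind)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV with a ``feature_id`` index column and ``NA`` missing."""
        self.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")

    @classmethod
    def read_tsv(cls, path, kind: str = "miRNA") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id", na_values=["NA"])
        return cls(df, kind=kind)


@dataclass
class GroupDesign:
    """Per-sample case/control labels plus the technical-replicate map.

    ``group`` is indexed by *physical* sample id with values in
    ``{"ET", "CTRL"}``.  ``replicate_map`` maps each matrix column id to its
    physical sample id; columns absent from the map are their own physical
    sample.
    """

    group: pd.Series
    replicate_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = pd.Series(self.group)
        bad = set(self.group) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.group == CASE).sum() == 0 or (self.group == CONTROL).sum() == 0:
            raise ValueError("both groups must be non-empty")
        for col, phys in self.replicate_map.items():
            if phys not in self.group.index:
                raise KeyError(f"replicate column {col!r} maps to unknown sample {phys!r}")

    @property
    def sample_ids(self) -> list[str]:
        """Physical sample ids, in design order."""
        return list(self.group.index)

    @property
    def z(self) -> np.ndarray:
        """Binary outcome vector over physical samples (1 = case)."""
        return (self.group == CASE).to_numpy().astype(int)

    @property
    def case_ids(self) -> list[str]:
        return list(self.group.index[self.group == CASE])

    @property
    def control_ids(self) -> list[str]:
        return list(self.group.index[self.group == CONTROL])

    def physical_of(self, column_id: str) -> str:
        return self.replicate_map.get(column_id, column_id)

    def columns_of(self, physical_id: str, columns) -> list[str]:
        """Matrix columns belonging to one physical sample."""
        return [c for c in columns if self.physical_of(c) == physical_id]

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, design_path, replicate_path=None) -> None:
        pd.DataFrame({"sample_id": self.group.index, "group": self.group.values}).to_csv(
            design_path, sep="\t", index=False
        )
        if replicate_path is not None:
            rows = [{"column_id": c, "sample_id": p} for c, p in self.replicate_map.items()]
            pd.DataFrame(rows, columns=["column_id", "sample_id"]).to_csv(
                replicate_path, sep="\t", index=False
            )

    @classmethod
    def read_tsv(cls, design_path, replicate_path=None) -> "GroupDesign":
        df = pd.read_csv(design_path, sep="\t")
        group = pd.Series(df["group"].values, index=df["sample_id"].values)
        rep: dict[str, str] = {}
        if replicate_path is not None:
            rdf = pd.read_csv(replicate_path, sep="\t")
            rep = dict(zip(rdf["column_id"], rdf["sample_id"]))
        return cls(group, rep)
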