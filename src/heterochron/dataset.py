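"""Expression age-series container and tab-delimited I/O.

The universal input of the pipeline is a gene x sample expression matrix
(log-scale values) together with per-sample age (years) and a two-level
group label (e.g. female/male, case/control).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "DatasetError", "read_dataset", "write_dataset"]

# float format preserving >= 15 significant digits for lossless-enough round trips
_FLOAT_FMT = "%.15g"


class DatasetError(ValueError):
    """Raised for structurally invalid expression datasets."""


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with sample ages and group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows, samples in columns; numeric, log-scale.
    ages : pandas.Series
        Age in years per sample, indexed like ``values.columns``.
    groups : pandas.Series
        Two-level group label per sample, indexed like ``values.columns``.
    """

    values: pd.DataFrame
    ages: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.ages = pd.Series(self.ages, dtype=float)
        self.groups = pd.Series(self.groups)
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise DatasetError("empty expression matrix")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DatasetError(f"duplicated gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DatasetError(f"duplicated sample id: {dup!r}")
        for meta, name in ((self.ages, "age"), (self.groups, "group")):
            missing = self.values.columns.difference(meta.index)
            if len(missing):
                raise DatasetError(
                    f"sample {missing[0]!r} has no {name} in the metadata"
                )
        extra = self.ages.index.difference(self.values.columns)
        if len(extra):
            raise DatasetError(f"metadata sample {extra[0]!r} absent from matrix")
        # align order to matrix columns
        self.ages = self.ages.loc[self.values.columns]
        self.groups = self.groups.loc[self.values.columns]
        if not np.isfinite(self.ages.to_numpy()).all():
            bad = self.ages.index[~np.isfinite(self.ages.to_numpy())][0]
            raise DatasetError(f"non-finite age for sample {bad!r}")
        if self.groups.isna().any():
            bad = self.groups.index[self.groups.isna()][0]
            raise DatasetError(f"missing group label for sample {bad!r}")
        try:
            arr = self.values.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"non-numeric expression values: {exc}") from exc
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise DatasetError(
                f"non-finite value for gene {self.values.index[gi]!r} "
                f"sample {self.values.columns[si]!r}"
            )
        levels = self.group_levels
        if len(levels) != 2:
            raise DatasetError(
                f"expected exactly two group levels, got {list(levels)}"
            )
        for g in levels:
            n = int((self.groups == g).sum())
            if n < 3:
                raise DatasetError(
                    f"group {g!r} has only {n} samples; at least 3 required"
                )

    # -- accessors -------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def group_levels(self) -> list:
        """The two group labels, sorted; the first is 'group A' throughout."""
        return sorted(pd.unique(self.groups))

    def group_mask(self, group) -> np.ndarray:
        return (self.groups == group).to_numpy()

    def group_arrays(self, gene):
        """Return (ages_a, values_a, ages_b, values_b) for one gene.

        Group A is the first sorted group level.
        """
        row = self.values.loc[gene].to_numpy(dtype=float)
        ages = self.ages.to_numpy(dtype=float)
        a, b = self.group_levels
        ma = self.group_mask(a)
        mb = self.group_mask(b)
        return ages[ma], row[ma], ages[mb], row[mb]

    def subset_genes(self, genes) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(genes)], self.ages, self.groups)

    def subset_samples(self, samples) -> "ExpressionDataset":
        samples = list(samples)
        return ExpressionDataset(
            self.values[samples], self.ages.loc[samples], self.groups.loc[samples]
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.copy(), self.ages.copy(), self.groups.copy()
        )


def write_dataset(ds: ExpressionDataset, directory, prefix: str = "") -> dict:
    """Write a dataset as ``<prefix>matrix.tsv`` + ``<prefix>metadata.tsv``.

    Returns a dict of the paths written. Round-trips through
    :func:`read_dataset` are lossless to >= 15 significant digits.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix_path = directory / f"{prefix}matrix.tsv"
    meta_path = directory / f"{prefix}metadata.tsv"
    ds.values.to_csv(matrix_path, sep="\t", index_label="gene",
                     float_format=_FLOAT_FMT)
    meta = pd.DataFrame(
        {"sample": ds.sample_ids, "age": ds.ages.to_numpy(),
         "group": ds.groups.to_numpy()}
    )
    meta.to_csv(meta_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return {"matrix": matrix_path, "metadata": meta_path}


def read_dataset(directory=None, *, matrix=None, metadata=None,
                 prefix: str = "") -> ExpressionDataset:
    """Read a dataset written by :func:`write_dataset`.

    Either give the directory (expects ``<prefix>matrix.tsv`` and
    ``<prefix>metadata.tsv``) or explicit ``matrix=``/``metadata=`` paths.
    """
    if directory is not None:
        directory = Path(directory)
        matrix = directory / f"{prefix}matrix.tsv"
        metadata = directory / f"{prefix}metadata.tsv"
    if matrix is None or metadata is None:
        raise DatasetError("need a directory or explicit matrix/metadata paths")
    values = pd.read_csv(matrix, sep="\t", index_col=0)
    meta = pd.read_csv(metadata, sep="\t")
    for col in ("sample", "age", "group"):
        if col not in meta.columns:
            raise DatasetError(f"metadata table lacks required column {col!r}")
    if meta["sample"].duplicated().any():
        dup = meta["sample"][meta["sample"].duplicated()].iloc[0]
        raise DatasetError(f"duplicated sample id in metadata: {dup!r}")
    meta = meta.set_index("sample")
    return ExpressionDataset(values, meta["age"], meta["group"])
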