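"""Model/Results interface over the heterochrony detection cascade.

`HeterochronyModel` is built from an :class:`ExpressionDataset` (or from a
values + metadata pair of DataFrames) and holds the analysis parameters;
``fit()`` runs the three-stage trajectory cascade followed by the
bidirectional DTW shift test on the cascade survivors and returns a
:class:`HeterochronyResults` carrying the per-gene tables, stage counts,
direction breakdown and a ``summary()``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .dtws import heterochrony_screen
from .trajectory import run_cascade

__all__ = ["HeterochronyModel", "HeterochronyResults"]


class HeterochronyModel:
    """Two-group transcriptional heterochrony model.

    Parameters
    ----------
    dataset : ExpressionDataset
    alpha : float
        Per-stage significance threshold (raw p-values by default).
    max_degree : int
        Largest polynomial degree considered by the adjusted-r² criterion.
    n_grid, slack : int
        DTW grid resolution and open-end slack (grid points).
    n_null : int
        Null-simulation replicates per gene and direction.
    null_mode : {"parametric", "permutation"}
    correction : {None, "fdr_bh"}
        Optional BH adjustment of the cascade p-values.
    """

    def __init__(self, dataset: ExpressionDataset, *, alpha: float = 0.05,
                 max_degree: int = 3, n_grid: int = 50, slack: int = 5,
                 n_null: int = 1000, null_mode: str = "parametric",
                 correction: str | None = None):
        self.dataset = dataset
        self.alpha = float(alpha)
        self.max_degree = int(max_degree)
        self.n_grid = int(n_grid)
        self.slack = int(slack)
        self.n_null = int(n_null)
        self.null_mode = null_mode
        self.correction = correction

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, metadata: pd.DataFrame,
                       **kwargs) -> "HeterochronyModel":
        """Build from a gene x sample values frame and a metadata frame
        with ``sample``/``age``/``group`` columns (or sample index)."""
        meta = metadata.copy()
        if "sample" in meta.columns:
            meta = meta.set_index("sample")
        ds = ExpressionDataset(values, meta["age"], meta["group"])
        return cls(ds, **kwargs)

    @property
    def params(self) -> dict:
        return {
            "alpha": self.alpha, "max_degree": self.max_degree,
            "n_grid": self.n_grid, "slack": self.slack,
            "n_null": self.n_null, "null_mode": self.null_mode,
            "correction": self.correction,
        }

    def fit(self, seed: int | None = None, threads: int = 1,
            genes=None) -> "HeterochronyResults":
        """Run the cascade, then the DTW shift test on its survivors."""
        ds = self.dataset if genes is None else self.dataset.subset_genes(genes)
        cascade = run_cascade(ds, alpha=self.alpha, max_degree=self.max_degree,
                              correction=self.correction)
        eligible = cascade.index[cascade["passes_stage3"]]
        het = heterochrony_screen(
            ds, genes=eligible, alpha=self.alpha, n_null=self.n_null,
            seed=seed, n_grid=self.n_grid, slack=self.slack,
            max_degree=self.max_degree, null_mode=self.null_mode,
            threads=threads,
        )
        return HeterochronyResults(self, cascade, het, seed)


@dataclass
class HeterochronyResults:
    """Fitted results: per-gene cascade and heterochrony tables."""

    model: HeterochronyModel
    cascade: pd.DataFrame
    heterochrony: pd.DataFrame
    seed: int | None

    @property
    def dataset(self) -> ExpressionDataset:
        return self.model.dataset

    @property
    def significant_genes(self) -> pd.Index:
        if self.heterochrony.empty:
            return pd.Index([], name="gene")
        return self.heterochrony.index[self.heterochrony["significant"]]

    @property
    def stage_counts(self) -> pd.Series:
        c = self.cascade
        het = self.heterochrony
        sig = het["significant"] if not het.empty else pd.Series(dtype=bool)
        direction = (het.loc[self.significant_genes, "direction"]
                     if not het.empty else pd.Series(dtype=object))
        return pd.Series(
            {
                "total_genes": len(c),
                "age_related": int(c["passes_stage1"].sum()),
                "divergent": int(c["passes_stage2"].sum()),
                "codirectional": int(c["passes_stage3"].sum()),
                "heterochrony_tested": len(het),
                "significant_heterochronic": int(sig.sum()),
                "A_accelerated": int((direction == "A-accelerated").sum()),
                "B_accelerated": int((direction == "B-accelerated").sum()),
            },
            name="count",
        )

    @property
    def direction_percentages(self) -> pd.Series:
        counts = self.stage_counts
        n_sig = counts["significant_heterochronic"]
        if n_sig == 0:
            return pd.Series({"A_accelerated": 0.0, "B_accelerated": 0.0},
                             name="percent")
        return pd.Series(
            {
                "A_accelerated": 100.0 * counts["A_accelerated"] / n_sig,
                "B_accelerated": 100.0 * counts["B_accelerated"] / n_sig,
            },
            name="percent",
        )

    def summary(self) -> str:
        """Human-readable run summary (stage counts and parameters)."""
        counts = self.stage_counts
        pct = self.direction_percentages
        a, b = self.dataset.group_levels
        lines = [
            "Transcriptional heterochrony analysis",
            "=" * 53,
            f"samples: {self.dataset.n_samples} "
            f"(group {a!r}: {int(self.dataset.group_mask(a).sum())}, "
            f"group {b!r}: {int(self.dataset.group_mask(b).sum())})",
            f"genes:   {self.dataset.n_genes}",
            "-" * 53,
            f"{'stage':<38}{'genes':>8}",
        ]
        labels = {
            "age_related": "1. age-related (poly F-test)",
            "divergent": "2. between-group divergent (ANCOVA)",
            "codirectional": "3. co-directional (Pearson)",
            "heterochrony_tested": "   tested for heterochrony (DTW)",
            "significant_heterochronic": "4. significantly heterochronic",
        }
        for key, label in labels.items():
            lines.append(f"{label:<38}{counts[key]:>8}")
        lines.append("-" * 53)
        lines.append(
            f"direction among significant: {a!r} accelerated "
            f"{counts['A_accelerated']} ({pct['A_accelerated']:.1f}%), "
            f"{b!r} accelerated {counts['B_accelerated']} "
            f"({pct['B_accelerated']:.1f}%)"
        )
        lines.append(f"parameters: {self.model.params}")
        lines.append(f"seed: {self.seed}")
        return "\n".join(lines)

    def save(self, directory, prefix: str = "") -> dict:
        """Write cascade / heterochrony / stage-count tables as TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, table in (
            ("cascade", self.cascade),
            ("heterochrony", self.heterochrony),
        ):
            p = directory / f"{prefix}{name}.tsv"
            table.to_csv(p, sep="\t", float_format="%.10g")
            paths[name] = p
        p = directory / f"{prefix}stage_counts.tsv"
        self.stage_counts.to_frame().to_csv(p, sep="\t")
        paths["stage_counts"] = p
        return paths
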