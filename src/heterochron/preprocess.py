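"""Normalization and sample QC for expression matrices.

Implements quantile normalization, per-gene standardization, marker-based
group-label verification (e.g. XIST / Y-linked genes for sex labels) and an
extreme-gene-count outlier screen with PCA coordinates for inspection.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

__all__ = [
    "quantile_normalize",
    "log2_transform",
    "standardize_genes",
    "verify_group_markers",
    "detect_outliers",
    "write_qc_report",
]


def _as_frame(matrix) -> pd.DataFrame:
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(matrix)
    arr = df.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        gi, si = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite value for gene {df.index[gi]!r} sample {df.columns[si]!r}"
        )
    return df


def quantile_normalize(matrix) -> pd.DataFrame:
    """Quantile-normalize columns of a gene x sample matrix.

    After normalization every column holds the same multiset of values: the
    value at rank r in each column is replaced by the mean of the rank-r
    values across columns. Row and column order are preserved; ties keep
    their original (stable sort) order, which makes the operation
    idempotent.
    """
    df = _as_frame(matrix)
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = rows
    sorted_means = np.sort(arr, axis=0).mean(axis=1)
    out = sorted_means[ranks]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def log2_transform(matrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount) for raw-scale input.

    Never applied automatically: the caller declares raw-scale input.
    """
    df = _as_frame(matrix)
    arr = df.to_numpy(dtype=float)
    if (arr + pseudocount <= 0).any():
        raise ValueError("log2 transform requires values > -pseudocount")
    return pd.DataFrame(np.log2(arr + pseudocount), index=df.index,
                        columns=df.columns)


def standardize_genes(matrix, ddof: int = 1, return_flags: bool = False):
    """Scale each gene (row) to mean 0, SD 1.

    ``ddof=1`` (sample SD) is the default so standardized residual variances
    remain comparable with the downstream variance F-tests; ``ddof=0`` gives
    population-SD scaling. Zero-variance rows are returned as all zeros and
    flagged.
    """
    df = _as_frame(matrix)
    arr = df.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    flat = sd[:, 0] <= 1e-300
    sd[flat] = 1.0
    out = (arr - mean) / sd
    out[flat] = 0.0
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    if return_flags:
        return res, pd.Series(flat, index=df.index, name="zero_variance")
    return res


def _marker_score(std_values: pd.DataFrame, marker_up, marker_down) -> pd.Series:
    up = std_values.loc[list(marker_up)].mean(axis=0) if len(marker_up) else 0.0
    down = (std_values.loc[list(marker_down)].mean(axis=0)
            if len(marker_down) else 0.0)
    return up - down


def verify_group_markers(ds: ExpressionDataset, marker_up, marker_down,
                         z_threshold: float = 3.0, up_group=None) -> pd.DataFrame:
    """Flag samples whose marker-gene profile contradicts their group label.

    ``marker_up`` are genes expected high in ``up_group`` (default: the
    first sorted group level), ``marker_down`` genes expected high in the
    other group. Each sample gets a signature score (mean standardized
    expression of marker_up minus marker_down); a sample is flagged as
    ``mislabeled-suspect`` when its score sits more than ``z_threshold``
    group-residual SDs from its own group's center *and* closer to the
    other group's center.
    """
    marker_up = [m for m in marker_up if m in ds.gene_ids]
    marker_down = [m for m in marker_down if m in ds.gene_ids]
    if not marker_up and not marker_down:
        raise ValueError("no marker genes found in the expression matrix")
    a, b = ds.group_levels
    if up_group is None:
        up_group = a
    std = standardize_genes(ds.values)
    score = _marker_score(std, marker_up, marker_down)
    centers = {g: score[ds.group_mask(g)].median() for g in (a, b)}
    resid = np.concatenate(
        [score[ds.group_mask(g)].to_numpy() - centers[g] for g in (a, b)]
    )
    scale = float(np.std(resid, ddof=1)) if len(resid) > 2 else 1.0
    scale = max(scale, 1e-12)

    rows = []
    for s in ds.sample_ids:
        g = ds.groups[s]
        other = b if g == a else a
        z_own = (score[s] - centers[g]) / scale
        suspect = (
            math.isfinite(z_threshold)
            and abs(z_own) > z_threshold
            and abs(score[s] - centers[other]) < abs(score[s] - centers[g])
        )
        rows.append(
            {
                "sample": s,
                "group": g,
                "marker_score": score[s],
                "marker_z": z_own,
                "marker_flag": "mislabeled-suspect" if suspect else "ok",
                "reasons": (
                    f"marker score {score[s]:.3g} is {abs(z_own):.1f} SD from "
                    f"group {g!r} center and closer to group {other!r}"
                    if suspect else ""
                ),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def detect_outliers(ds: ExpressionDataset, sd_cutoff: float = 3.0,
                    min_extreme_genes: int | None = None) -> pd.DataFrame:
    """Extreme-gene-count outlier screen.

    For each sample, count the genes where the sample's value lies more
    than ``sd_cutoff`` cross-sample SDs from that gene's mean; flag samples
    whose count reaches ``min_extreme_genes``. The default threshold is the
    larger of 3% of the genes (absolute floor) and the 99th percentile of
    the per-sample counts, so the rule adapts to platform size. First two
    principal-component coordinates are reported for visual inspection.
    """
    if ds.n_samples < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    arr = ds.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    sd[sd <= 1e-300] = np.inf
    if math.isinf(sd_cutoff):
        counts = np.zeros(ds.n_samples, dtype=int)
    else:
        counts = (np.abs(arr - mean) > sd_cutoff * sd).sum(axis=0)
    if min_extreme_genes is None:
        floor = int(np.ceil(0.03 * ds.n_genes))
        perc = int(np.ceil(np.percentile(counts, 99)))
        min_extreme_genes = max(floor, perc)

    from sklearn.decomposition import PCA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pcs = PCA(n_components=2, svd_solver="full").fit_transform(
            arr.T - arr.T.mean(axis=0)
        )
    flagged = counts >= min_extreme_genes
    report = pd.DataFrame(
        {
            "n_extreme_genes": counts,
            "outlier_flag": flagged,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "reasons": [
                (f"{c} genes beyond {sd_cutoff} SD "
                 f"(threshold {min_extreme_genes})") if f else ""
                for c, f in zip(counts, flagged)
            ],
        },
        index=ds.sample_ids.rename("sample"),
    )
    report.attrs["min_extreme_genes"] = int(min_extreme_genes)
    return report


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", float_format="%.6g")
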