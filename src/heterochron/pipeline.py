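"""End-to-end reproducible pipeline runs driven by a flat config.

``run_pipeline`` executes simulate/load -> QC -> cascade -> heterochrony ->
downstream, writing per-stage tab-delimited tables, a JSON manifest of
seeds/thresholds/counts and a log; the same config and seed reproduce
byte-identical tables.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import ExpressionDataset, read_dataset, write_dataset
from .downstream import bootstrap_cluster_samples, cluster_genes, variance_f_test
from .model import HeterochronyModel
from .preprocess import detect_outliers, write_qc_report
from .synthdata import SimulationConfig, generate, write_truth
from .trajectory import _overlap_grid, fit_best_polynomial

__all__ = ["RunConfig", "run_pipeline", "summarize_counts", "read_run_config"]

_FLOAT_FMT = "%.10g"

logger = logging.getLogger("heterochron")


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run.

    Either ``matrix``/``metadata`` paths or ``simulate=True`` (with the
    generator parameters in ``sim``) must be given.
    """

    outdir: str = "heterochron_run"
    matrix: str | None = None
    metadata: str | None = None
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    max_degree: int = 3
    n_grid: int = 50
    slack: int = 5
    n_null: int = 1000
    n_boot: int = 1000
    k_gene_clusters: int = 6
    correction: str | None = None
    null_mode: str = "parametric"
    run_qc: bool = True
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not (self.simulate or (self.matrix and self.metadata)):
            raise ValueError("need matrix+metadata paths or simulate=True")


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def read_run_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file (# starts a comment).

    Generator parameters are prefixed ``sim.``, e.g. ``sim.n_genes = 500``.
    """
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        raw[key] = value

    def convert(value: str, typ):
        if typ is bool or isinstance(typ, bool):
            return _BOOL[value.lower()]
        if value.lower() in ("none", ""):
            return None
        if typ in (int, float, str):
            return typ(value)
        if "," in value:  # tuple-valued fields, e.g. shift ranges
            return tuple(float(v) for v in value.split(","))
        try:
            return int(value)
        except ValueError:
            try:
                return float(value)
            except ValueError:
                return value

    run_fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    run_kw: dict = {}
    sim_kw: dict = {}
    for key, value in raw.items():
        if key.startswith("sim."):
            name = key[4:]
            if name not in sim_fields:
                raise ValueError(f"unknown simulation key {key!r}")
            sim_kw[name] = convert(value, None)
        elif key in run_fields:
            typ = {"outdir": str, "matrix": str, "metadata": str,
                   "simulate": bool, "run_qc": bool, "alpha": float,
                   "correction": str, "null_mode": str}.get(key, int)
            run_kw[key] = convert(value, typ)
        else:
            raise ValueError(f"unknown config key {key!r}")
    if sim_kw:
        run_kw["sim"] = SimulationConfig(**sim_kw)
    return RunConfig(**run_kw)


def summarize_counts(results) -> pd.DataFrame:
    """Stage-count table: genes per stage plus direction percentages."""
    counts = results.stage_counts
    pct = results.direction_percentages
    total = max(counts["total_genes"], 1)
    rows = []
    for key in ("total_genes", "age_related", "divergent", "codirectional",
                "heterochrony_tested", "significant_heterochronic"):
        rows.append({"stage": key, "genes": int(counts[key]),
                     "fraction_of_total": counts[key] / total})
    n_sig = max(counts["significant_heterochronic"], 1)
    for key in ("A_accelerated", "B_accelerated"):
        rows.append({"stage": key, "genes": int(counts[key]),
                     "fraction_of_total": counts[key] / total,
                     "percent_of_significant": float(
                         pct[key.replace("-", "_")])})
    return pd.DataFrame(rows).set_index("stage")


def _downstream_tables(ds: ExpressionDataset, results, config: RunConfig):
    """Variance F-tests, gene clusters and the sample partition for the
    significant heterochronic genes."""
    genes = list(results.significant_genes)
    tables: dict[str, pd.DataFrame] = {}
    if not genes:
        return tables
    var_rows = []
    curves = []
    a_level, b_level = ds.group_levels
    for gene in genes:
        aa, ya, ab, yb = ds.group_arrays(gene)
        fit_a = fit_best_polynomial(aa, ya, max_degree=config.max_degree)
        fit_b = fit_best_polynomial(ab, yb, max_degree=config.max_degree)
        try:
            vt = variance_f_test(ya, yb, aa, ab, fit_a, fit_b)
            var_rows.append({
                "gene": gene, "F": vt.F,
                "p_A_greater": vt.p_a_greater, "p_B_greater": vt.p_b_greater,
            })
        except ValueError as exc:
            var_rows.append({"gene": gene, "F": np.nan,
                             "p_A_greater": np.nan, "p_B_greater": np.nan,
                             "reason": str(exc)})
        grid = _overlap_grid(aa, ab, 50)
        c = np.concatenate([fit_a.predict(grid), fit_b.predict(grid)])
        curves.append(c)
    tables["variance"] = pd.DataFrame(var_rows).set_index("gene")
    feat = pd.DataFrame(np.asarray(curves), index=pd.Index(genes, name="gene"))
    k = min(config.k_gene_clusters, len(genes))
    tables["gene_clusters"] = cluster_genes(feat, k).to_frame()
    if len(genes) >= 10:
        boot = bootstrap_cluster_samples(ds.subset_genes(genes),
                                         n_boot=config.n_boot,
                                         seed=config.seed,
                                         detrend_ages=ds.ages)
        part = boot.partition.to_frame()
        part["stability"] = boot.stability
        tables["sample_partition"] = part
        tables["coassignment"] = boot.coassignment
    return tables


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict with results and written paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    paths: dict[str, Path] = {}
    try:
        if config.simulate:
            logger.info("simulating dataset: %s", config.sim)
            ds, truth = generate(config.sim)
            paths.update(write_dataset(ds, outdir))
            paths["truth"] = write_truth(truth, outdir / "truth.tsv")
        else:
            logger.info("reading dataset: %s / %s", config.matrix,
                        config.metadata)
            ds = read_dataset(matrix=config.matrix, metadata=config.metadata)
            truth = None

        if config.run_qc:
            logger.info("sample QC (extreme-gene outlier screen)")
            qc = detect_outliers(ds)
            write_qc_report(qc, outdir / "qc.tsv")
            paths["qc"] = outdir / "qc.tsv"
            n_flag = int(qc["outlier_flag"].sum())
            logger.info("QC flagged %d samples", n_flag)

        model = HeterochronyModel(
            ds, alpha=config.alpha, max_degree=config.max_degree,
            n_grid=config.n_grid, slack=config.slack, n_null=config.n_null,
            null_mode=config.null_mode, correction=config.correction,
        )
        logger.info("cascade + heterochrony test (seed=%d)", config.seed)
        results = model.fit(seed=config.seed, threads=config.threads)
        paths.update(results.save(outdir))

        counts = summarize_counts(results)
        counts.to_csv(outdir / "stage_summary.tsv", sep="\t",
                      float_format=_FLOAT_FMT)
        paths["stage_summary"] = outdir / "stage_summary.tsv"
        logger.info("stage counts: %s", results.stage_counts.to_dict())

        for name, table in _downstream_tables(ds, results, config).items():
            p = outdir / f"{name}.tsv"
            table.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
            paths[name] = p

        manifest = {
            "version": __version__,
            "config": _config_dict(config),
            "stage_counts": {k: int(v) for k, v in
                             results.stage_counts.items()},
            "direction_percent": {k: float(v) for k, v in
                                  results.direction_percentages.items()},
            "outputs": {k: Path(v).name for k, v in sorted(paths.items())},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        paths["manifest"] = outdir / "manifest.json"
        return {"dataset": ds, "truth": truth, "results": results,
                "summary": counts, "paths": paths}
    finally:
        logger.removeHandler(handler)
        handler.close()


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    sim = d.pop("sim")
    sim = {k: (list(v) if isinstance(v, tuple) else v) for k, v in sim.items()}
    d["sim"] = sim if config.simulate else None
    return d
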