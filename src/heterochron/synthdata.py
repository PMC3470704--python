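"""Synthetic two-group expression age-series with known planted structure.

The generator emulates the structure of a bulk-brain expression age-series:
~10-15k genes measured in ~20 individuals per group with ages spanning
roughly 20-99 years. A configurable fraction of genes follows polynomial
age trajectories (degree 1-3); a sub-fraction of those diverges between the
two groups, and a sub-fraction of the divergent genes is heterochronic,
i.e. the two groups share the same trajectory shape but differ in timing:

* ``onset-shift`` genes: group A follows ``f(age + shift)`` while group B
  follows ``f(age)`` -- parallel curves, displaced along the age axis;
* ``rate-scale`` genes: group A follows ``f(age_min + k*(age - age_min))``
  with ``k`` chosen so the planted shift is realized at the age-span
  midpoint -- the curves coincide at the youngest age and diverge with age.

A positive ``true_shift`` means group A is accelerated (it reaches group
B's older-age expression states at a younger age). Every planted property
is emitted in a ground-truth table for recovery and error-rate tests.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

__all__ = [
    "SimulationConfig",
    "generate",
    "write_truth",
    "read_truth",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic age-series generator.

    Defaults emulate the study design the generator is modelled on:
    ~20 individuals per group with ages between 20 and 99 years, with
    roughly 40% of genes age-related, ~38% of those divergent between
    groups, 27% of divergent genes heterochronic, and a 98% bias of the
    planted acceleration toward group A.
    """

    n_genes: int = 12000
    n_per_group: int = 20
    age_min: float = 20.0
    age_max: float = 99.0
    age_sampling: str = "uniform"          # "uniform" | "from_list"
    age_list: tuple | None = None          # used when age_sampling == "from_list"
    frac_age_related: float = 0.40
    frac_divergent_given_age_related: float = 0.38
    frac_heterochronic_given_divergent: float = 0.27
    direction_bias: float = 0.98           # P(planted shift accelerates group A)
    shift_years: float | tuple = (5.0, 20.0)   # fixed value or (lo, hi) uniform
    heterochrony_mode_mix: float = 0.5     # P(onset-shift) vs rate-scale
    trajectory_degree_weights: tuple = (0.0, 0.6, 0.25, 0.15)
    signal_amplitude: float = 1.0          # SD of noiseless trajectory over ages
    noise_sd: float = 0.25                 # per-observation Gaussian SD
    divergence_offset: float | None = None  # default 0.5 * signal_amplitude
    frac_variance_inflated: float = 0.0
    variance_inflation_factor: float = 2.0  # variance ratio (group A inflated)
    subpopulation_fraction: float = 0.0    # fraction of group-A samples shifted
    baseline_mean: float = 7.0             # log2-scale baseline expression
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = {
            "frac_age_related": self.frac_age_related,
            "frac_divergent_given_age_related": self.frac_divergent_given_age_related,
            "frac_heterochronic_given_divergent": self.frac_heterochronic_given_divergent,
            "direction_bias": self.direction_bias,
            "heterochrony_mode_mix": self.heterochrony_mode_mix,
            "frac_variance_inflated": self.frac_variance_inflated,
            "subpopulation_fraction": self.subpopulation_fraction,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.variance_inflation_factor < 1:
            raise ValueError("variance_inflation_factor must be >= 1")
        if self.n_per_group < 4:
            raise ValueError(
                "n_per_group must be >= 4 (degree-3 + intercept models need it)"
            )
        if self.age_sampling not in ("uniform", "from_list"):
            raise ValueError("age_sampling must be 'uniform' or 'from_list'")
        if self.age_sampling == "from_list":
            if self.age_list is None or len(self.age_list) != self.n_per_group:
                raise ValueError("age_list must supply n_per_group ages")
        w = np.asarray(self.trajectory_degree_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or w[1:].sum() <= 0:
            raise ValueError(
                "trajectory_degree_weights must be 4 non-negative weights with "
                "positive mass on degrees 1-3"
            )

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _sample_shift(rng: np.random.Generator, spec) -> float:
    if np.isscalar(spec):
        return float(spec)
    lo, hi = spec
    return float(rng.uniform(lo, hi))


def _base_polynomial(rng: np.random.Generator, degree: int,
                     amplitude: float) -> np.ndarray:
    """Coefficients (intercept first) in the scaled-age basis u in [-1, 1],
    rescaled so the trajectory SD over uniform ages equals ``amplitude``."""
    if degree == 0:
        return np.zeros(1)
    u = np.linspace(-1.0, 1.0, 201)
    while True:
        coefs = np.concatenate([[0.0], rng.normal(0.0, 1.0, degree)])
        vals = np.polynomial.polynomial.polyval(u, coefs)
        sd = vals.std()
        if sd > 1e-8:
            return coefs * (amplitude / sd)


def generate(config: SimulationConfig):
    """Generate a two-group dataset with planted structure.

    Returns
    -------
    ds : ExpressionDataset
        Groups labelled ``"A"`` and ``"B"``; A receives planted acceleration
        when the direction bias applies.
    truth : pandas.DataFrame
        One row per gene: ``is_age_related``, ``is_divergent``,
        ``is_heterochronic``, ``true_mode``, ``true_shift`` (years, signed;
        positive = A accelerated), ``trajectory_degree``,
        ``base_coefficients`` (scaled-age basis, intercept first). The
        attribute ``truth.attrs["subpopulation_samples"]`` lists the group-A
        samples belonging to the shifted subpopulation, if any.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_group
    mid = 0.5 * (cfg.age_min + cfg.age_max)
    half = 0.5 * (cfg.age_max - cfg.age_min)

    if cfg.age_sampling == "uniform":
        ages_a = np.sort(rng.uniform(cfg.age_min, cfg.age_max, n))
        ages_b = np.sort(rng.uniform(cfg.age_min, cfg.age_max, n))
    else:
        ages_a = np.asarray(cfg.age_list, dtype=float)
        ages_b = ages_a.copy()

    g = cfg.n_genes
    is_age = rng.random(g) < cfg.frac_age_related
    is_div = is_age & (rng.random(g) < cfg.frac_divergent_given_age_related)
    is_het = is_div & (rng.random(g) < cfg.frac_heterochronic_given_divergent)

    w = np.asarray(cfg.trajectory_degree_weights, dtype=float)[1:]
    w = w / w.sum()
    degrees = np.where(is_age, rng.choice([1, 2, 3], size=g, p=w), 0)

    # subpopulation of group A receiving the planted acceleration
    n_sub = int(round(cfg.subpopulation_fraction * n))
    sub_idx = np.sort(rng.permutation(n)[:n_sub]) if n_sub else np.array([], int)
    sub_mask = np.zeros(n, dtype=bool)
    sub_mask[sub_idx] = True

    offset_mag = (cfg.divergence_offset if cfg.divergence_offset is not None
                  else 0.5 * cfg.signal_amplitude)

    inflated = rng.random(g) < cfg.frac_variance_inflated
    infl_sd = cfg.noise_sd * np.sqrt(cfg.variance_inflation_factor)

    u_a = (ages_a - mid) / half
    u_b = (ages_b - mid) / half

    vals = np.empty((g, 2 * n))
    modes = np.full(g, "none", dtype=object)
    shifts = np.zeros(g)
    coef_list = []
    polyval = np.polynomial.polynomial.polyval

    for i in range(g):
        d = int(degrees[i])
        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
        coefs = _base_polynomial(rng, d, cfg.signal_amplitude)
        coef_list.append(coefs)
        mean_b = baseline + polyval(u_b, coefs)
        if is_het[i]:
            delta = _sample_shift(rng, cfg.shift_years)
            if rng.random() >= cfg.direction_bias:
                delta = -delta
            shifts[i] = delta
            onset = rng.random() < cfg.heterochrony_mode_mix
            modes[i] = "onset-shift" if onset else "rate-scale"
            if onset:
                shifted_ages = ages_a + delta
            else:
                k = 1.0 + delta / (mid - cfg.age_min)
                shifted_ages = cfg.age_min + k * (ages_a - cfg.age_min)
            u_shift = (shifted_ages - mid) / half
            accel = baseline + polyval(u_shift, coefs)
            if n_sub:
                mean_a = baseline + polyval(u_a, coefs)
                mean_a[sub_mask] = accel[sub_mask]
            else:
                mean_a = accel
        elif is_div[i]:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            mean_a = baseline + polyval(u_a, coefs) + sign * offset_mag
        else:
            mean_a = baseline + polyval(u_a, coefs)
        noise = rng.normal(0.0, 1.0, 2 * n)
        sd_a = infl_sd if inflated[i] else cfg.noise_sd
        vals[i, :n] = mean_a + sd_a * noise[:n]
        vals[i, n:] = mean_b + cfg.noise_sd * noise[n:]

    width = len(str(g))
    gene_ids = [f"g{j + 1:0{width}d}" for j in range(g)]
    sample_ids = [f"A{j + 1:03d}" for j in range(n)] + [
        f"B{j + 1:03d}" for j in range(n)
    ]
    values = pd.DataFrame(vals, index=gene_ids, columns=sample_ids)
    ages = pd.Series(np.concatenate([ages_a, ages_b]), index=sample_ids)
    groups = pd.Series(["A"] * n + ["B"] * n, index=sample_ids)
    ds = ExpressionDataset(values, ages, groups)

    truth = pd.DataFrame(
        {
            "is_age_related": is_age,
            "is_divergent": is_div,
            "is_heterochronic": is_het,
            "true_mode": modes,
            "true_shift": shifts,
            "trajectory_degree": degrees,
            "base_coefficients": coef_list,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    truth.attrs["subpopulation_samples"] = [sample_ids[j] for j in sub_idx]
    return ds, truth


def write_truth(truth: pd.DataFrame, path) -> Path:
    """Write the ground-truth table as tab-delimited text."""
    path = Path(path)
    out = truth.copy()
    out["base_coefficients"] = [
        ";".join(f"{c:.15g}" for c in np.atleast_1d(c))
        for c in out["base_coefficients"]
    ]
    out.to_csv(path, sep="\t", float_format="%.15g")
    return path


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col=0)
    truth["base_coefficients"] = [
        np.array([float(x) for x in s.split(";")])
        for s in truth["base_coefficients"]
    ]
    return truth
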