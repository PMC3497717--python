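"""Reproducible convergence and comparison studies.

Each study builds reduced networks over a sweep of node counts (or grid
levels), measures the collective period or a Hopf location, compares
against a documented high-resolution reference computed the same way,
and returns a tidy :class:`pandas.DataFrame` plus a metadata dict with
fitted log-log convergence slopes.  Everything is determined by the
configuration and explicit seeds, so re-running reproduces the tables
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bifurcation import locate_hopf
from .dynamics import find_period
from .grids import HeterogeneityAxis, grid_to_parameters, smolyak_grid, tensor_product
from .model import ModelParameters, NeuronParameterTable
from .quadrature import (
    hermite_rule,
    inverse_cdf_rule,
    legendre_rule,
    make_rule,
    midpoint_rule,
    monte_carlo_rule,
)

__all__ = [
    "ExperimentConfig",
    "fit_loglog_slope",
    "study_period_convergence",
    "study_hopf_convergence",
    "study_two_parameter_heterogeneity",
    "study_sparse_vs_full",
    "FOUR_PARAMETER_AXES",
]

logger = logging.getLogger("hetosc.experiments")

#: The four-parameter heterogeneity benchmark used for the sparse-vs-full
#: comparison: every parameter independently uniform over its range.
FOUR_PARAMETER_AXES = (
    ("Iapp", 17.5, 32.5),
    ("gNa", 2.55, 3.05),
    ("Vsyn", -1.0, 1.0),
    ("VNa", 49.0, 51.0),
)


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment run.

    Only the fields a given study consumes matter for that study; the
    round-trip contract (``from_dict(to_dict(c)) == c``) holds for all
    of them.
    """

    name: str = "experiment"
    Im: float = 17.5
    Is: float = 7.5
    sigma: float = 0.25
    n_mu: int = 10
    parameter_overrides: dict = field(default_factory=dict)
    n_values: list = field(default_factory=lambda: [10, 20, 40, 80])
    m_values: list = field(default_factory=lambda: [2, 4, 8, 16, 32])
    seeds: list = field(default_factory=lambda: list(range(10)))
    levels: list = field(default_factory=lambda: [0, 1, 2, 3])
    tensor_n_values: list = field(default_factory=lambda: [2, 3, 4])
    ref_n: int = 200
    ref_m: int = 60
    ref_level: int = 4
    abs_tol: float = 1e-10
    rel_tol: float = 1e-12
    upper_bracket: tuple = (30.0, 36.0)
    lower_bracket: tuple = (4.0, 8.0)
    out_dir: Optional[str] = None

    def params(self) -> ModelParameters:
        return ModelParameters().with_overrides(**self.parameter_overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["upper_bracket"] = list(d["upper_bracket"])
        d["lower_bracket"] = list(d["lower_bracket"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("upper_bracket", "lower_bracket"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        if path.suffix == ".toml":
            import tomllib

            return cls.from_dict(tomllib.loads(text))
        if path.suffix == ".json":
            return cls.from_dict(json.loads(text))
        raise ValueError(f"unsupported config format: {path.suffix}")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def fit_loglog_slope(
    n_values: Sequence[float],
    errors: Sequence[float],
    floor: Optional[float] = None,
) -> tuple[float, list[int]]:
    """OLS slope of log10(error) against log10(N).

    Points with error at or below ``floor`` (saturated by reference or
    integration error) are excluded; the indices actually used are
    returned alongside the slope.
    """
    n_values = np.asarray(n_values, dtype=float)
    errors = np.asarray(errors, dtype=float)
    mask = errors > 0
    if floor is not None:
        mask &= errors > floor
    used = np.flatnonzero(mask)
    if used.size < 2:
        raise ValueError("fewer than two usable points for the slope fit")
    slope = np.polyfit(np.log10(n_values[used]), np.log10(errors[used]), 1)[0]
    return float(slope), used.tolist()


def _iapp_table(rule, params: ModelParameters, Im: float, Is: float) -> NeuronParameterTable:
    return NeuronParameterTable.from_parameters(
        params, rule.weights, Iapp=Im + Is * rule.nodes
    )


# ---------------------------------------------------------------------------
# Period convergence in one heterogeneous parameter
# ---------------------------------------------------------------------------

def study_period_convergence(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Period error versus node count for midpoint and Gauss-Legendre rules.

    The reference period is a Gauss-Legendre run at ``config.ref_n``
    nodes; its own error is estimated from a half-resolution run and
    points saturated below 10x that estimate are excluded from slope
    fits.
    """
    params = config.params()
    kw = dict(abs_tol=config.abs_tol, rel_tol=config.rel_tol)

    def period_at(rule) -> float:
        table = _iapp_table(rule, params, config.Im, config.Is)
        return find_period(table, **kw).period

    ref = period_at(legendre_rule(config.ref_n))
    ref_check = period_at(legendre_rule(max(config.ref_n // 2, 2)))
    ref_err = abs(ref - ref_check)
    floor = 10.0 * max(ref_err, 1e-12)
    logger.info("reference period %.12f (est. error %.2e)", ref, ref_err)

    rows = []
    for N in config.n_values:
        for kind, rule in (("midpoint", midpoint_rule(N)), ("gauss_legendre", legendre_rule(N))):
            period = period_at(rule)
            rows.append(
                {"rule": kind, "N": N, "period": period, "abs_error": abs(period - ref)}
            )
            logger.debug("%s N=%d period=%.12f", kind, N, period)
    df = pd.DataFrame(rows)

    meta = {
        "reference_period": ref,
        "reference_n": config.ref_n,
        "reference_error_estimate": ref_err,
        "saturation_floor": floor,
        "slopes": {},
        "slope_points": {},
    }
    for kind in ("midpoint", "gauss_legendre"):
        sub = df[df["rule"] == kind]
        try:
            slope, used = fit_loglog_slope(sub["N"], sub["abs_error"], floor)
            meta["slopes"][kind] = slope
            meta["slope_points"][kind] = used
        except ValueError:
            meta["slopes"][kind] = None
            meta["slope_points"][kind] = []
    return df, meta


# ---------------------------------------------------------------------------
# Hopf-location convergence
# ---------------------------------------------------------------------------

def study_hopf_convergence(
    config: ExperimentConfig, which: str = "both"
) -> tuple[pd.DataFrame, dict]:
    """Hopf-location error versus node count for both quadrature rules.

    ``which`` selects the ``"upper"`` or ``"lower"`` Hopf point (or
    ``"both"``).  References are Gauss-Legendre at ``config.ref_n``.
    """
    params = config.params()
    brackets = {"upper": tuple(config.upper_bracket), "lower": tuple(config.lower_bracket)}
    if which == "both":
        targets = ("upper", "lower")
    elif which in brackets:
        targets = (which,)
    else:
        raise ValueError(f"which must be 'upper', 'lower' or 'both', got {which!r}")

    def hopf_at(rule, point: str) -> float:
        factory = lambda Im: _iapp_table(rule, params, Im, config.Is)
        return locate_hopf(factory, brackets[point]).parameter

    meta = {"references": {}, "slopes": {}, "slope_points": {}, "reference_n": config.ref_n}
    rows = []
    for point in targets:
        ref = hopf_at(legendre_rule(config.ref_n), point)
        ref_check = hopf_at(legendre_rule(max(config.ref_n // 2, 2)), point)
        ref_err = abs(ref - ref_check)
        floor = 10.0 * max(ref_err, 2e-6)  # never below the bisection width
        meta["references"][point] = ref
        for N in config.n_values:
            for kind, rule in (
                ("midpoint", midpoint_rule(N)),
                ("gauss_legendre", legendre_rule(N)),
            ):
                im_star = hopf_at(rule, point)
                rows.append(
                    {
                        "point": point,
                        "rule": kind,
                        "N": N,
                        "Im_star": im_star,
                        "abs_error": abs(im_star - ref),
                    }
                )
        df_point = pd.DataFrame([r for r in rows if r["point"] == point])
        for kind in ("midpoint", "gauss_legendre"):
            sub = df_point[df_point["rule"] == kind]
            key = f"{point}_{kind}"
            try:
                slope, used = fit_loglog_slope(sub["N"], sub["abs_error"], floor)
                meta["slopes"][key] = slope
                meta["slope_points"][key] = used
            except ValueError:
                meta["slopes"][key] = None
                meta["slope_points"][key] = []
    return pd.DataFrame(rows), meta


# ---------------------------------------------------------------------------
# Second heterogeneous parameter (normal gNa): MC vs inverse-CDF vs Hermite
# ---------------------------------------------------------------------------

def study_two_parameter_heterogeneity(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Period error versus M for three choices of normal-direction nodes.

    Applied current stays uniform (Gauss-Legendre, ``config.n_mu``
    nodes, Iapp = Im + Is*mu) while gNa = 2.8 + sigma*lambda is sampled
    with M Monte Carlo draws, M inverse-CDF quantiles, or M
    Gauss-Hermite nodes.  The reference uses Gauss-Hermite at
    ``config.ref_m``.  Monte Carlo runs are repeated over
    ``config.seeds`` and their absolute errors averaged.
    """
    params = config.params()
    mu_rule = legendre_rule(config.n_mu)
    kw = dict(abs_tol=config.abs_tol, rel_tol=config.rel_tol)
    gna_mean = params.gNa

    def period_with(lambda_rule) -> float:
        grid = tensor_product([mu_rule, lambda_rule])
        table = NeuronParameterTable.from_parameters(
            params,
            grid.weights,
            Iapp=config.Im + config.Is * grid.nodes[:, 0],
            gNa=gna_mean + config.sigma * grid.nodes[:, 1],
        )
        return find_period(table, **kw).period

    ref = period_with(hermite_rule(config.ref_m))
    ref_check = period_with(hermite_rule(max(config.ref_m // 2, 2)))
    ref_err = abs(ref - ref_check)
    floor = 10.0 * max(ref_err, 1e-12)
    logger.info("two-parameter reference period %.12f (est. error %.2e)", ref, ref_err)

    rows = []
    for M in config.m_values:
        for seed in config.seeds:
            p = period_with(monte_carlo_rule(M, seed=int(seed)))
            rows.append(
                {"method": "monte_carlo", "M": M, "seed": int(seed),
                 "period": p, "abs_error": abs(p - ref)}
            )
        p = period_with(inverse_cdf_rule(M))
        rows.append(
            {"method": "inverse_cdf", "M": M, "seed": -1, "period": p,
             "abs_error": abs(p - ref)}
        )
        p = period_with(hermite_rule(M))
        rows.append(
            {"method": "gauss_hermite", "M": M, "seed": -1, "period": p,
             "abs_error": abs(p - ref)}
        )
    df = pd.DataFrame(rows)

    meta = {
        "reference_period": ref,
        "reference_m": config.ref_m,
        "reference_error_estimate": ref_err,
        "saturation_floor": floor,
        "error_averaging": "absolute errors averaged over seeds",
        "slopes": {},
        "slope_points": {},
    }
    for method in ("monte_carlo", "inverse_cdf", "gauss_hermite"):
        mean_err = (
            df[df["method"] == method].groupby("M")["abs_error"].mean().sort_index()
        )
        try:
            slope, used = fit_loglog_slope(mean_err.index, mean_err.values, floor)
            meta["slopes"][method] = slope
            meta["slope_points"][method] = used
        except ValueError:
            meta["slopes"][method] = None
            meta["slope_points"][method] = []
    return df, meta


# ---------------------------------------------------------------------------
# Four heterogeneous parameters: sparse versus full tensor grids
# ---------------------------------------------------------------------------

def four_parameter_axes(n_nodes: int = 2) -> list[HeterogeneityAxis]:
    """The four uniform heterogeneity axes of the high-dimensional study."""
    return [
        HeterogeneityAxis.uniform_range(name, lo, hi, n_nodes=n_nodes)
        for name, lo, hi in FOUR_PARAMETER_AXES
    ]


def study_sparse_vs_full(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Period error versus neuron count for tensor and Smolyak grids.

    Four independent uniformly distributed parameters (applied current,
    sodium conductance, synaptic and sodium reversal potentials).  Full
    grids use N nodes per direction (N^4 neurons); sparse grids use the
    nested-size Gauss-Legendre family.  The reference is a sparse grid
    at ``config.ref_level``.
    """
    params = config.params()
    axes = four_parameter_axes()
    kw = dict(abs_tol=config.abs_tol, rel_tol=config.rel_tol)

    def period_for(grid) -> float:
        table = grid_to_parameters(grid, params, axes)
        return find_period(table, **kw).period

    ref_grid = smolyak_grid(config.ref_level, 4)
    ref = period_for(ref_grid)
    logger.info(
        "sparse-vs-full reference period %.12f from level-%d grid (%d nodes)",
        ref, config.ref_level, ref_grid.n_nodes,
    )

    rows = []
    for N in config.tensor_n_values:
        grid = tensor_product([legendre_rule(N)] * 4)
        p = period_for(grid)
        rows.append(
            {"kind": "tensor", "label": f"{N}^4", "n_nodes": grid.n_nodes,
             "period": p, "abs_error": abs(p - ref)}
        )
    for L in config.levels:
        grid = smolyak_grid(L, 4)
        p = period_for(grid)
        rows.append(
            {"kind": "smolyak", "label": f"A({L},4)", "n_nodes": grid.n_nodes,
             "period": p, "abs_error": abs(p - ref)}
        )
    df = pd.DataFrame(rows)
    meta = {
        "reference_period": ref,
        "reference_level": config.ref_level,
        "reference_n_nodes": int(ref_grid.n_nodes),
        "axes": [
            {"parameter": name, "low": lo, "high": hi} for name, lo, hi in FOUR_PARAMETER_AXES
        ],
    }
    return df, meta


def write_study(
    df: pd.DataFrame, meta: dict, out_dir: str | Path, name: str
) -> None:
    """Emit a study's CSV table and JSON metadata under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    (out / f"{name}.json").write_text(json.dumps(meta, indent=2, default=float))
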