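"""Batch experiment runner: scenario grids over many stochastic
architectures, aggregation, hypothesis tests, sensitivity analysis and the
cardiac-phase study.

Seeding: architecture ``i`` of a batch uses ``master_seed + i``; everything
downstream of the architecture is deterministic for a given pressure set, so
a rerun with the same master seed reproduces the table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .errors import ParameterError
from .metrics import egress_closure, ingress_filling, percent_filling, \
    nidus_risk_summary
from .network import attach_nidus, build_extranidal_template, \
    vessel_resistance
from .nidus import sample_architecture
from .scenarios import PressureSet, phase_grid, standard_grid
from .solver import solve, total_nidal_flow

RESULT_COLUMNS = [
    "arch_seed", "n_vessels", "hypotension", "cvp", "tbo", "site",
    "injection_mmHg", "phase", "total_flow_ml_min", "pct_filling",
    "pct_filling_ingress", "mean_risk_pct", "max_risk_pct",
]


def _parent_key(s: PressureSet):
    return (s.hypotension_level, s.cvp_level, s.tbo, s.phase)


def simulate_architecture(arch_seed: int, template,
                          sets: Sequence[PressureSet],
                          config: SimulationConfig) -> list[dict]:
    """Run every pressure set against one freshly generated architecture."""
    arch = sample_architecture(arch_seed, config)
    net = attach_nidus(template, arch)

    baselines = {_parent_key(s): i for i, s in enumerate(sets)
                 if s.injection is None}
    extra = []
    for s in sets:
        if s.injection is not None and _parent_key(s) not in baselines:
            baselines[_parent_key(s)] = len(sets) + len(extra)
            extra.append(s.baseline_parent())
    solutions = solve(net, list(sets) + extra)

    rows = []
    for s, sol in zip(sets, solutions):
        mean_risk, max_risk = nidus_risk_summary(sol, arch, config.risk)
        row = {
            "arch_seed": arch_seed,
            "n_vessels": arch.n_vessels,
            "hypotension": s.hypotension_level,
            "cvp": s.cvp_level,
            "tbo": s.tbo or "none",
            "site": s.injection[0] if s.injection else "none",
            "injection_mmHg": s.injection[1] if s.injection else 0.0,
            "phase": s.phase,
            "total_flow_ml_min": total_nidal_flow(sol),
            "pct_filling": np.nan,
            "pct_filling_ingress": np.nan,
            "mean_risk_pct": mean_risk,
            "max_risk_pct": max_risk,
        }
        if s.injection is not None:
            parent = solutions[baselines[_parent_key(s)]]
            ingress = ingress_filling(sol, s.injection[0])
            final = egress_closure(parent, ingress)
            row["pct_filling_ingress"] = percent_filling(ingress, arch)
            row["pct_filling"] = percent_filling(final, arch)
        rows.append(row)
    return rows


def run_sets(n_architectures: int, seed: int, sets: Sequence[PressureSet],
             config: SimulationConfig | None = None,
             progress: Optional[Callable[[int], None]] = None
             ) -> pd.DataFrame:
    """Run a list of pressure sets over ``n_architectures`` architectures."""
    if n_architectures < 1:
        raise ParameterError("n_architectures must be >= 1")
    config = config or SimulationConfig()
    template = build_extranidal_template(config)
    rows: list[dict] = []
    for i in range(n_architectures):
        rows.extend(simulate_architecture(seed + i, template, sets, config))
        if progress is not None:
            progress(i + 1)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_main_grid(n_architectures: int, seed: int,
                  config: SimulationConfig | None = None,
                  progress: Optional[Callable[[int], None]] = None
                  ) -> pd.DataFrame:
    """The 320-set standard grid over many architectures
    (n x 320 result rows; n = 1139 reproduces the full published design)."""
    config = config or SimulationConfig()
    return run_sets(n_architectures, seed, standard_grid(config), config,
                    progress)


def aggregate(table: pd.DataFrame, group_by: Sequence[str],
              values: Sequence[str] = ("total_flow_ml_min", "pct_filling",
                                       "mean_risk_pct", "max_risk_pct")
              ) -> pd.DataFrame:
    """Group means, standard deviations and group sizes.

    Returns one row per group with ``<value>_mean``, ``<value>_sd`` columns
    and an ``n`` column (the per-bar sample size of the corresponding chart).
    """
    if table.empty:
        raise ParameterError("cannot aggregate an empty table")
    for colset in (group_by, values):
        for col in colset:
            if col not in table.columns:
                raise ParameterError(f"unknown column {col!r}")
    grouped = table.groupby(list(group_by), observed=True)
    out = grouped[list(values)].agg(["mean", "std"])
    out.columns = [f"{v}_{s}" for v, s in out.columns]
    for v in values:
        out[f"{v}_sd"] = out.pop(f"{v}_std").fillna(0.0)
    out["n"] = grouped.size()
    return out.reset_index()


@dataclass
class TestReport:
    """Result of one statistical comparison (alpha = 0.05)."""

    test: str  # t | anova
    factor: str
    levels: tuple
    group_means: tuple
    group_sizes: tuple
    statistic: float
    df: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare(table: pd.DataFrame, value: str, factor: str,
            fixed: Optional[dict] = None, welch: bool = False) -> TestReport:
    """Compare group means across the levels of one factor.

    With exactly two levels an unpaired two-tailed Student's t-test is used
    (pooled variance by default; ``welch=True`` for unequal variances); with
    three levels a one-way ANOVA.  ``fixed`` restricts the table to rows
    matching the given column values so the groups differ only in ``factor``.
    """
    sub = table
    for col, val in (fixed or {}).items():
        if col not in sub.columns:
            raise ParameterError(f"unknown column {col!r}")
        sub = sub[sub[col] == val]
    if factor not in sub.columns:
        raise ParameterError(f"unknown column {factor!r}")
    levels = sorted(sub[factor].dropna().unique().tolist())
    groups = [sub.loc[sub[factor] == lv, value].dropna().to_numpy()
              for lv in levels]
    if any(len(g) < 2 for g in groups) or len(groups) < 2:
        raise ParameterError(
            "insufficient data: every group needs at least two observations")
    if len(groups) == 2:
        res = stats.ttest_ind(groups[0], groups[1], equal_var=not welch)
        df = float(res.df)
        test = "t"
    elif len(groups) == 3:
        res = stats.f_oneway(*groups)
        df = float(len(groups) - 1)
        test = "anova"
    else:
        raise ParameterError("compare expects two or three groups")
    return TestReport(
        test=test, factor=factor, levels=tuple(levels),
        group_means=tuple(float(g.mean()) for g in groups),
        group_sizes=tuple(len(g) for g in groups),
        statistic=float(res.statistic), df=df, p_value=float(res.pvalue))


def sensitivity_analysis(n_architectures: int = 1000, jitter: float = 0.10,
                         seed: int = 0,
                         config: SimulationConfig | None = None) -> dict:
    """Baseline-flow robustness to vessel-dimension perturbation.

    For each architecture, every vessel's length and radius are resampled
    uniformly within ``+/- jitter`` of their configured values before solving
    the baseline (normotension, normal CVP) state.  Returns the min / mean /
    max total nidal flow (mL/min) and the per-architecture flow array.
    """
    if not 0.0 <= jitter < 0.5:
        raise ParameterError("jitter must lie in [0, 0.5)")
    config = config or SimulationConfig()
    template = build_extranidal_template(config)
    baseline = standard_grid(config)[0]
    rng = np.random.default_rng(seed)
    flows = np.empty(n_architectures)
    for i in range(n_architectures):
        arch = sample_architecture(seed + i, config)
        net = attach_nidus(template, arch)
        if jitter > 0:
            for v in net.vessels.values():
                v.length *= rng.uniform(1 - jitter, 1 + jitter)
                v.radius *= rng.uniform(1 - jitter, 1 + jitter)
                v.resistance = vessel_resistance(v.length, v.radius,
                                                 config.viscosity)
            net._cache.clear()
        flows[i] = total_nidal_flow(solve(net, baseline)[0])
    return {"min": float(flows.min()), "mean": float(flows.mean()),
            "max": float(flows.max()), "flows": flows}


def phase_study(n_architectures: int = 61, seed: int = 0,
                config: SimulationConfig | None = None,
                hypotension_levels: Sequence[str] = ("mild", "moderate",
                                                     "profound"),
                injection_pressures: Sequence[float] | None = None
                ) -> pd.DataFrame:
    """Cardiac-phase study: filling vs injection pressure per phase, at
    normal CVP with DV1 injections."""
    config = config or SimulationConfig()
    sets = phase_grid(config, hypotension_levels=hypotension_levels,
                      injection_pressures=injection_pressures)
    return run_sets(n_architectures, seed, sets, config)
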