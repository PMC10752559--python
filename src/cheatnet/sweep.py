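"""Parameter sweep over cheating configurations, with matched baselines.

The theoretical experiment crosses the four cheating parameters
(proportion of cheaters, cheating frequency, innovative fraction, cost
of mutualism) with two cheater-identity scenarios, three backbone
connectances and many seeded communities.  Every cheating run is
differenced against the no-cheating (omega = 0) run of the same
community and cost, so the "effect of cheating" isolates cheating from
community composition.

The full grid is 10 x 11 x 11 x 3 = 3,630 cheating combinations and
500 seeds x 3,630 x 2 scenarios x 3 connectances = 10,890,000 jobs; the
enumerator produces it, and ``run_sweep`` executes any (sub)grid, so
scaled-down replicas are first-class configurations rather than ad-hoc
scripts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cheating import CheatingConfig
from .community import generate_community
from .dynamics import DynamicsParams, integrate_to_equilibrium
from .metrics import bipartite_modularity, connectance, nodf

__all__ = [
    "SweepGrid",
    "enumerate_grid",
    "job_count",
    "run_sweep",
    "variance_explained",
    "center_within",
    "residual_structure_model",
]


def _rnd(values: Iterable[float]) -> tuple[float, ...]:
    return tuple(round(float(v), 10) for v in values)


@dataclass(frozen=True)
class SweepGrid:
    """The experiment grid; defaults reproduce the full production design."""

    delta_bar_values: tuple[float, ...] = _rnd(np.arange(0.1, 1.05, 0.1))
    omega_values: tuple[float, ...] = _rnd(np.arange(0.0, 1.05, 0.1))
    psi_values: tuple[float, ...] = _rnd(np.arange(0.0, 1.05, 0.1))
    lambda_values: tuple[float, ...] = (0.0, 0.15, 0.3)
    scenarios: tuple[str, ...] = ("generalist", "specialist")
    phi_values: tuple[float, ...] = (0.2, 0.3, 0.4)
    n_seeds: int = 500
    n_P: int = 20
    n_A: int = 20
    pollinator_interference: bool = True


def enumerate_grid(grid: SweepGrid) -> list[tuple[float, float, float, float]]:
    """Cartesian product of the cheating parameters (delta_bar, omega, psi, lambda)."""
    return list(
        product(
            grid.delta_bar_values,
            grid.omega_values,
            grid.psi_values,
            grid.lambda_values,
        )
    )


def job_count(grid: SweepGrid) -> int:
    """Total simulation count: seeds x combos x scenarios x connectances."""
    return (
        grid.n_seeds
        * len(enumerate_grid(grid))
        * len(grid.scenarios)
        * len(grid.phi_values)
    )


def run_sweep(
    grid: SweepGrid,
    base_seed: int = 0,
    params: DynamicsParams | None = None,
    structure_metrics: bool = False,
) -> pd.DataFrame:
    """Run every job in the grid and difference against matched baselines.

    One omega=0 baseline is integrated per (seed, phi, lambda) and shared
    across scenarios and the (delta_bar, psi) axes, where omega=0 makes
    the dynamics identical.  Returns a long-format table with one row
    per job, including the baseline persistence and the effect.
    """
    if params is None:
        params = DynamicsParams()
    params = replace(
        params, pollinator_interference=grid.pollinator_interference
    )
    combos = enumerate_grid(grid)
    rows = []
    seeds = [base_seed + i for i in range(grid.n_seeds)]
    for seed in seeds:
        for phi in grid.phi_values:
            com = generate_community(
                n_P=grid.n_P, n_A=grid.n_A, phi=phi, seed=seed
            )
            struct: dict[str, float] = {
                "connectance_realized": connectance(com.IM),
                "mean_r_P": float(com.r_P.mean()),
                "mean_r_A": float(com.r_A.mean()),
            }
            if structure_metrics:
                struct["nodf"] = nodf(com.IM)
                struct["modularity"] = bipartite_modularity(
                    com.IM, seed=seed
                )[0]
            baselines = {}
            for lam in grid.lambda_values:
                cfg0 = CheatingConfig(
                    delta_bar=0.0, omega=0.0, psi=0.0, lambda_cost=lam
                )
                baselines[lam] = integrate_to_equilibrium(com, cfg0, params)
            for scenario in grid.scenarios:
                for delta_bar, omega, psi, lam in combos:
                    base = baselines[lam]
                    if omega == 0.0:
                        res = base
                    else:
                        cfg = CheatingConfig(
                            delta_bar=delta_bar,
                            omega=omega,
                            psi=psi,
                            lambda_cost=lam,
                            scenario=scenario,  # type: ignore[arg-type]
                        )
                        res = integrate_to_equilibrium(com, cfg, params)
                    rows.append(
                        {
                            "seed": seed,
                            "phi": phi,
                            "scenario": scenario,
                            "delta_bar": delta_bar,
                            "omega": omega,
                            "psi": psi,
                            "lambda": lam,
                            "persistence": res.persistence,
                            "baseline_persistence": base.persistence,
                            "effect": res.persistence - base.persistence,
                            "converged": res.converged,
                            "stable": res.stable,
                            "steps": res.steps_used,
                            **struct,
                        }
                    )
    return pd.DataFrame(rows)


def variance_explained(
    results: pd.DataFrame,
    group_cols: Sequence[str] = (
        "delta_bar", "omega", "psi", "lambda", "scenario",
    ),
    value_col: str = "effect",
) -> float:
    """Proportion of variance explained by the grouping: 1 - V_g / V.

    V is the total variance of the effect; V_g the variance of the
    group-mean-centered effects (the residual effects).  Returns NaN
    when the total variance is zero.
    """
    values = results[value_col].to_numpy(dtype=float)
    v_total = values.var()
    if v_total == 0:
        return float("nan")
    centered = values - results.groupby(list(group_cols))[
        value_col
    ].transform("mean").to_numpy(dtype=float)
    return 1.0 - centered.var() / v_total


def center_within(
    df: pd.DataFrame, col: str, by: str = "phi"
) -> pd.Series:
    """Subtract the within-class mean (e.g., nestedness within connectance)."""
    return df[col] - df.groupby(by)[col].transform("mean")


def residual_structure_model(
    results: pd.DataFrame,
    covariates: Sequence[str] = (
        "mean_r_P", "mean_r_A", "connectance_realized", "nodf", "modularity",
    ),
    group_cols: Sequence[str] = (
        "delta_bar", "omega", "psi", "lambda", "scenario",
    ),
    value_col: str = "effect",
    center_by: str = "phi",
) -> pd.DataFrame:
    """OLS of the residual cheating effect on community structure.

    The response is the group-mean-centered effect (parameter and
    scenario combinations removed); nestedness and modularity are
    centered within connectance class to break their correlation with
    connectance.  Returns the coefficient table (estimate, se, t, p).
    """
    df = results.copy()
    df["residual_effect"] = df[value_col] - df.groupby(list(group_cols))[
        value_col
    ].transform("mean")
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        if cov in ("nodf", "modularity") and center_by in df:
            X[cov + "_centered"] = center_within(df, cov, by=center_by)
        else:
            X[cov] = df[cov]
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        cols = list(X.columns)
        for i in range(1, len(cols)):
            sub = X[cols[: i + 1]].to_numpy()
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(cols[i])
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")
    fit = sm.OLS(df["residual_effect"], X).fit()
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
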