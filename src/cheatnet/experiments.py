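"""Canned scaled-down replicas of the production simulation experiments.

The production design integrates 10.89 million communities; these
presets re-run its key measurements at desk scale with seeded RNG:

* ``convergence_rate`` - how often the stopping rule (trailing-window
  abundance variance below 1e-14 or the 8,000-step cap) delivers a
  stable steady state (negative-real-part Jacobian spectrum), sampling
  parameters uniformly from the production grids;
* ``favorable_window_max_effect`` - the ceiling of the average
  persistence gain from cheating inside the favorable window
  (specialist cheaters, no mutualism cost, connectance 0.4, mostly
  innovative cheating at low-to-intermediate frequency).
"""

from __future__ import annotations

import numpy as np

from .cheating import CheatingConfig
from .community import generate_community
from .dynamics import DynamicsParams, integrate_to_equilibrium
from .sweep import SweepGrid, run_sweep

__all__ = [
    "convergence_rate",
    "favorable_window_grid",
    "favorable_window_max_effect",
]

_MAX_SEED = 2 ** 31 - 1


def convergence_rate(
    n_sims: int = 1000,
    seed: int = 0,
    n_P: int = 20,
    n_A: int = 20,
) -> dict:
    """Fraction of random-grid simulations reaching a stable equilibrium.

    Parameters are sampled uniformly from the production grids
    (delta_bar, omega, psi, lambda, scenario, connectance); each
    simulation integrates a fresh seeded community with the standard
    stopping rule and verifies the final state with the Jacobian
    eigenvalue test.
    """
    grid = SweepGrid()
    rng = np.random.default_rng(seed)
    params = DynamicsParams()
    n_stable = n_converged = 0
    for _ in range(n_sims):
        com = generate_community(
            n_P=n_P, n_A=n_A,
            phi=float(rng.choice(grid.phi_values)),
            seed=int(rng.integers(_MAX_SEED)),
        )
        cfg = CheatingConfig(
            delta_bar=float(rng.choice(grid.delta_bar_values)),
            omega=float(rng.choice(grid.omega_values)),
            psi=float(rng.choice(grid.psi_values)),
            lambda_cost=float(rng.choice(grid.lambda_values)),
            scenario=str(rng.choice(grid.scenarios)),  # type: ignore[arg-type]
        )
        res = integrate_to_equilibrium(com, cfg, params)
        n_stable += bool(res.stable)
        n_converged += res.converged
    return {
        "n_sims": n_sims,
        "percent_stable": 100.0 * n_stable / n_sims,
        "percent_variance_rule": 100.0 * n_converged / n_sims,
    }


def favorable_window_grid(n_seeds: int = 50) -> SweepGrid:
    """The sub-grid where cheating is expected to help persistence most:
    specialist cheaters, Lambda = 0, phi = 0.4, mostly-innovative
    cheating (psi 0.8/1.0) at omega 0.2-0.6, delta_bar 0.1/0.3/0.5."""
    return SweepGrid(
        delta_bar_values=(0.1, 0.3, 0.5),
        omega_values=(0.2, 0.3, 0.4, 0.5, 0.6),
        psi_values=(0.8, 1.0),
        lambda_values=(0.0,),
        scenarios=("specialist",),
        phi_values=(0.4,),
        n_seeds=n_seeds,
    )


def favorable_window_max_effect(
    n_seeds: int = 50, base_seed: int = 0
) -> dict:
    """Maximum over combinations of the seed-averaged persistence gain."""
    df = run_sweep(favorable_window_grid(n_seeds), base_seed=base_seed)
    means = df.groupby(["delta_bar", "omega", "psi"])["effect"].mean()
    best = means.idxmax()
    return {
        "n_seeds": n_seeds,
        "max_mean_effect": float(means.max()),
        "argmax": {"delta_bar": best[0], "omega": best[1], "psi": best[2]},
        "n_positive_combinations": int((means > 0).sum()),
        "n_combinations": int(len(means)),
        "per_combination": means,
        "records": df,
    }
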