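"""Generalized Lotka-Volterra dynamics with saturating, interference-laden
functional responses.

Plants (P) and pollinators (A) interact through a legitimate-strength
matrix M and an illegitimate (cheating) strength matrix C.  Per capita:

  dP_i/dt = P_i * ( r_Pi
      + (alpha - Lambda) * sum_j M_ij A_j
          / (1 + beta * sum_j M_ij A_j + c * sum_k Pi_ik P_k)
      - Lambda * sum_j C_ij A_j
          / (1 + beta * sum_j C_ij A_j + c * sum_k Gamma_ik P_k)
      - sum_k cP_ik P_k )

  dA_j/dt = A_j * ( r_Aj
      + sum_i [alpha (M_ij + C_ij) - Lambda M_ij] P_i
          / (1 + beta * sum_i (M_ij + C_ij) P_i + c * sum_k Theta_jk A_k)
      - sum_k cA_jk A_k )

Benefits saturate with handling time ``beta`` and are diluted by
within-guild interference ``c`` weighted by niche-similarity matrices:
Pi (plants sharing pollinators), Gamma (plants sharing cheaters), Theta
(pollinators sharing plants).  Cheaters escape the mutualism cost
``Lambda`` on their cheating interactions; cheated plants still pay it.
Similarity is measured as the cosine overlap of interaction-strength
profiles (rows of M for Pi, rows of C for Gamma, columns of M + C for
Theta), which is 1 for identical niches, 0 for disjoint ones.

Integration starts from abundance 1 for every species and is sampled at
unit time steps; a run stops when the variance of every species'
abundance over the trailing 10 samples drops below 1e-14, or after 8,000
steps.  Species dipping below 1e-9 are clamped to zero (extinction is
absorbing).  Persistence is the percentage of species above 1e-5 at the
final state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import ode
from scipy.linalg import eigvals

from .cheating import CheatingConfig, strength_pair
from .community import Community, assign_cheaters

__all__ = [
    "DynamicsParams",
    "SimilaritySet",
    "EquilibriumResult",
    "similarity_matrices",
    "make_rhs",
    "rhs",
    "integrate_strengths",
    "integrate_to_equilibrium",
    "check_stability",
    "persistence",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Functional-response and integration parameters.

    Defaults follow the standard parameterization: benefit alpha=1.5,
    handling time beta=1, interference c=1, intraspecific
    competition-for-space 1 (identity matrices), no interspecific
    competition for space.
    """

    alpha: float = 1.5
    beta: float = 1.0
    c: float = 1.0
    comp_P: Optional[np.ndarray] = None  # default: identity
    comp_A: Optional[np.ndarray] = None
    pollinator_interference: bool = True  # c in the Theta term of dA/dt
    max_steps: int = 8000
    conv_window: int = 10
    conv_tol: float = 1e-14
    extinct_tol: float = 1e-5
    clamp_tol: float = 1e-9
    rtol: float = 1e-8
    atol: float = 1e-10

    def validate_cost(self, lambda_cost: float) -> None:
        if lambda_cost >= self.alpha:
            raise ValueError(
                f"mutualism requires alpha > Lambda "
                f"(alpha={self.alpha}, Lambda={lambda_cost})"
            )


@dataclass
class SimilaritySet:
    """Within-guild niche-similarity matrices."""

    Pi: np.ndarray      # plants, legitimate niches (rows of M)
    Gamma: np.ndarray   # plants, shared-cheater niches (rows of C)
    Theta: np.ndarray   # pollinators, total-interaction niches (cols of M+C)


@dataclass
class EquilibriumResult:
    abundances: np.ndarray        # concatenated (P, A)
    n_P: int
    converged: bool               # variance rule met before the cap
    stable: Optional[bool]        # Jacobian test at the final state
    persistence: float            # % of species above extinct_tol
    steps_used: int
    trajectory: Optional[np.ndarray] = None  # (steps+1, n) unit-time samples

    def trajectory_tsv(self, path) -> None:
        """Dump the recorded trajectory as a time x species TSV."""
        if self.trajectory is None:
            raise ValueError("run with record_trajectory=True first")
        import pandas as pd

        n_A = self.abundances.size - self.n_P
        cols = [f"P{i}" for i in range(self.n_P)] + \
            [f"A{j}" for j in range(n_A)]
        df = pd.DataFrame(self.trajectory, columns=cols)
        df.insert(0, "time", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)

    @property
    def P(self) -> np.ndarray:
        return self.abundances[: self.n_P]

    @property
    def A(self) -> np.ndarray:
        return self.abundances[self.n_P:]


def _cosine_rows(X: np.ndarray) -> np.ndarray:
    """Cosine similarity between rows; zero rows get 0 off-diag, 1 on diag."""
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    S = (X @ X.T) / np.outer(safe, safe)
    np.fill_diagonal(S, 1.0)
    return np.clip(S, 0.0, 1.0)


def similarity_matrices(M: np.ndarray, C: np.ndarray) -> SimilaritySet:
    """Niche-similarity matrices from the strength pair (M, C)."""
    return SimilaritySet(
        Pi=_cosine_rows(np.asarray(M, dtype=float)),
        Gamma=_cosine_rows(np.asarray(C, dtype=float)),
        Theta=_cosine_rows(np.asarray(M + C, dtype=float).T),
    )


def make_rhs(
    r_P: np.ndarray,
    r_A: np.ndarray,
    M: np.ndarray,
    C: np.ndarray,
    params: DynamicsParams,
    lambda_cost: float,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the time-derivative closure f(t, y), y = concat(P, A).

    The closure supports complex input (for complex-step Jacobians).
    """
    params.validate_cost(lambda_cost)
    n_P, n_A = M.shape
    sim = similarity_matrices(M, C)
    alpha, beta, c = params.alpha, params.beta, params.c
    lam = lambda_cost
    comp_P = np.eye(n_P) if params.comp_P is None else params.comp_P
    comp_A = np.eye(n_A) if params.comp_A is None else params.comp_A
    theta_c = c if params.pollinator_interference else 0.0
    benefit = alpha - lam
    T = M + C
    TT = T.T.copy()
    BA = (alpha * T - lam * M).T.copy()  # pollinator numerator weights
    Pi, Gamma, Theta = sim.Pi, sim.Gamma, sim.Theta
    cheating_active = bool(np.any(C > 0))

    def f(t: float, y: np.ndarray) -> np.ndarray:
        P = y[:n_P]
        A = y[n_P:]
        MA = M @ A
        growth_P = r_P + benefit * MA / (1.0 + beta * MA + c * (Pi @ P)) \
            - comp_P @ P
        if cheating_active and lam != 0.0:
            CA = C @ A
            growth_P = growth_P - lam * CA / (
                1.0 + beta * CA + c * (Gamma @ P)
            )
        TP = TT @ P
        growth_A = r_A + (BA @ P) / (1.0 + beta * TP + theta_c * (Theta @ A)) \
            - comp_A @ A
        return np.concatenate((P * growth_P, A * growth_A))

    return f


def rhs(
    P: np.ndarray,
    A: np.ndarray,
    r_P: np.ndarray,
    r_A: np.ndarray,
    M: np.ndarray,
    C: np.ndarray,
    params: DynamicsParams,
    lambda_cost: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dP/dt, dA/dt) at abundances (P, A)."""
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.isnan(P).any() or np.isnan(A).any():
        raise ValueError("NaN abundances")
    if (P < 0).any() or (A < 0).any():
        raise ValueError("negative abundances")
    f = make_rhs(r_P, r_A, M, C, params, lambda_cost)
    dy = f(0.0, np.concatenate((P, A)))
    return dy[: len(P)], dy[len(P):]


def _complex_step_jacobian(
    f: Callable, y: np.ndarray, h: float = 1e-20
) -> np.ndarray:
    """Jacobian of f at y by complex-step differentiation (exact to O(h^2))."""
    n = len(y)
    J = np.empty((n, n))
    yc = y.astype(complex)
    for k in range(n):
        yk = yc.copy()
        yk[k] += 1j * h
        J[:, k] = np.imag(f(0.0, yk)) / h
    return J


def check_stability(
    abundances: np.ndarray,
    f: Callable[[float, np.ndarray], np.ndarray],
    extinct_tol: float = 1e-5,
    eig_tol: float = 1e-8,
) -> bool:
    """Jacobian eigenvalue test on the surviving-species subsystem.

    Extinct species (abundance <= extinct_tol) are held at their
    absorbing state; stability requires every eigenvalue of the
    surviving-subsystem Jacobian to have real part below ``eig_tol``.
    An all-extinct state is stable (the origin absorbs the dynamics
    when all growth rates are negative).
    """
    y = np.asarray(abundances, dtype=float)
    alive = y > extinct_tol
    if not alive.any():
        return True

    idx = np.flatnonzero(alive)

    def sub(t: float, z: np.ndarray) -> np.ndarray:
        full = y.astype(z.dtype)
        full[idx] = z
        return f(t, full)[idx]

    J = _complex_step_jacobian(sub, y[idx])
    return bool(np.max(eigvals(J).real) < eig_tol)


def persistence(abundances: np.ndarray, extinct_tol: float = 1e-5) -> float:
    """Percent of species strictly above the extinction threshold."""
    y = np.asarray(abundances, dtype=float)
    if y.size == 0:
        raise ValueError("empty abundance vector")
    return 100.0 * float((y > extinct_tol).sum()) / y.size


def integrate_strengths(
    r_P: np.ndarray,
    r_A: np.ndarray,
    M: np.ndarray,
    C: np.ndarray,
    params: DynamicsParams = DynamicsParams(),
    lambda_cost: float = 0.0,
    y0: Optional[np.ndarray] = None,
    record_trajectory: bool = False,
) -> EquilibriumResult:
    """Integrate the system defined by explicit strength matrices.

    Sampling is at unit time steps; the run stops when the per-species
    abundance variance over the trailing window is below ``conv_tol``
    or at ``max_steps``.  Species below ``clamp_tol`` are clamped to
    zero between samples.
    """
    n_P, n_A = M.shape
    n = n_P + n_A
    f = make_rhs(r_P, r_A, M, C, params, lambda_cost)
    y = np.ones(n) if y0 is None else np.asarray(y0, dtype=float).copy()

    solver = ode(f)
    solver.set_integrator(
        "lsoda", rtol=params.rtol, atol=params.atol, nsteps=100000
    )
    solver.set_initial_value(y, 0.0)

    window = params.conv_window
    buf = np.empty((window, n))
    traj = [y.copy()] if record_trajectory else None
    converged = False
    steps = 0
    failed = False
    for step in range(1, params.max_steps + 1):
        solver.integrate(float(step))
        steps = step
        if not solver.successful():
            failed = True
            break
        y = solver.y.copy()
        # absorbing extinction: clamp tiny/negative abundances to zero
        tiny = (y < params.clamp_tol) & (y != 0.0)
        if tiny.any():
            y[tiny] = 0.0
            solver.set_initial_value(y, float(step))
        if traj is not None:
            traj.append(y.copy())
        buf[(step - 1) % window] = y
        if step >= window:
            if np.var(buf, axis=0).max() < params.conv_tol:
                converged = True
                break

    y = np.maximum(y, 0.0)
    stable = None if failed else check_stability(
        y, f, extinct_tol=params.extinct_tol
    )
    return EquilibriumResult(
        abundances=y,
        n_P=n_P,
        converged=converged,
        stable=stable,
        persistence=persistence(y, params.extinct_tol),
        steps_used=steps,
        trajectory=np.asarray(traj) if traj is not None else None,
    )


def integrate_to_equilibrium(
    community: Community,
    config: Optional[CheatingConfig] = None,
    params: DynamicsParams = DynamicsParams(),
) -> EquilibriumResult:
    """Integrate a community under a cheating configuration.

    ``config=None`` (or omega=0) is the pure-mutualism baseline M = IM,
    C = 0.  Cheater identity is assigned from the community backbone by
    degree rank, with ties broken by the community seed, so baseline and
    cheating runs for the same seed share every other ingredient.
    """
    if config is None:
        config = CheatingConfig(delta_bar=0.0, omega=0.0, psi=0.0)
    cheaters = assign_cheaters(
        community.IM, config.delta_bar, config.scenario, seed=community.seed
    )
    pair = strength_pair(
        community.IM, cheaters.delta, config.omega, config.psi
    )
    return integrate_strengths(
        community.r_P,
        community.r_A,
        pair.M,
        pair.C,
        params=params,
        lambda_cost=config.lambda_cost,
    )
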