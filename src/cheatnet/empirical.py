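"""Parameterizing the dynamics with observed (or synthetic) field networks.

The field network supplies the interaction backbone: I_ij = 1 where a
plant-bird pair interacted legitimately at least once, the per-pair
cheating proportion C_ij = illegitimate / total frequency, and the
legitimate ability M_ij = I_ij (1 - C_ij).  Pairs that only interacted
illegitimately contribute to C with I = 0 (configurable).  Interaction
matrices encode ability, not frequency - abundance is modeled
separately by the dynamics.

The effect of observed cheating on persistence is measured by paired
simulations (with C as observed vs. C set to 0) sharing growth-rate
vectors, over a grid of per-interaction benefit alpha, mutualism cost
Lambda and interference strength c.  Observed cheating patterns are
compared against randomized ones via logit z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .community import draw_growth_rates
from .dynamics import DynamicsParams, integrate_strengths
from .fieldsynth import FieldNetwork

__all__ = [
    "EmpiricalBackbone",
    "NullComparison",
    "build_backbone",
    "effect_of_cheating",
    "randomize_cheating",
    "logit_zscore",
    "zscore_pipeline",
]

ALPHA_GRID = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
LAMBDA_GRID = (0.0, 0.05, 0.1, 0.15, 0.3)
C_GRID = (0.5, 1.0)


@dataclass
class EmpiricalBackbone:
    """Binary mutualistic backbone I with per-pair cheating proportions."""

    I: np.ndarray
    Cprop: np.ndarray
    M: np.ndarray
    site_id: str = ""

    @property
    def overall_cheating(self) -> float:
        """Total cheating mass over total interaction-ability mass."""
        total = self.M.sum() + self.Cprop.sum()
        return float(self.Cprop.sum() / total) if total > 0 else 0.0


@dataclass
class NullComparison:
    observed_z: np.ndarray   # one clamped z per growth-rate seed
    site_z: float            # mean over seeds


def build_backbone(
    net: FieldNetwork, include_pure_cheating: bool = True
) -> EmpiricalBackbone:
    """Backbone from frequency matrices: I, Cprop, M = I (1 - Cprop).

    Species with zero total interactions are dropped.  Pairs with only
    illegitimate records get I = 0, Cprop = 1 (they feed the cheating
    matrix only) unless ``include_pure_cheating`` is False.
    """
    legit = np.asarray(net.legit_freq, dtype=float)
    illegit = np.asarray(net.illegit_freq, dtype=float)
    total = legit + illegit
    if total.sum() == 0:
        raise ValueError(f"site {net.site_id}: all-zero network")
    keep_p = total.sum(axis=1) > 0
    keep_b = total.sum(axis=0) > 0
    legit = legit[np.ix_(keep_p, keep_b)]
    illegit = illegit[np.ix_(keep_p, keep_b)]
    total = total[np.ix_(keep_p, keep_b)]
    I = (legit > 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        Cprop = np.where(total > 0, illegit / np.where(total > 0, total, 1), 0.0)
    if not include_pure_cheating:
        Cprop = Cprop * I
    M = I * (1.0 - Cprop)
    return EmpiricalBackbone(I=I, Cprop=Cprop, M=M, site_id=net.site_id)


def _run_pair(
    backbone: EmpiricalBackbone,
    r_P: np.ndarray,
    r_A: np.ndarray,
    params: DynamicsParams,
    lam: float,
) -> tuple[float, float]:
    """(persistence with cheating, persistence without) for shared rates."""
    with_c = integrate_strengths(
        r_P, r_A, backbone.M, backbone.Cprop, params=params, lambda_cost=lam
    )
    no_c = integrate_strengths(
        r_P, r_A, backbone.I, np.zeros_like(backbone.Cprop),
        params=params, lambda_cost=lam,
    )
    return with_c.persistence, no_c.persistence


def _growth_rates(
    backbone: EmpiricalBackbone, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    ss = np.random.SeedSequence(seed)
    s_p, s_a = ss.spawn(2)
    n_p, n_b = backbone.I.shape
    return (
        draw_growth_rates(n_p, np.random.default_rng(s_p)),
        draw_growth_rates(n_b, np.random.default_rng(s_a)),
    )


def effect_of_cheating(
    backbone: EmpiricalBackbone,
    alpha_grid: Sequence[float] = ALPHA_GRID,
    lambda_grid: Sequence[float] = LAMBDA_GRID,
    c_grid: Sequence[float] = C_GRID,
    n_seeds: int = 100,
    base_seed: int = 0,
    base_params: DynamicsParams = DynamicsParams(),
) -> pd.DataFrame:
    """Persistence effect of observed cheating over the parameter grid.

    For each (alpha, Lambda, c) combination and growth-rate seed, the
    model is integrated with the observed C and with C = 0, sharing the
    growth-rate vectors; the effect is the persistence difference.
    """
    rows = []
    rates = [_growth_rates(backbone, base_seed + s) for s in range(n_seeds)]
    for alpha, lam, c in product(alpha_grid, lambda_grid, c_grid):
        params = replace(base_params, alpha=alpha, c=c)
        for s, (r_P, r_A) in enumerate(rates):
            with_c, no_c = _run_pair(backbone, r_P, r_A, params, lam)
            rows.append(
                {
                    "site_id": backbone.site_id,
                    "alpha": alpha,
                    "lambda": lam,
                    "c": c,
                    "seed": base_seed + s,
                    "persistence_with": with_c,
                    "persistence_without": no_c,
                    "effect": with_c - no_c,
                }
            )
    return pd.DataFrame(rows)


def randomize_cheating(
    backbone: EmpiricalBackbone, seed: int | np.random.Generator
) -> EmpiricalBackbone:
    """Re-draw cheater identities and cheating placement, same total mass.

    The multiset of positive per-pair cheating proportions is kept; the
    set of cheating birds is re-drawn uniformly (same count), and each
    value lands on a distinct uniformly chosen pair of a new cheater -
    on an I = 1 pair it becomes conservative cheating (reducing that
    pair's M), on an I = 0 pair innovative.  Total cheating mass
    sum(C) is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    values = backbone.Cprop[backbone.Cprop > 0]
    if values.size == 0:
        raise ValueError("backbone has no cheating to randomize")
    n_p, n_b = backbone.Cprop.shape
    n_cheaters = int((backbone.Cprop.sum(axis=0) > 0).sum())
    cheaters = rng.choice(n_b, size=n_cheaters, replace=False)
    flat = np.array(
        [(i, j) for j in cheaters for i in range(n_p)], dtype=int
    )
    if len(flat) < values.size:
        raise ValueError("not enough pairs to place the cheating values")
    pick = rng.choice(len(flat), size=values.size, replace=False)
    Cnew = np.zeros_like(backbone.Cprop)
    vals = rng.permutation(values)
    for (i, j), v in zip(flat[pick], vals):
        Cnew[i, j] = v
    Mnew = backbone.I * (1.0 - Cnew)
    return EmpiricalBackbone(
        I=backbone.I.copy(), Cprop=Cnew, M=Mnew, site_id=backbone.site_id
    )


def logit_zscore(
    observed: float, nulls: np.ndarray, clamp: float = 5.0
) -> float:
    """z-score of an observed persistence against a null distribution.

    Persistence values (in %) are mapped to proportions, 0 and 1 are
    adjusted to 0.01 and 0.99, and logit-transformed before scoring.
    A zero null standard deviation gives z = 0 when the numerator is
    also ~0, else +/- clamp; finite scores are clipped to [-clamp, clamp].
    """
    def tologit(p):
        p = np.clip(np.asarray(p, dtype=float) / 100.0, 0.01, 0.99)
        return np.log(p / (1.0 - p))

    obs = tologit(observed)
    nl = tologit(np.asarray(nulls, dtype=float))
    if nl.size < 2:
        raise ValueError("need >= 2 null values")
    sd = nl.std(ddof=0)
    num = obs - nl.mean()
    if sd == 0:
        if abs(num) < 1e-12:
            return 0.0
        return clamp if num > 0 else -clamp
    return float(np.clip(num / sd, -clamp, clamp))


def zscore_pipeline(
    observed: np.ndarray, nulls: np.ndarray, clamp: float = 5.0
) -> NullComparison:
    """Per-seed clamped z-scores and their site-level mean.

    ``observed`` has one persistence value per growth-rate seed;
    ``nulls`` is (n_seeds, n_randomizations).
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    nulls = np.atleast_2d(np.asarray(nulls, dtype=float))
    if nulls.shape[0] != observed.size:
        raise ValueError("null rows must match the observed seeds")
    z = np.array(
        [logit_zscore(o, nulls[i], clamp) for i, o in enumerate(observed)]
    )
    return NullComparison(observed_z=z, site_z=float(z.mean()))
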