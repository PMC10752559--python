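"""Expansion of cheating parameters into interaction-strength matrices.

Three parameters describe the cheating pattern of the pollinator guild:
the proportion of species cheating (``delta_bar``), the frequency at
which cheaters cheat (``omega``) and the innovative fraction of that
cheating (``psi``).  A cheater diverts a fraction ``omega`` of its
legitimate interaction strength into cheating; a fraction ``psi`` of the
diverted amount lands on partners outside its mutualistic niche
(innovative cheating, new links), the rest on existing partners
(conservative cheating).

For backbone ``IM`` and cheater flags ``delta`` this gives

    M_ij = IM_ij * (1 - delta_j * omega)
    C_ij = delta_j * omega * ((1 - psi) * IM_ij + psi * (1 - IM_ij))

A fourth parameter, the per-interaction cost of mutualism ``lambda_cost``,
is carried alongside but only enters the dynamics right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "CheatingConfig",
    "StrengthPair",
    "legitimate_strengths",
    "cheating_strengths",
    "strength_pair",
]


@dataclass(frozen=True)
class CheatingConfig:
    """The four cheating parameters plus the cheater-assignment scenario."""

    delta_bar: float
    omega: float
    psi: float
    lambda_cost: float = 0.0
    scenario: Literal["generalist", "specialist"] = "specialist"

    def __post_init__(self) -> None:
        for name in ("delta_bar", "omega", "psi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lambda_cost < 0:
            raise ValueError("lambda_cost must be >= 0")


@dataclass
class StrengthPair:
    """Legitimate (M) and illegitimate (C) per-capita strength matrices."""

    M: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        for name, mat in (("M", self.M), ("C", self.C)):
            if ((mat < 0) | (mat > 1)).any():
                raise ValueError(f"{name} entries outside [0, 1]")


def _check(omega: float, psi: float = 0.0) -> None:
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega={omega} outside [0, 1]")
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi={psi} outside [0, 1]")


def legitimate_strengths(
    IM: np.ndarray, delta: np.ndarray, omega: float
) -> np.ndarray:
    """M_ij = IM_ij (1 - delta_j omega): cheaters divert strength away."""
    _check(omega)
    IM = np.asarray(IM, dtype=float)
    delta = np.asarray(delta, dtype=float)
    return IM * (1.0 - delta[None, :] * omega)


def cheating_strengths(
    IM: np.ndarray, delta: np.ndarray, omega: float, psi: float
) -> np.ndarray:
    """C_ij = delta_j omega ((1-psi) IM_ij + psi (1-IM_ij)).

    The first term is conservative cheating (on existing links), the
    second innovative cheating (on non-links).
    """
    _check(omega, psi)
    IM = np.asarray(IM, dtype=float)
    delta = np.asarray(delta, dtype=float)
    return delta[None, :] * omega * ((1.0 - psi) * IM + psi * (1.0 - IM))


def strength_pair(
    IM: np.ndarray, delta: np.ndarray, omega: float, psi: float
) -> StrengthPair:
    return StrengthPair(
        M=legitimate_strengths(IM, delta, omega),
        C=cheating_strengths(IM, delta, omega, psi),
    )
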