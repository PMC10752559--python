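"""Synthetic plant-pollinator communities.

A community is a bipartite set of ``n_P`` plants and ``n_A`` pollinators.
Each species carries a one-dimensional Gaussian morphological trait; a
binary mutualistic backbone ``IM`` links trait-matching pairs at a target
connectance ``phi``.  Basal growth rates are negative (obligate mutualism:
no species persists alone) and beta-distributed on [-0.5, -0.001], with
beta shape parameters redrawn per community so that the ensemble spans a
wide variety of growth-rate vectors.

Cheater identity is assigned by degree rank on the backbone: under the
``specialist`` scenario the pollinators with the fewest mutualistic
partners cheat, under ``generalist`` the ones with the most.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "Community",
    "CheaterVector",
    "draw_traits",
    "build_backbone",
    "draw_growth_rates",
    "assign_cheaters",
    "generate_community",
]

Scenario = Literal["generalist", "specialist"]

GROWTH_RATE_LOW = -0.5
GROWTH_RATE_HIGH = -0.001
CONNECTANCE_TOL = 0.05
_MAX_TRAIT_REDRAWS = 50


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1, 1.5 -> 2, -0.5 -> -1)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class Community:
    """A synthetic bipartite community with its mutualistic backbone."""

    n_P: int
    n_A: int
    plant_trait: np.ndarray
    animal_trait: np.ndarray
    IM: np.ndarray
    r_P: np.ndarray
    r_A: np.ndarray
    phi: float
    seed: int

    def __post_init__(self) -> None:
        self.IM = np.asarray(self.IM, dtype=float)
        if self.IM.shape != (self.n_P, self.n_A):
            raise ValueError(
                f"IM shape {self.IM.shape} != ({self.n_P}, {self.n_A})"
            )

    @property
    def connectance(self) -> float:
        return float(self.IM.mean())

    def validate(self) -> None:
        if not np.isin(self.IM, (0.0, 1.0)).all():
            raise ValueError("IM entries must be 0/1")
        if (self.IM.sum(axis=1) < 1).any() or (self.IM.sum(axis=0) < 1).any():
            raise ValueError("IM has an isolated species")
        for r in (self.r_P, self.r_A):
            if ((r < GROWTH_RATE_LOW) | (r > GROWTH_RATE_HIGH)).any():
                raise ValueError("growth rates outside [-0.5, -0.001]")
        if abs(self.connectance - self.phi) > CONNECTANCE_TOL:
            raise ValueError(
                f"realized connectance {self.connectance:.3f} "
                f"too far from target {self.phi}"
            )

    def to_dir(self, path: str | Path) -> None:
        """Serialize to a directory of TSV files + JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        plants = [f"P{i}" for i in range(self.n_P)]
        animals = [f"A{j}" for j in range(self.n_A)]
        pd.DataFrame(self.IM.astype(int), index=plants, columns=animals).to_csv(
            path / "IM.tsv", sep="\t"
        )
        pd.DataFrame(
            {"species": plants + animals, "growth_rate": np.r_[self.r_P, self.r_A]}
        ).to_csv(path / "growth_rates.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"species": plants + animals,
             "trait": np.r_[self.plant_trait, self.animal_trait]}
        ).to_csv(path / "traits.tsv", sep="\t", index=False)
        (path / "community.json").write_text(
            json.dumps({"phi": self.phi, "seed": self.seed,
                        "n_P": self.n_P, "n_A": self.n_A})
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "Community":
        path = Path(path)
        meta = json.loads((path / "community.json").read_text())
        im = pd.read_csv(path / "IM.tsv", sep="\t", index_col=0)
        rates = pd.read_csv(path / "growth_rates.tsv", sep="\t")
        traits = pd.read_csv(path / "traits.tsv", sep="\t")
        n_P, n_A = meta["n_P"], meta["n_A"]
        return cls(
            n_P=n_P,
            n_A=n_A,
            plant_trait=traits["trait"].to_numpy()[:n_P],
            animal_trait=traits["trait"].to_numpy()[n_P:],
            IM=im.to_numpy(dtype=float),
            r_P=rates["growth_rate"].to_numpy()[:n_P],
            r_A=rates["growth_rate"].to_numpy()[n_P:],
            phi=meta["phi"],
            seed=meta["seed"],
        )


@dataclass
class CheaterVector:
    """Binary cheater flags for the pollinator guild."""

    delta: np.ndarray  # 0/1 per pollinator
    scenario: Scenario
    delta_bar: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)

    @property
    def n_cheaters(self) -> int:
        return int(self.delta.sum())


def draw_traits(
    n_P: int, n_A: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw standard-normal morphological traits for both guilds."""
    if n_P < 1 or n_A < 1:
        raise ValueError("species counts must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal(n_P), rng.standard_normal(n_A)


def _backbone_from_traits(
    plant_trait: np.ndarray, animal_trait: np.ndarray, phi: float
) -> np.ndarray:
    """Trait-distance backbone: link iff |t_P - t_A| <= d, d tuned to phi.

    The distance threshold is found by bisection so the realized
    connectance is as close as possible to the target; any species left
    isolated is then wired to its nearest-trait partner.
    """
    dist = np.abs(plant_trait[:, None] - animal_trait[None, :])
    lo, hi = 0.0, float(dist.max())
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if (dist <= mid).mean() < phi:
            lo = mid
        else:
            hi = mid
    # pick the better of the two bracket ends
    cands = [(abs((dist <= d).mean() - phi), d) for d in (lo, hi)]
    d = min(cands)[1]
    im = (dist <= d).astype(float)
    # re-attach isolated species to the closest partner
    for i in np.flatnonzero(im.sum(axis=1) == 0):
        im[i, np.argmin(dist[i])] = 1.0
    for j in np.flatnonzero(im.sum(axis=0) == 0):
        im[np.argmin(dist[:, j]), j] = 1.0
    return im


def _build_with_retries(
    plant_trait: np.ndarray,
    animal_trait: np.ndarray,
    phi: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backbone + the trait vectors that produced it (traits may be redrawn)."""
    if phi == 1.0:
        return (
            np.ones((len(plant_trait), len(animal_trait))),
            plant_trait,
            animal_trait,
        )
    for _ in range(_MAX_TRAIT_REDRAWS):
        im = _backbone_from_traits(plant_trait, animal_trait, phi)
        if abs(im.mean() - phi) <= CONNECTANCE_TOL:
            return im, plant_trait, animal_trait
        plant_trait = rng.standard_normal(len(plant_trait))
        animal_trait = rng.standard_normal(len(animal_trait))
    raise RuntimeError(
        f"could not build a connected backbone at phi={phi} "
        f"for sizes {len(plant_trait)}x{len(animal_trait)}"
    )


def build_backbone(
    traits: tuple[np.ndarray, np.ndarray],
    phi: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Binary interaction matrix at target connectance from trait matching.

    If the connectance tolerance (|realized - phi| <= 0.05) cannot be met
    with the given traits, traits are redrawn (up to 50 times) from the
    same RNG stream.
    """
    if not 0.0 < phi <= 1.0:
        raise ValueError("phi must be in (0, 1]")
    rng = np.random.default_rng(seed)
    im, _, _ = _build_with_retries(traits[0], traits[1], phi, rng)
    return im


def draw_growth_rates(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Beta-distributed basal growth rates mapped onto [-0.5, -0.001].

    The beta shape parameters are themselves drawn uniformly from
    [0.5, 5] per call, so repeated communities sample a wide variety of
    growth-rate vectors (skewed low, skewed high, u-shaped, bell-shaped).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a, b = rng.uniform(0.5, 5.0, size=2)
    x = rng.beta(a, b, size=n)
    return GROWTH_RATE_LOW + x * (GROWTH_RATE_HIGH - GROWTH_RATE_LOW)


def assign_cheaters(
    IM: np.ndarray,
    delta_bar: float,
    scenario: Scenario,
    seed: int | np.random.Generator = 0,
) -> CheaterVector:
    """Flag round(delta_bar * n_A) pollinators as cheaters by degree rank.

    ``specialist`` picks the lowest-degree columns of IM, ``generalist``
    the highest-degree ones.  Ties are broken by a seeded permutation of
    the column indices so the assignment is reproducible.
    """
    if not 0.0 <= delta_bar <= 1.0:
        raise ValueError("delta_bar must be in [0, 1]")
    if scenario not in ("generalist", "specialist"):
        raise ValueError(f"unknown scenario {scenario!r}")
    IM = np.asarray(IM, dtype=float)
    n_A = IM.shape[1]
    k = round_half_away(delta_bar * n_A)
    degree = IM.sum(axis=0)
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n_A)
    order = np.lexsort((tiebreak, degree))  # ascending degree
    if scenario == "generalist":
        order = order[::-1]
    delta = np.zeros(n_A)
    delta[order[:k]] = 1.0
    return CheaterVector(delta=delta, scenario=scenario, delta_bar=delta_bar)


def generate_community(
    n_P: int = 20,
    n_A: int = 20,
    phi: float = 0.4,
    seed: int = 0,
) -> Community:
    """Generate a full community (traits, backbone, growth rates).

    All randomness is spawned from ``seed`` via independent substreams,
    so the community is bit-reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_traits, s_backbone, s_rp, s_ra = ss.spawn(4)
    plant_trait, animal_trait = draw_traits(
        n_P, n_A, np.random.default_rng(s_traits)
    )
    if not 0.0 < phi <= 1.0:
        raise ValueError("phi must be in (0, 1]")
    im, plant_trait, animal_trait = _build_with_retries(
        plant_trait, animal_trait, phi, np.random.default_rng(s_backbone)
    )
    com = Community(
        n_P=n_P,
        n_A=n_A,
        plant_trait=plant_trait,
        animal_trait=animal_trait,
        IM=im,
        r_P=draw_growth_rates(n_P, np.random.default_rng(s_rp)),
        r_A=draw_growth_rates(n_A, np.random.default_rng(s_ra)),
        phi=phi,
        seed=seed,
    )
    com.validate()
    return com
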