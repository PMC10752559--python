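"""Synthetic plant-bird field data over an elevation gradient.

Emulates camera-trap interaction sampling in tropical plant-hummingbird
communities: multiple sites spread over an elevation gradient, per-site
plant x bird matrices of legitimate and illegitimate visit counts,
per-plant sampling effort (hours), flower traits (corolla length in mm
and a dimensionless curvature score) and bird bill lengths.

The generator encodes the cheating patterns the estimators are meant to
recover, as ground truth stored next to the data:

* birds interact legitimately with plants whose flowers they can reach
  (corolla length not much larger than bill length, limited curvature);
* a fraction ``delta_bar_true`` of birds cheat, preferentially the ones
  with few accessible partners (specialists cheat more);
* a cheater's cheating frequency follows a logit-linear model,
  decreasing with the log of its mutualistic partner diversity and with
  (scaled) elevation;
* a fraction ``psi_true`` of cheating mass is innovative: placed on
  plants outside the convex hull of the bird's legitimate partners in
  (corolla length, curvature) space, preferentially far from the niche
  centroid.

Counts are negative-binomial (camera-trap visit counts are
overdispersed) and converted to frequencies in interactions/day by
``counts / hours * 24``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "FieldConfig",
    "FieldNetwork",
    "FieldDataset",
    "normalize_counts",
    "generate_field_dataset",
]


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p / (1.0 - p))


def _inv_logit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class FieldConfig:
    """Generator settings; defaults mimic a two-country, 17-site survey."""

    n_sites: int = 17
    elevation_min: float = 100.0    # m a.s.l.
    elevation_max: float = 3500.0
    n_plants_range: tuple[int, int] = (10, 18)
    n_birds_range: tuple[int, int] = (7, 14)
    delta_bar_true: float = 0.8     # fraction of birds that are cheaters
    psi_true: float = 0.9           # innovative fraction of cheating mass
    omega_intercept: float = 1.0    # logit cheating frequency at log-div 0
    diversity_slope: float = -1.2   # per unit log partner diversity
    elevation_slope: float = -2.0   # per unit scaled (0-1) elevation
    base_rate_per_day: float = 1.2  # legit visits/day at perfect trait match
    hours_range: tuple[float, float] = (100.0, 400.0)
    nb_dispersion: float = 2.0      # NB size; smaller = more overdispersed
    reach_slack_mm: float = 4.0     # corolla may exceed bill by this much
    max_curvature: float = 45.0     # accessible curvature ceiling


@dataclass
class FieldNetwork:
    """One site: frequency matrices (plants x birds), traits, effort."""

    site_id: str
    elevation: float
    legit_freq: np.ndarray
    illegit_freq: np.ndarray
    sampling_hours: np.ndarray      # per plant
    plant_traits: pd.DataFrame     # columns: corolla_length, curvature
    bird_bill_length: np.ndarray

    @property
    def n_plants(self) -> int:
        return self.legit_freq.shape[0]

    @property
    def n_birds(self) -> int:
        return self.legit_freq.shape[1]

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        plants = [f"plant_{i}" for i in range(self.n_plants)]
        birds = [f"bird_{j}" for j in range(self.n_birds)]
        pd.DataFrame(self.legit_freq, index=plants, columns=birds).to_csv(
            path / "legitimate.tsv", sep="\t"
        )
        pd.DataFrame(self.illegit_freq, index=plants, columns=birds).to_csv(
            path / "illegitimate.tsv", sep="\t"
        )
        plant_df = self.plant_traits.copy()
        plant_df.insert(0, "plant", plants)
        plant_df["sampling_hours"] = self.sampling_hours
        plant_df.to_csv(path / "plants.tsv", sep="\t", index=False)
        pd.DataFrame({"bird": birds, "bill_length": self.bird_bill_length}
                     ).to_csv(path / "birds.tsv", sep="\t", index=False)
        (path / "site.json").write_text(
            json.dumps({"site_id": self.site_id, "elevation": self.elevation})
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "FieldNetwork":
        path = Path(path)
        meta = json.loads((path / "site.json").read_text())
        legit = pd.read_csv(path / "legitimate.tsv", sep="\t", index_col=0)
        illegit = pd.read_csv(path / "illegitimate.tsv", sep="\t", index_col=0)
        plants = pd.read_csv(path / "plants.tsv", sep="\t")
        birds = pd.read_csv(path / "birds.tsv", sep="\t")
        return cls(
            site_id=meta["site_id"],
            elevation=meta["elevation"],
            legit_freq=legit.to_numpy(dtype=float),
            illegit_freq=illegit.to_numpy(dtype=float),
            sampling_hours=plants["sampling_hours"].to_numpy(dtype=float),
            plant_traits=plants[["corolla_length", "curvature"]].copy(),
            bird_bill_length=birds["bill_length"].to_numpy(dtype=float),
        )


@dataclass
class FieldDataset:
    sites: list[FieldNetwork]
    ground_truth: dict

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for net in self.sites:
            net.to_dir(path / net.site_id)
        (path / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=1)
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "FieldDataset":
        path = Path(path)
        truth = json.loads((path / "ground_truth.json").read_text())
        sites = [
            FieldNetwork.from_dir(p)
            for p in sorted(path.iterdir())
            if p.is_dir() and (p / "site.json").exists()
        ]
        return cls(sites=sites, ground_truth=truth)


def normalize_counts(
    counts: np.ndarray, hours: np.ndarray | float
) -> np.ndarray:
    """Counts -> frequencies in interactions/day: counts / hours * 24."""
    counts = np.asarray(counts, dtype=float)
    hours_arr = np.broadcast_to(
        np.atleast_1d(np.asarray(hours, dtype=float))[:, None]
        if np.ndim(hours) == 1 and counts.ndim == 2
        else np.asarray(hours, dtype=float),
        counts.shape,
    )
    if (hours_arr <= 0).any():
        if ((hours_arr <= 0) & (counts > 0)).any():
            raise ValueError("nonzero counts with non-positive sampling hours")
        raise ValueError("sampling hours must be positive")
    return counts / hours_arr * 24.0


def _out_of_hull(points: np.ndarray, hull_points: np.ndarray) -> np.ndarray:
    """Boolean mask of points outside the convex hull of hull_points.

    Degenerate hulls (fewer than 3 distinct points, collinear points)
    fall back to 'outside' for every point not in the hull set.
    """
    if len(hull_points) >= 3:
        try:
            tri = Delaunay(hull_points)
            return tri.find_simplex(points) < 0
        except QhullError:
            pass
    out = np.ones(len(points), dtype=bool)
    for hp in hull_points:
        out &= ~np.all(np.isclose(points, hp[None, :]), axis=1)
    return out


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, size_param: float
) -> np.ndarray:
    """Negative-binomial counts with the given mean and dispersion size."""
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    out = np.zeros(mean.shape, dtype=float)
    pos = mean > 0
    p = size_param / (size_param + mean[pos])
    out[pos] = rng.negative_binomial(size_param, p)
    return out


def _generate_site(
    config: FieldConfig,
    site_id: str,
    elevation: float,
    elev01: float,
    rng: np.random.Generator,
) -> tuple[FieldNetwork, dict]:
    n_p = int(rng.integers(*config.n_plants_range, endpoint=True))
    n_b = int(rng.integers(*config.n_birds_range, endpoint=True))
    corolla = rng.lognormal(np.log(18.0), 0.45, size=n_p)
    curvature = rng.beta(2.0, 4.0, size=n_p) * 60.0
    bill = rng.lognormal(np.log(22.0), 0.35, size=n_b)
    hours = rng.uniform(*config.hours_range, size=n_p)

    feasible = (
        (corolla[:, None] <= bill[None, :] + config.reach_slack_mm)
        & (curvature[:, None] <= config.max_curvature)
    )
    # every bird can reach at least its best-matching flower
    for j in np.flatnonzero(feasible.sum(axis=0) == 0):
        feasible[np.argmin(np.abs(corolla - bill[j])), j] = True

    match = np.exp(-np.abs(corolla[:, None] - bill[None, :]) / 8.0)
    legit_mean = np.where(
        feasible, config.base_rate_per_day * match * hours[:, None] / 24.0, 0.0
    )

    diversity = feasible.sum(axis=0).astype(float)
    n_cheaters = int(round(config.delta_bar_true * n_b))
    # specialists cheat: lowest accessible-partner diversity first
    order = np.lexsort((rng.permutation(n_b), diversity))
    cheater = np.zeros(n_b, dtype=bool)
    cheater[order[:n_cheaters]] = True
    omega_true = np.where(
        cheater,
        np.clip(
            _inv_logit(
                config.omega_intercept
                + config.diversity_slope * np.log(diversity)
                + config.elevation_slope * elev01
            ),
            0.0,
            0.95,
        ),
        0.0,
    )

    traits = np.column_stack([corolla, curvature])
    scale = traits.std(axis=0)
    scale[scale == 0] = 1.0
    illegit_mean = np.zeros((n_p, n_b))
    for j in range(n_b):
        if omega_true[j] == 0:
            continue
        total_legit = legit_mean[:, j].sum()
        budget = omega_true[j] / (1.0 - omega_true[j]) * total_legit
        cons = (1.0 - config.psi_true) * budget
        innov = config.psi_true * budget
        if cons > 0 and total_legit > 0:
            illegit_mean[:, j] += cons * legit_mean[:, j] / total_legit
        if innov > 0:
            partners = traits[feasible[:, j]]
            # out of the mutualistic niche: unreachable plants, refined by
            # the trait-space convex hull of the legitimate partners
            out = ~feasible[:, j] & _out_of_hull(traits, partners)
            if not out.any():
                out = ~feasible[:, j]
            if not out.any():
                # bird can reach every plant: innovative cheating is
                # infeasible for it, divert the mass to conservative
                if total_legit > 0:
                    illegit_mean[:, j] += (
                        innov * legit_mean[:, j] / total_legit
                    )
                continue
            centroid = np.average(
                partners, axis=0, weights=legit_mean[feasible[:, j], j] + 1e-9
            )
            dist2 = (((traits - centroid) / scale) ** 2).sum(axis=1)
            w = np.where(out, dist2 + 0.1, 0.0)
            illegit_mean[:, j] += innov * w / w.sum()

    n_innovative_capable = int(
        sum(
            1
            for j in range(n_b)
            if omega_true[j] > 0 and (~feasible[:, j]).any()
        )
    )
    legit_counts = _nb_counts(rng, legit_mean, config.nb_dispersion)
    illegit_counts = _nb_counts(rng, illegit_mean, config.nb_dispersion)
    # keep every bird observed at least once legitimately
    for j in np.flatnonzero(legit_counts.sum(axis=0) == 0):
        best = np.argmax(legit_mean[:, j])
        legit_counts[best, j] = 1.0

    net = FieldNetwork(
        site_id=site_id,
        elevation=float(elevation),
        legit_freq=normalize_counts(legit_counts, hours),
        illegit_freq=normalize_counts(illegit_counts, hours),
        sampling_hours=hours,
        plant_traits=pd.DataFrame(
            {"corolla_length": corolla, "curvature": curvature}
        ),
        bird_bill_length=bill,
    )
    truth = {
        "site_id": site_id,
        "elevation": float(elevation),
        "omega_true": omega_true.tolist(),
        "cheater": cheater.astype(int).tolist(),
        "diversity": diversity.tolist(),
        "n_innovative_capable": n_innovative_capable,
    }
    return net, truth


def generate_field_dataset(
    config: FieldConfig = FieldConfig(), seed: int = 0
) -> FieldDataset:
    """Generate a multi-site dataset with its generating parameters."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    elevations = np.linspace(
        config.elevation_min, config.elevation_max, config.n_sites
    )
    elevations = elevations + rng.uniform(
        -50, 50, size=config.n_sites
    ) * (config.n_sites > 1)
    span = config.elevation_max - config.elevation_min
    sites, site_truths = [], []
    for s, elev in enumerate(elevations):
        elev01 = (elev - config.elevation_min) / span if span > 0 else 0.0
        net, truth = _generate_site(
            config, f"site_{s:02d}", elev, float(elev01), rng
        )
        sites.append(net)
        site_truths.append(truth)
    if config.psi_true > 0 and not any(
        t["n_innovative_capable"] > 0 for t in site_truths
    ):
        raise ValueError(
            "psi_true > 0 but no bird in any site has an out-of-niche "
            "plant to cheat on; widen the trait distributions"
        )
    ground_truth = {
        "config": asdict(config),
        "seed": seed,
        "psi_true": config.psi_true,
        "delta_bar_true": config.delta_bar_true,
        "diversity_slope": config.diversity_slope,
        "elevation_slope": config.elevation_slope,
        "sites": site_truths,
    }
    return FieldDataset(sites=sites, ground_truth=ground_truth)
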