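"""Estimators of cheating patterns from plant-bird interaction networks.

Four quantities describe the cheating pattern of a site or bird:

* proportion of cheaters: birds with at least one illegitimate
  interaction, over the birds observed at the site;
* cheating frequency of a bird: illegitimate over total interaction
  frequency, both summed over its partners at the site;
* overall level of cheating of a site: illegitimate over total
  frequency summed over all plant-bird pairs (the delta_bar x omega
  level of the site);
* innovative proportion of a bird: one minus the overlap between two
  weighted 2D kernel-density estimates over flower traits (corolla
  length, curvature) - one weighted by legitimate, one by illegitimate
  frequencies.  Each density is normalized to sum to one on a shared
  grid; the overlap is the mass under the pointwise minimum and equals
  the conservative proportion.

Trend statistics use (quasi)binomial GLMs with a logit link:
quasibinomial for site-level proportions against elevation, binomial
for per-bird cheating frequency against log partner diversity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fieldsynth import FieldDataset, FieldNetwork

__all__ = [
    "proportion_cheaters",
    "cheating_frequency",
    "partner_diversity",
    "overall_cheating",
    "innovative_proportion",
    "weighted_kde_2d",
    "glm_trend",
    "site_estimates",
    "bird_estimates",
    "innovative_estimates",
    "trend_tests",
]


def _observed_birds(net: FieldNetwork) -> np.ndarray:
    return (net.legit_freq.sum(axis=0) + net.illegit_freq.sum(axis=0)) > 0


def proportion_cheaters(net: FieldNetwork) -> float:
    """Fraction of observed birds with >= 1 illegitimate interaction."""
    obs = _observed_birds(net)
    if not obs.any():
        raise ValueError(f"site {net.site_id} has no observed birds")
    cheats = net.illegit_freq.sum(axis=0) > 0
    return float(cheats[obs].sum() / obs.sum())


def cheating_frequency(net: FieldNetwork, bird: int) -> float:
    """Illegitimate / total interaction frequency for one bird at a site."""
    il = float(net.illegit_freq[:, bird].sum())
    le = float(net.legit_freq[:, bird].sum())
    if il + le == 0:
        raise ValueError(
            f"bird {bird} has no interactions at site {net.site_id}"
        )
    return il / (il + le)


def partner_diversity(net: FieldNetwork, bird: int) -> int:
    """Number of plants with >= 1 legitimate interaction with the bird."""
    return int((net.legit_freq[:, bird] > 0).sum())


def overall_cheating(net: FieldNetwork) -> float:
    """Site-level illegitimate / total frequency over all pairs."""
    il = float(net.illegit_freq.sum())
    le = float(net.legit_freq.sum())
    if il + le == 0:
        raise ValueError(f"site {net.site_id} is empty")
    return il / (il + le)


def _silverman_bandwidths(
    points: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Silverman's rule per dimension on weighted points (d=2).

    h_d = sigma_d * n_eff^(-1/6), with n_eff the Kish effective sample
    size of the weights.  Zero spread falls back to 1% of the grid-side
    scale to keep the kernel proper.
    """
    w = weights / weights.sum()
    n_eff = 1.0 / (w ** 2).sum()
    mu = np.average(points, axis=0, weights=w)
    var = np.average((points - mu) ** 2, axis=0, weights=w)
    sigma = np.sqrt(var)
    fallback = np.maximum(np.abs(mu) * 0.01, 1e-3)
    sigma = np.where(sigma > 0, sigma, fallback)
    return sigma * n_eff ** (-1.0 / 6.0)


def weighted_kde_2d(
    points: np.ndarray,
    weights: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    bandwidths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Weighted Gaussian product-kernel density on a rectangular grid.

    Returns a (len(grid_x), len(grid_y)) array normalized to sum to 1.
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if bandwidths is None:
        bandwidths = _silverman_bandwidths(points, weights)
    hx, hy = bandwidths
    kx = np.exp(-0.5 * ((grid_x[:, None] - points[None, :, 0]) / hx) ** 2)
    ky = np.exp(-0.5 * ((grid_y[:, None] - points[None, :, 1]) / hy) ** 2)
    dens = np.einsum("k,ik,jk->ij", weights, kx, ky)
    total = dens.sum()
    if total == 0:
        raise ValueError("density vanished on the grid; widen the grid")
    return dens / total


def innovative_proportion(
    legit_weights: np.ndarray,
    illegit_weights: np.ndarray,
    traits: np.ndarray,
    gridsize: int = 100,
    padding: float = 0.1,
    bandwidths: Optional[np.ndarray] = None,
) -> float:
    """1 - overlap of legitimate- and illegitimate-weighted trait KDEs.

    Plants with missing traits must be dropped by the caller.  The two
    densities share a grid spanning the union of the supporting points,
    padded by ``padding`` per side; the overlap is the sum of the
    pointwise minimum of the (sum-normalized) densities.
    """
    traits = np.asarray(traits, dtype=float)
    lw = np.asarray(legit_weights, dtype=float)
    iw = np.asarray(illegit_weights, dtype=float)
    if lw.sum() == 0 or iw.sum() == 0:
        raise ValueError(
            "innovative proportion needs >=1 legitimate and >=1 "
            "illegitimate partner"
        )
    support = traits[(lw > 0) | (iw > 0)]
    lo = support.min(axis=0)
    hi = support.max(axis=0)
    span = np.where(hi > lo, hi - lo, np.maximum(np.abs(hi), 1.0))
    lo = lo - padding * span
    hi = hi + padding * span
    gx = np.linspace(lo[0], hi[0], gridsize)
    gy = np.linspace(lo[1], hi[1], gridsize)
    mask_l, mask_i = lw > 0, iw > 0
    d_legit = weighted_kde_2d(
        traits[mask_l], lw[mask_l], gx, gy, bandwidths=bandwidths
    )
    d_illegit = weighted_kde_2d(
        traits[mask_i], iw[mask_i], gx, gy, bandwidths=bandwidths
    )
    conservative = float(np.minimum(d_legit, d_illegit).sum())
    return 1.0 - conservative


@dataclass
class GLMTrend:
    """A fitted (quasi)binomial logit trend."""

    params: pd.Series
    bse: pd.Series
    dispersion: float
    wald_chi2: pd.Series     # type II Wald chi-square per term
    wald_p: pd.Series
    converged: bool


def glm_trend(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    weights: str,
    family: str = "quasibinomial",
) -> GLMTrend:
    """(Quasi)binomial logit GLM of a proportion on predictors.

    ``weights`` are binomial denominators (total interaction
    frequency).  The quasibinomial family is the binomial IRLS fit with
    the covariance scaled by the Pearson dispersion.  Type II Wald
    chi-square statistics are computed per term: each term is tested
    from the largest model that contains every other term.
    """
    if family not in ("binomial", "quasibinomial"):
        raise ValueError(f"unknown family {family!r}")
    X = sm.add_constant(data[list(predictors)].astype(float))
    y = data[response].astype(float)
    w = data[weights].astype(float)
    scale = "X2" if family == "quasibinomial" else 1.0
    fit = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit(
        scale=scale
    )
    chi2, pvals = {}, {}
    from scipy.stats import chi2 as chi2_dist

    for term in predictors:
        z = fit.params[term] / fit.bse[term]
        chi2[term] = float(z ** 2)
        pvals[term] = float(chi2_dist.sf(chi2[term], df=1))
    return GLMTrend(
        params=fit.params,
        bse=fit.bse,
        dispersion=float(fit.scale),
        wald_chi2=pd.Series(chi2),
        wald_p=pd.Series(pvals),
        converged=bool(fit.converged),
    )


def site_estimates(dataset: FieldDataset) -> pd.DataFrame:
    """Per-site proportion of cheaters and overall cheating level."""
    rows = []
    for net in dataset.sites:
        total = float(net.legit_freq.sum() + net.illegit_freq.sum())
        rows.append(
            {
                "site_id": net.site_id,
                "elevation": net.elevation,
                "n_birds": int(_observed_birds(net).sum()),
                "proportion_cheaters": proportion_cheaters(net),
                "overall_cheating": overall_cheating(net),
                "total_frequency": total,
            }
        )
    return pd.DataFrame(rows)


def bird_estimates(dataset: FieldDataset) -> pd.DataFrame:
    """Per (bird, site) cheating frequency and partner diversity."""
    rows = []
    for net in dataset.sites:
        for j in range(net.n_birds):
            total = float(
                net.legit_freq[:, j].sum() + net.illegit_freq[:, j].sum()
            )
            if total == 0:
                continue
            rows.append(
                {
                    "site_id": net.site_id,
                    "elevation": net.elevation,
                    "bird": j,
                    "cheating_frequency": cheating_frequency(net, j),
                    "partner_diversity": partner_diversity(net, j),
                    "total_frequency": total,
                }
            )
    return pd.DataFrame(rows)


def innovative_estimates(
    dataset: FieldDataset, gridsize: int = 100
) -> pd.DataFrame:
    """Per-bird innovative proportion, pooling a bird's sites.

    Birds are identified per site (no cross-site identity in synthetic
    data); only birds with both legitimate and illegitimate partners
    contribute.
    """
    rows = []
    for net in dataset.sites:
        traits = net.plant_traits[
            ["corolla_length", "curvature"]
        ].to_numpy(dtype=float)
        ok = np.isfinite(traits).all(axis=1)
        for j in range(net.n_birds):
            lw = net.legit_freq[ok, j]
            iw = net.illegit_freq[ok, j]
            if lw.sum() == 0 or iw.sum() == 0:
                continue
            rows.append(
                {
                    "site_id": net.site_id,
                    "bird": j,
                    "innovative_proportion": innovative_proportion(
                        lw, iw, traits[ok], gridsize=gridsize
                    ),
                    "illegit_frequency": float(iw.sum()),
                }
            )
    return pd.DataFrame(rows)


def trend_tests(dataset: FieldDataset) -> dict[str, GLMTrend]:
    """The three trend fits: cheating vs elevation (x2) and vs diversity."""
    sites = site_estimates(dataset)
    birds = bird_estimates(dataset).copy()
    birds["log_diversity"] = np.log(
        birds["partner_diversity"].clip(lower=1)
    )
    return {
        "overall_cheating_vs_elevation": glm_trend(
            sites, "overall_cheating", ["elevation"], "total_frequency",
            family="quasibinomial",
        ),
        "proportion_cheaters_vs_elevation": glm_trend(
            sites, "proportion_cheaters", ["elevation"], "n_birds",
            family="quasibinomial",
        ),
        "cheating_frequency_vs_log_diversity": glm_trend(
            birds, "cheating_frequency", ["log_diversity"],
            "total_frequency", family="binomial",
        ),
    }
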