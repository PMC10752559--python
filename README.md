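# cheatnet

Cheating in mutualistic plant–pollinator networks: when does nectar
robbing destabilize a community, and when does it help species coexist?

Many pollinators exploit flowers without pollinating them. Two kinds of
exploitation can be told apart at the interaction level:

* **conservative cheating** — a pollinator robs a plant it also visits
  legitimately, replacing mutualism without adding links;
* **innovative cheating** — a pollinator robs a plant outside its
  mutualistic niche (e.g., a corolla longer than its bill), adding new
  links to the network.

`cheatnet` implements a generalized Lotka–Volterra model of bipartite
communities that separates the two, the parameter sweep that maps their
consequences for network persistence, structural network metrics (NODF
nestedness, Barber bipartite modularity), a synthetic camera-trap-style
field-data generator, and the estimators that extract cheating patterns
from field data.

## Model

Plants `P_i` and pollinators `A_j` interact through a binary mutualistic
backbone `IM` drawn from Gaussian trait matching at target connectance φ.
Cheating is controlled by four parameters: the proportion of pollinator
species cheating (Δ̄), their cheating frequency (Ω), the innovative
proportion of that cheating (Ψ), and the per-interaction cost of
mutualism (Λ < α). These expand into strength matrices

```
M_ij = IM_ij (1 − Δ_j Ω)
C_ij = Δ_j Ω ((1 − Ψ) IM_ij + Ψ (1 − IM_ij))
```

and the dynamics

```
dP_i/dt = P_i ( r_Pi + (α−Λ) Σ_j M_ij A_j / (1 + β Σ_j M_ij A_j + c Σ_k Π_ik P_k)
                      −  Λ   Σ_j C_ij A_j / (1 + β Σ_j C_ij A_j + c Σ_k Υ_ik P_k)
                      − Σ_k cP_ik P_k )
dA_j/dt = A_j ( r_Aj + Σ_i [α(M_ij+C_ij) − Λ M_ij] P_i
                        / (1 + β Σ_i (M_ij+C_ij) P_i + c Σ_k Θ_jk A_k)
                      − Σ_k cA_jk A_k )
```

with handling time β, within-guild interference c weighted by
niche-similarity matrices Π, Υ, Θ, and negative basal growth rates
(obligate mutualism). Network persistence is the percentage of species
above abundance 1e−5 at equilibrium; the effect of cheating is the
persistence difference against a matched no-cheating (Ω = 0) baseline.

## Worked example

```python
from cheatnet.community import generate_community
from cheatnet.cheating import CheatingConfig
from cheatnet.dynamics import DynamicsParams, integrate_to_equilibrium

com = generate_community(n_P=20, n_A=20, phi=0.4, seed=0)
base = integrate_to_equilibrium(com, None, DynamicsParams())
cfg = CheatingConfig(delta_bar=0.3, omega=0.4, psi=1.0,
                     lambda_cost=0.0, scenario="specialist")
res = integrate_to_equilibrium(com, cfg, DynamicsParams())
print(f"baseline persistence {base.persistence:.1f}%")
print(f"with innovative specialist cheating {res.persistence:.1f}%")
print(f"effect of cheating {res.persistence - base.persistence:+.1f} points")
```

prints

```
baseline persistence 97.5%
with innovative specialist cheating 100.0%
effect of cheating +2.5 points
```

— for this community, innovative cheating by specialists lets one
otherwise-extinct species persist. Averaged over many seeded
communities the same window yields a small positive mean effect, while
conservative cheating (Ψ = 0) or costly mutualism (Λ > 0) pushes the
effect negative; see the drivers under `analysis/` for the full
scaled-down experiments (sweep, variance decomposition, community-size
and interference contrasts, synthetic field survey, empirical
parameterization).

The command-line interface exposes the same steps
(`cheatnet simulate --seed 1`, `cheatnet sweep --scaled-down smoke ...`,
`cheatnet synth-field ...`, `cheatnet estimate ...`; see `--help`).

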