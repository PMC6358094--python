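# nichecluster

Stochastic niche-community simulators and abundance-weighted metrics for
detecting clusters of similar species on a trait axis.

Classical competition theory expects coexisting competitors to be *more*
different than chance (limiting similarity). A more recent line of work
predicts the opposite signature: competition self-organizes communities
into **clusters of similar species** around emergent niche positions,
with sparse gaps in between, and immigration can make these otherwise
transient clusters persistent. This package is for theoretical community
ecologists who want to (a) generate communities under explicit niche
mechanisms with demographic stochasticity and immigration, and (b) test
any community table for trait clustering with parameter-free,
abundance-weighted statistics.

## Models

All models are zero-sum lotteries on a community of J individuals open
to immigration (rate m) from a fixed neutral metacommunity (biodiversity
parameter θ). Each death is followed by a recruitment lottery; the niche
mechanism sets the weights:

| mechanism | death weight | local recruitment weight |
|---|---|---|
| Lotka-Volterra | Σ_j A_ij N_i N_j, A_ij = exp[−(\|x_i−x_j\|/w)⁴] | r_i N_i |
| resource partitioning | N_i (equal mortality) | Σ_a C_ai X_a N_i, C_ai = exp[−(d_ai/σ)²] |
| habitat gradient | uniform site | T_ai · seed rain, T_ai = exp[−(Δ_ai/σ)²] |
| competition–colonization | Σ_j (f_i+f_j)Γ_ij N_i N_j | (f_i − μ) N_i |
| neutral baseline | N_i | N_i |

Resources follow their own stochastic logistic birth-death process with
absorbing extirpation; the habitat model is spatially explicit with
Gaussian dispersal (global or local); the tradeoff model uses the
sigmoidal displacement matrix Γ_ij = 0.5(1 − tanh[s(f_j − f_i)]) and
also ships its deterministic ODE for equilibrium analysis.

## Metrics

Both metrics compare a community against B = 100 null communities in
which the observed abundances are shuffled across all pool species
(traits stay attached to species), testing specifically for
trait–abundance association:

- **k-means gap**: exact abundance-weighted 1-D k-means (dynamic
  programming — no restarts, no free parameters) for k = 1..20; the gap
  curve's argmax estimates the number of clusters, and the maximal
  per-k-studentized gap gives a permutation z-score and p-value.
- **Ripley's-K gap**: the abundance-weighted interspecific
  pair-accumulation curve K(d); the statistic is the maximal studentized
  *deficit* of pairs at intermediate separations — the signature of
  sparse gaps between clusters — and its argmax d is the gap scale.

## Worked example

```python
import numpy as np
import nichecluster as nc

pool = nc.generate_pool(theta=50, metacommunity_size=150_000, seed=1)
community = nc.simulate_lv(pool, nc.LVParams(w=0.063), J=21_000, m=0.08,
                           generations=100, seed=1)
print(f"pool: {pool.S} species; community: {community.richness} present")

rng = np.random.default_rng(1)
km = nc.kmeans_gap_metric(community, pool, B=100, rng=rng)
rp = nc.ripley_gap_metric(community, pool, B=100, rng=rng)
print(f"k-means : k_est = {km.k_est}, z = {km.z:.2f}, p = {km.p:.4f}")
print(f"Ripley K: d_gap = {rp.d_gap:.3f}, z = {rp.z:.2f}, p = {rp.p:.4f}")
```

prints

```
pool: 422 species; community: 220 present
k-means : k_est = 13, z = 2.84, p = 0.0198
Ripley K: d_gap = 0.062, z = 5.21, p = 0.0099
```

The Lotka-Volterra community with niche width w = 0.063 organizes into
13 clusters (k_est), both metrics reject the shuffled null at p < 0.05,
and the Ripley gap scale 0.062 ≈ w is the sparse spacing between
clusters. A neutral community run the same way is significant only at
background rates.

## Command line

```
nichecluster pool    --theta 50 --size 150000 --seed 1 --out pool.csv
nichecluster run     --config scenario.yaml --out results/
nichecluster sweep   --config scenario.yaml --axis theta --values 5,10,20,30,50 --out sweep/
nichecluster metric  --method ripley --community c.csv --pool p.csv --nulls 100 --seed 7
nichecluster fixture --kind k_clumps --k 13 --out fx
```

`scenario.yaml` mirrors `ScenarioConfig` (model, params, J, m, theta,
generations, n_replicates, n_nulls, base_seed).

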