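# distdecay

Distance decay of community similarity for presence–absence survey data.

Community ecologists measuring **beta diversity** across a region — county
checklists, survey grids, island inventories — repeatedly need the same
analysis chain: pairwise similarity between assemblages, how fast that
similarity falls off with geographic distance, and how much of the turnover
is attributable to geography, environment, or isolation once the three are
disentangled. `distdecay` packages that chain for binary site × species
matrices, with a synthetic landscape generator so every stage can be tested
against known ground truth.

## What it computes

**Similarity.** For each site pair with `a` shared species and `b`, `c`
species unique to either site: Jaccard `J = a/(a+b+c)` and Simpson
`S = a/(a+min(b,c))`; the Simpson index equals 1 for nested assemblages, so
it isolates true turnover from richness gradients.

**Decay regressions and halving distance.** Similarity `y` vs geodesic
distance `x` (km, WGS84) under three forms, each fitted by OLS on its
linearizing transform:

| form | model | fitted as |
|---|---|---|
| linear | `y = ax + b` | y on x |
| logarithmic | `y = a·ln(x) + b` | y on ln x |
| exponential | `y = b·e^(ax)` | ln y on x |

The **halving distance** is the closed-form solution of `model(x) = S0/2`,
where `S0` is the initial similarity (by default the maximum observed pair);
it expresses "how many km until half the starting similarity is gone" and is
comparable across regions, zones and models. Because the n(n−1)/2 pairs
share sites, significance comes from matrix permutation (site labels of the
similarity matrix permuted rows-and-columns together, model refitted,
add-one corrected p).

**Explanatory matrices.** Geodesic distance between centroids; Euclidean
distance on the principal components of the (correlation-matrix) PCA of the
environmental variables; absolute differences in mean elevation (isolation
proxy), elevation range (heterogeneity proxy) and area.

**Attribution.** Simple and partial Mantel tests (residual-permutation
scheme), multiple regression on distance matrices (MRM), and the
seven-fraction Venn partition of the full-model R² into pure and joint
effects of geographic distance (G), environmental distance (E) and
mean-elevation difference (A), plus incremental ΔR² for extra matrices.

**Zonation.** Latitudinal/longitudinal bands and elevation classes with the
whole decay analysis repeated per zone, for directional and elevational
comparisons of turnover speed.

**Synthetic test bed.** `distdecay.synth` generates landscapes (jittered
site grid, parametric ridges, spatially structured environment) and
communities driven by switchable mechanisms — dispersal limitation, niche
filtering, ridge-crossing barrier costs that may grow with elevation — with
the generating truth returned alongside, so mechanism recovery is testable.

## Worked example

```python
import distdecay as dd
from distdecay import synth

sites, occ = synth.demo_dataset(seed=0)          # 164 sites x 191 species
sim = dd.similarity_matrix(occ, "jaccard")
geo = dd.geo_distance_matrix(sites)
for form in ("linear", "logarithmic", "exponential"):
    fit = dd.fit_decay(sim, geo, form)
    fit = dd.decay.attach_significance(fit, sim, geo, n_perm=199, seed=1)
    print(form, fit.a, fit.b, fit.r2, fit.s0, fit.halving_distance, fit.p_perm)
```

prints (formatted):

```
164 sites, 191 species, 13366 pairs
linear       a=-0.00044  b=0.6200  R2=0.574  S0=0.977  HD=298 km  p=0.005
logarithmic  a=-0.27970  b=2.0983  R2=0.618  S0=0.977  HD=316 km  p=0.005
exponential  a=-0.00207  b=0.9344  R2=0.495  S0=0.977  HD=314 km  p=0.005
```

Similarity falls significantly with distance under all three forms
(p = 0.005 is the minimum attainable with 199 permutations), and the three
halving distances agree that half the initial similarity is lost within
roughly 300 km on this landscape. Continuing,

```python
E = dd.env_distance_matrix(dd.env_pca(sites, variance_target=0.95), sites.site_ids)
A = dd.scalar_diff_matrix(sites, "mean_elev")
print(dd.mantel_simple(sim, geo, n_perm=199, seed=2).r)   # -0.757
vp = dd.partition3(sim, geo, E, A)
print(vp.fractions(), vp.residual)
```

partitions 85% of the similarity variance, most of it in the joint
geography-environment fraction (0.475) — as expected on a landscape whose
environment is itself spatially structured, the generator's default.

The same stages are scriptable from the shell (`distdecay synth | sim |
dist | decay | mantel | varpart | zones | pipeline`); `distdecay pipeline
--config run.json` writes every matrix, fit table and partition plus a
manifest of output digests for reproducibility.

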