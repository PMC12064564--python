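# microvi

Joint probabilistic modeling of microbiome survey count data with mean-field
variational inference.

## The problem

Microbiome surveys deliver a samples × taxa table of overdispersed,
compositional sequence counts together with heterogeneous context: continuous
environmental or host covariates, categorical spatiotemporal labels (for a
marine survey: biogeographic province, depth layer, season), and the implicit
co-occurrence structure of the taxa themselves. Conventional analyses treat
abundance–covariate associations and taxon–taxon associations separately;
`microvi` estimates them jointly in a single generative model, for analysts
who want interpretable effect sizes, a latent embedding of taxa, and a
principled way to ask which data source actually improves prediction.

## The model

Counts follow a negative binomial with mean–dispersion parameterization,

```
w_ij ~ NB(τ_j μ_ij, φ_j),    E(w_ij) = τ_j μ_ij,
Var(w_ij) = τ_j μ_ij + (τ_j μ_ij)² / φ_j,
```

with a taxon shape parameter τ_j ∈ (0,1), dispersion φ_j > 0, and a log-linear
mean anchored by a per-sample compositional offset t_i (a zero-aware geometric
mean of the sample's counts), so the linear predictor acts on an approximately
centered log-ratio scale:

```
log μ_ij = log t_i + η_ij,
η_ij     = x_i'γ_.j  +  (r_i α + d_i δ + s_i ϑ) β_.j  +  η_ij^[I].
```

The three mechanisms are (i) **direct coupling**: covariates x_i with
coefficients γ (p × q); (ii) **latent coupling**: one-hot context vectors
(province r_i, depth d_i, season s_i) mapped through coefficient matrices α,
δ, ϑ into a shared k-dimensional latent space β (k × q); and (iii) a
**latent interaction term** in the style of item–item basket models: for a
present taxon j,

```
η_ij^[I] = (1/(a_i − 1)) ρ_.j' Σ_{m≠j, w_im≠0} β_.m,      η_ij^[I] = 0 if w_ij = 0,
```

where a_i is the number of taxa present in sample i. Sparsity-inducing
Laplace(0, λ) priors sit on all coefficients, a reciprocal half-Cauchy
(scale υ) on each φ_j, and a flat Beta(1,1) on each τ_j. The posterior is
approximated with a factorized Gaussian on the unconstrained scale (log φ,
logit τ) optimized by stochastic gradient ascent on the ELBO with analytic
gradients; `microvi` adds held-out cross-validated LLPD model selection,
component ablation, posterior predictive checks, and downstream read-outs
(cosine-distance kNN modularity clustering of β, symmetrized interactions
I = (ρ_i'β_j + ρ_j'β_i)/2 with credible-interval sign calls, group-level
effect summaries).

## Worked example

`examples/01_simulate_and_fit.py` simulates a survey from the generative model
with known truth and fits it back:

```
$ python examples/01_simulate_and_fit.py
simulated 60 samples x 30 taxa, mean count 12.9, 40% cells nonzero
fit: 12000 iterations, final ELBO -3115.0
Pearson r between fitted and true covariate effects (gamma): 0.906
```

The correlation of 0.906 between the posterior-mean γ and the generating γ*
says the direct environmental couplings are recovered from counts alone.
`examples/03_modules_and_interactions.py` continues to the latent read-outs:

```
3 latent modules of sizes [11, 11, 8], modularity 0.639
adjusted Rand index vs planted modules: 1.000 (1 = perfect recovery)
```

i.e. greedy-modularity clustering of the fitted latent vectors exactly
recovers the three taxon communities planted in the simulation, and the
module-wise depth effects (δβ) separate shallow- from deep-associated
communities. `examples/02_model_selection.py` shows hyperparameter search and
ablation: removing the covariate component drops the held-out LLPD from
−4.18 to −6.19 nats per cell, quantifying its predictive contribution.

A thin CLI mirrors the library for shell pipelines:

```
microvi simulate --out sim --seed 3
microvi fit --counts sim/counts.tsv --covariates sim/covariates.tsv \
            --metadata sim/metadata.tsv --out fit --k 5 --iters 10000
microvi embed --fit-dir fit --knn 6
```

Input formats are plain TSV: counts (first column `sample_id`, one column per
taxon), numeric covariates, and metadata with `province`, `depth_layer` and
`season` (or an ISO `date` from which the calendar-quarter season is derived).

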