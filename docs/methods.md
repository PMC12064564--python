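# Methods

## Generative model

For a survey of n samples and q taxa, counts are modeled as
`w_ij ~ NB(τ_j μ_ij, φ_j)` in mean–dispersion form: `E(w) = τμ` and
`Var(w) = τμ + (τμ)²/φ`. The shape parameter τ_j ∈ (0,1) absorbs disparities
in overall abundance between taxa; φ_j > 0 is the taxon's dispersion. The
log-mean decomposes into a fixed per-sample offset and a linear predictor,
`log μ_ij = log t_i + η_ij`, with η the sum of a direct covariate term `Xγ`,
three one-hot context terms coupled through a shared latent space
(`Rαβ`, `Dδβ`, `Sϑβ`), and a presence-conditional taxon–taxon interaction
term. Zeros are data: every observed cell, zero or not, enters the
likelihood. The interaction term is exactly zero at absent cells, and for a
present cell averages the latent vectors of the *other* present taxa of the
sample against the taxon's interaction loadings ρ_.j.

Assumptions worth keeping in mind: counts are conditionally independent
across cells given the parameters and the presence pattern; the interaction
term conditions on observed presence rather than modeling it (no zero
inflation or hurdle component); all context enters through one-hot
categories; a single Laplace scale λ is shared by every coefficient block.

## Offsets

Because sequencing depth is arbitrary, the model needs a per-sample scale.
The default estimator is the pseudo-count geometric mean
`t_i = exp(mean_j log(w_ij + pseudo))` with `pseudo = 1` — a simple,
consistent zero-aware surrogate for the geometric mean, making η act on an
approximately centered log-ratio scale. The estimator is a strategy argument
(`compute_offsets(..., estimator=...)`), so a different zero-aware geometric
mean can be dropped in without touching callers. `pseudo = 0` is allowed only
for tables without zeros, where the estimator becomes the exact geometric
mean.

Two standard preprocessing steps are provided. The top-contributor filter
keeps the union over samples of each sample's shortest count-descending
prefix reaching a fraction (default 40%) of its library; ties are broken by
ascending taxon index and the first crossing is included. Note that this
operation is *not* idempotent: re-applying it recomputes library sizes on the
restricted table, so the retained set can only shrink. Common-sum scaling
rescales every row to the smallest library size and re-rounds half-to-even,
because the NB likelihood consumes integers.

## Priors

Laplace(0, λ) on every entry of α, δ, ϑ, β, γ, ρ (sparsity-inducing; one
shared λ); for the dispersion, the reciprocal of a half-Cauchy(0, υ)
variable, which in closed form is again half-Cauchy with scale 1/υ,
`p(φ) = (2υ/π) / (1 + (υφ)²)`; and flat Beta(1,1) on τ ∈ (0,1).

## Variational inference

The posterior is approximated by a fully factorized Gaussian on the
unconstrained scale: identity for coefficients, log for φ, logit for τ, with
the log-Jacobians added to the objective. The ELBO is maximized by stochastic
gradient ascent: the entropy of the factorized Gaussian is analytic, and the
joint term uses reparameterized Monte-Carlo gradients (default one draw per
step). Because no automatic-differentiation framework is used, the gradients
of the log-joint are derived in closed form (standard GLM-style chain rule
through the NB log-pmf, plus the bilinear/trilinear structure of the latent
terms) and are verified against central finite differences in the test
suite at relative tolerance 1e-4.

Optimizer: Adam-style per-coordinate adaptive steps, default learning rate
0.01 with an optional polynomial decay `lr/(1 + d·iter)`, iteration cap
30 000. Initialization: variational means ~ Normal(0, 0.1), log-sd = −2.
Convergence: the trace of per-iteration MC-ELBO values is smoothed over a
100-iteration window; the fit stops early when the smoothed value changes by
less than 1e-4 in relative terms. Every run is exactly reproducible from its
seed; a non-finite ELBO raises an optimization error recommending a smaller
step size.

Ablation removes a component's predictor term *and* its parameter block (and
the latent space β itself once no component uses it), so the free-parameter
count shrinks by exactly the removed block size.

## Held-out LLPD and cross-validation

Model selection scores hyperparameters (k, λ, υ) by the log posterior
predictive density of held-out data, reported **per held-out cell**:
`LLPD = mean_cells log( mean_draws p(w | draw) )`. Cross-validation holds out
random *cells*, not whole samples: the interaction term and the offsets both
need a sample's presence pattern, which an entirely unseen sample lacks.
Held-out cells are strictly masked from the likelihood and from the presence
sums (and from a_i) during fitting. When scoring a held-out cell, the
interaction branch is chosen by the held-out observation itself while the
presence sums come from training cells only; the averaging denominator is the
actual number of summands, which reproduces the 1/(a_i − 1) form exactly on
training cells. Because the LLPD is per-cell, values are comparable across
fold sizes but are on a different scale from implementations that report
sums or other normalizations of the same quantity.

The random search samples k uniformly over an integer range and λ, υ
log-uniformly (defaults k ∈ [25, 300], λ, υ ∈ [0.01, 1]); settings are scored
by mean cross-validated LLPD and ranked. The published-scale budgets
(50 draws × 5 folds × 50 initializations) are configuration; reduced budgets
are used throughout the tests. `multi_init` refits from distinct seeds on one
fixed 20% random-cell holdout so that the reported spread reflects
optimization noise only.

## Posterior predictive check

The test statistic of a count matrix is the mean over posterior draws of its
total log-likelihood, with the predictors (including the interaction term's
presence pattern) held fixed at the observed data for every matrix scored, so
the statistic does not depend on which matrix it scores. Replicates are NB
draws given those predictors, and the p-value is the fraction of replicates
whose statistic falls strictly below the observed one (ties count zero). The
calibration experiment draws the "observed" matrix from the fitted model
itself and scores it symmetrically with the replicate ensemble, which makes
its rank exactly exchangeable and the p-value exactly uniform; the p-value of
a model refitted to its own small training matrix is *not* uniform — the fit
adapts to the observed matrix and the statistic sits above the replicate
distribution — which is a known property of posterior predictive p-values,
not a defect of the optimizer.

## Synthetic-data generator

The generator runs the model forward at chosen scales. Defaults (n=60, q=30,
p=3, binary province/depth/season, k=5): covariates standard normal then
centered; context categories uniform; coefficients Normal with sd 0.75 (γ),
0.6 (α, δ, ϑ), 0.3 (ρ); 25% of γ and ρ entries set exactly to zero to mimic
sparse effects; τ uniform on (0.2, 0.8); φ log-uniform on (0.5, 2), i.e.
strong overdispersion. These scales give realistic sparse tables (roughly
30–50% nonzero cells, mean counts around 10) in which the effects are
identifiable at n=60.

Latent modules are planted by drawing β columns around g=3 centroids
(sd 1.0·√k in norm, within-module noise sd 0.1) arranged as a regular simplex
— the maximally angularly separated configuration, pairwise cosine distance
1 + 1/(g−1) — embedded in the leading right-singular subspace of the stacked
context coefficients. The embedding choice reflects what a latent module *is*
in this model: a community with a distinct spatiotemporal signature; it is
also what makes the partition recoverable, because β is only informed through
the context and interaction couplings, and centroid directions orthogonal to
the context row space would be shrunk away by the prior.

The interaction term conditions on presence, which is circular at generation
time; counts are therefore drawn in two passes (first without the interaction
term, then redrawn with the interaction computed from first-pass presence).
Offsets are unity at generation so estimated offsets are part of what the
pipeline must absorb. Rows that come out all-zero are redrawn.

What the generator does **not** emulate: real library-size distributions and
their depth stratification, taxonomic correlation structure, biogeographic
autocorrelation, or zero inflation beyond the NB. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to the ways real surveys violate
them.

## Numerical and design choices

- NB log-pmf via log-gamma functions; sampling via the (size=φ,
  prob=φ/(mean+φ)) mapping.
- Degenerate samples with a single present taxon get interaction value 0
  (empty sum), avoiding division by zero.
- kNN graphs symmetrize by union; distance ties break by ascending taxon
  index. Community detection is greedy modularity maximization
  (Clauset–Newman–Moore, via networkx, deterministic for fixed input);
  module labels order by decreasing size. For the q=30 test scenarios the
  graph uses k_nn = 6 (about half the expected module size); the
  survey-scale default is k_nn = 10.
- Interaction significance uses equal-tailed posterior credible intervals
  (default 95%) on the per-draw symmetrized matrices; the point estimate uses
  posterior-mean ρ and β.
- An all-zero latent column has no direction; its cosine distances are
  defined as 1 with a warning.
- Effect summaries aggregate γ (environment), δβ (depth), αβ (province) and
  ϑβ (season) by uniform within-group means.

## Known limitations

- The latent space is identified only up to invertible linear maps;
  cosine-distance clustering removes per-taxon scale but not a shared linear
  distortion. In practice a common "intercept-like" direction appears in the
  fitted β (per-taxon baseline corrections that the bounded τ cannot absorb,
  routed through the context and interaction terms); strong planted structure
  survives it, weak structure need not.
- The presence-conditioned interaction term can *proxy* categorical context:
  presence patterns are depth-driven, so ablating the depth component does
  not reliably hurt held-out prediction while the interaction term remains.
  Ablation conclusions are cleanest for components with no such proxy (e.g.
  the direct covariate term) or with the interaction term excluded.
- Mean-field VI underestimates posterior variance; credible-interval sign
  calls on interactions are anti-conservative to an unquantified degree.
- Per-cell LLPD values are not comparable to implementations with a
  different (e.g. summed or differently normalized) definition of the same
  quantity.
- The suite's problem sizes (n ≤ 80 in fits, q ≤ 30) are chosen so the full
  pipeline — including 5-fold-style cross-validation and 50-repetition
  calibration experiments — runs in minutes on one CPU; all budgets are
  configuration, and survey-scale runs simply raise them.
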