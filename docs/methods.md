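# Methods

## Problem and model

Cellular-resolution spatial transcriptomics (Stereo-seq, Slide-seqV2,
Pixel-seq) produces spot × gene UMI count matrices where each spot covers
roughly one to a few cells, total counts per spot are low (tens to low
hundreds), and datasets reach 10⁵–5·10⁵ spots. `spotvae` infers each spot's
cell-type composition Y_i from its count vector X_i with a variational
encoder–decoder:

    z_i   ~ N(0, I_D)
    Z_i   = E_σ(X_i) ⊙ z_i + E_μ(X_i)          (reparameterization)
    Y_i   = sparsemax(D_ω(Z_i))
    μ_ig  = l_i (s_g Σ_t y_it u_tg + γ_g)
    X_ig  ~ NB(μ_ig, β_g)

The encoder E maps log1p counts to the mean and diagonal standard deviation
of a Gaussian posterior over a D-dimensional latent code; the decoder D_ω
maps the code to T cell-type logits, and **sparsemax** — the Euclidean
projection onto the probability simplex — turns them into proportions with
exact zeros, matching the sparse compositions of small spots. Expected
expression mixes frozen cell-type signatures u_tg (estimated from a labelled
scRNA-seq reference), with a trainable gene-specific scaling s_g and
additive noise γ_g. Counts are negative binomial with mean μ and gene
inverse-dispersion β_g:

    pmf(x; μ, β) = Γ(x+β)/(Γ(β) x!) (β/(β+μ))^β (μ/(β+μ))^x,
    Var X = μ + μ²/β.

Poisson and zero-inflated NB (per-gene dropout τ_g) variants are available,
as is a DNN ablation: the same hidden/output stack applied directly to
counts, with no latent variable.

The model treats spots independently given their counts; there is no spatial
smoothness prior, and coordinates are used only for evaluation (Moran's I).

### Per-spot library factor

The mean equation above carries no per-spot depth term, yet real spots
differ several-fold in total counts; without a depth term the proportions
absorb depth. Each spot therefore gets a fixed multiplicative factor
l_i = total counts / median total counts, computed once per dataset and
switchable off (`use_library=False`).

## Reference signatures

u_tg and β_g are estimated from the labelled reference by direct NB maximum
likelihood: X_cg ~ NB(o_c u_{t(c),g}, β_g) with fixed per-cell offsets
o_c = total/median-total (so u is on a "median-library" scale), one mean per
(type, gene) and one dispersion per gene shared across types. Optimization
is joint gradient ascent on (log u, log β) — positivity for free — with a
monotone line search: a step that lowers the total log-likelihood is halved
and retried, so the likelihood trace is non-decreasing by construction.
Initialization is the offset-adjusted per-type mean for u and a method-of-
moments estimate for β. Genes with no counts in a type keep u_tg = 0
exactly; genes with no counts anywhere keep β at the floor. β is clamped to
[1e-3, 1e4] to keep Γ evaluations finite. Convergence is declared at
relative log-likelihood change < 1e-6 (default `tol`).

## Pseudo-spots (supervised signal)

A pseudo-spot pools k ~ uniform{k_min..k_max} reference cells drawn
uniformly without replacement (default k ∈ {1..5}; the synthetic benchmark
uses {1..3} to match its tissue), sums their counts, and binomially thins
the sum so the expected total UMI matches a target — by default the median
total of the spatial dataset under analysis, so the supervised examples live
in the same noise regime as the real spots. Ground-truth proportions are
cell-count fractions (the standard benchmark convention), not UMI shares.
Pseudo-spots carry no coordinates.

## Objective and training

Real spots contribute the single-sample negative ELBO

    L = D_KL(q_φ(Z|X) ‖ N(0,I)) − log p_θ(X|Z),

with the KL in closed form, ½ Σ_d (μ_d² + σ_d² − 1 − log σ_d²). Pseudo-spot
rows contribute the same terms plus an L1 penalty Σ_t |y_pred − y_true|
(mean over pseudo rows). L1 is safe with sparsemax's exact zeros, where
cross-entropy is undefined off-support.

**Supervised weight.** The reconstruction term sums over all G genes and is
O(G · depth) per spot, while the per-spot L1 penalty is O(1). With equal
weights the supervised term is numerically inert: the decoder flattens, γ_g
absorbs the data, and the posterior collapses (KL → 0, all spots decode to
the same composition). The default supervised weight is therefore the number
of genes, which puts both terms on the same extensive scale; it is a plain
config field for sensitivity analysis. `kl_weight` defaults to 1.

Trainable parameters are φ, ω, s (exp-parameterized), γ (softplus) and τ
(sigmoid, ZINB only); u and β stay frozen at the reference estimates.
Mini-batches of 128 mix real and pseudo rows at `pseudo_ratio` = 0.5;
optimizer is Adam at 1e-3. 10% of the pseudo-spots are held out and the
validation L1 (posterior-mean forward pass) drives early stopping with
patience 10, restoring the best parameters. A `pretrain_epochs` option
trains on pseudo-spots alone first. One seed controls initialization, batch
shuffling and the reparameterization draws, making training bit-reproducible.

The networks are NumPy MLPs (defaults: two hidden ReLU layers of 128 units,
D = 10) with hand-written backpropagation, including the sparsemax
Jacobian (I − 11ᵀ/|S| on the support S, zero elsewhere); gradients are
verified against central finite differences in the test suite for all three
likelihoods. Inference (`deconvolve`) uses the posterior mean Z = E_μ(X)
with no sampling, so repeated calls are identical; it is batched to bound
memory.

Numerical floors: σ ≥ 1e-4, μ ≥ 1e-8 (likelihoods stay finite on all-zero
spots), softplus/sigmoid evaluated in overflow-safe forms. Sparsemax needs
no tie-breaking: the projection is unique; coordinates exactly at the
threshold receive the projected value.

## Evaluation metrics

* **Marker correlation** — Spearman's ρ (average ranks for ties) between a
  type's inferred proportions and each of its marker genes' expression
  across spots; zero-variance vectors yield NaN, never an imputed 0, and
  NaNs are excluded from summary medians.
* **Moran's I** — I = (n/ΣW) Σ_ij w_ij (x_i−x̄)(x_j−x̄) / Σ_i (x_i−x̄)², on a
  k-nearest-neighbour graph (default k = 6) with row-standardized binary
  weights; ≈ −1/(n−1) under spatial randomness.
* **JS distance** — √(Jensen–Shannon divergence), base-2 logs, a metric in
  [0,1]. The reported comparator is a marker-derived composition per spot
  (each type's mean marker expression, normalized across types; spots with
  no marker signal get the uniform composition) — a pragmatic stand-in for
  an unknown truth, defined here explicitly because no canonical choice
  exists.

## Synthetic benchmark

`simulate_reference` draws a shared log-normal(0,1) gene baseline, gives
each type a block of marker genes upregulated `marker_fold` = 6 (≥ 4-fold,
so markers are unambiguous), scales to 2000 expected counts per cell, draws
β_g log-uniform on [0.3, 10] (small β = strong overdispersion), applies
log-normal(0, 0.3) cell size factors (median-normalized), and samples NB
counts. `simulate_tissue` arranges spots on a grid whose horizontal bands
each favour one type — sampling probabilities decay with distance to the
band center, `band_softness` controlling boundary mixing, echoing laminar
tissue — draws 1..k_max cells per spot for the true sparse Y, and samples
NB counts at mean total UMI 100 with log-normal(0, 0.3) spot depth factors.
Default scale: T = 5 types, G = 300 genes, 100 reference cells/type,
50 × 40 = 2000 spots, k_max = 3 — the benchmark the tests and the
acceptance script run end-to-end in well under a minute on one CPU.

What the generator does **not** emulate: bead/nanoball binning artifacts,
spatial bleed or segmentation error, batch effects between reference and
tissue, cell types absent from the reference, and real marker-gene
redundancy. Passing the benchmark shows the estimator and optimizer recover
the truth when the model family matches the data; it does not certify
performance under reference–tissue mismatch.

## Known limitations

* CPU-only NumPy training; fine at benchmark scale and linear in spots, but
  no GPU path.
* The NB signature model shares one dispersion per gene across types.
* Uniform (not type-stratified) cell sampling for pseudo-spots reproduces
  reference type imbalance; the imbalance is logged.
* Proportions are point estimates; no uncertainty intervals.
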