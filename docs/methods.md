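# Methods

## Setting

`freda` implements privacy-preserving, federated, unsupervised domain
adaptation for regression. N *source* clients each hold a labeled tabular
dataset (samples × P features); one *target* client holds unlabeled data for
the same features, tagged by group (in the motivating application: tissue of
a DNA-methylation sample, with the label being Horvath-transformed age); an
*aggregator* coordinates and holds no data. The goal is a per-group linear
model that predicts the target's labels despite covariate shift — some
features' dependency structure differs between source and target — without
any party revealing raw data.

The pipeline has four phases:

1. **Feature models.** One Gaussian-process regression (GPR) per feature f
   models that feature from all others on the pooled source data, trained
   through masked matrix products and secure aggregation.
2. **Weights.** The target client scores how typical its observed values of
   each feature are under the source-trained predictive distribution, per
   group, and converts the scores into elastic-net penalty weights.
3. **Lambda.** Weighted elastic nets are trained federatively over a grid of
   regularization strengths λ; λ for held-out groups is predicted from a
   linear model of log10(λ) on domain similarity (or by source-side CV).
4. **Final models.** One federated weighted elastic net per target group;
   the models are broadcast to the target for inference.

## Feature models (phase 1)

For feature f with source inputs `X = X_source without column f` and source
targets `x_f = column f`, the linear-kernel GPR has closed-form predictive
distribution on target rows `X*`:

    K   = sigma_k^2 X X^T + sigma_eps^2 I
    K*  = sigma_k^2 X* X^T
    K** = sigma_k^2 X* X*^T
    mean = K* K^-1 x_f,   cov = K** - K* K^-1 K*^T

Only Gram matrices of the data enter. Hyper-parameters `(sigma_k2,
sigma_eps2)` maximize the local marginal likelihood per client (L-BFGS-B in
log-parameters, box bounds [1e-6, 1e6], init (1, 1), analytic gradients, the
best-evaluated point returned so the result never degrades the init); the
global values are the unweighted mean of the per-client optima, computed
through the secure sum (a sample-size-weighted mean is available via
`aggregate_hyperparams(..., sample_sizes=...)`). Per-client optimization per
feature follows the "each source client maximizes its local marginal
likelihood" reading; averaging local optima approximates, not equals, the
pooled optimum, which is why the transparency guarantee below is stated *at*
the aggregated hyper-parameters.

**Federation transparency.** Because the masked protocols reconstruct the
exact pooled Gram matrices, the federated predictive mean and variance equal
the pooled closed form at the same hyper-parameters up to floating-point and
fixed-point noise; measured gaps are ~1e-11 at P=50, n_S=200 — far inside
the 1e-6 contract asserted in the tests.

## Privacy mechanisms

**Randomized encoding.** All data-holding parties derive a common mask
`M (d × P)`, d = (P−1) + `d_extra` (default `d_extra=10`), entries i.i.d.
standard normal (rank-checked, resampled up to 5 times), from a seed the
aggregator never sees. Each party ships `X_p L_p S` where
`S = (M M^T)^{1/2}` (symmetric PSD root via eigendecomposition, negative
eigenvalues clipped at 0) and `L_p` is the Moore–Penrose left inverse
`(M^T M)^{-1} M^T`. Since `L_p M = I` and `S S^T = M M^T`, cross-party
products of encodings equal the raw Gram blocks exactly, while individual
encodings live in a d-dimensional space that hides values and
dimensionality. A per-party randomized null-space component
(`randomize_left_inverses=True`) is available; it preserves `L_p M = I` and
hence all results.

**Secure aggregation.** Scalar/vector aggregates (hyper-parameter means,
FedAvg model averages) run on a 2^64 fixed-point ring (default 32 fractional
bits): every unordered party pair shares a seed, draws the same pseudo-random
ring tensor per round, one adds and one subtracts, so masks cancel *exactly*
and the aggregator sees only masked ring elements. Encoding reserves
headroom bits for the party count and raises a protocol error on overflow.
Quantization error is at most `2^-32 × n_parties` per entry.

**Masked predictive mean.** The aggregator computes `B = K* K^{-1}`, applies
a random invertible row mask `C` (condition number capped at 1e8, redrawn up
to 5 times), and sends each source client only its masked column block; the
client returns the block times its private feature column to the target,
which sums the contributions and removes `C` with `C^{-1}`. Only the
*diagonal* of the predictive covariance is released to the target (the
confidence score needs nothing else).

**Transcript audit.** Every cross-party payload is logged with a content
digest. The audit fails if any digest of a private payload (raw matrices,
single feature columns, label vectors) appears in a cross-party message, or
if mask keying material is routed to the aggregator. This is an operational
check of information flow in the simulated deployment, not a cryptographic
proof; the threat model is semi-honest throughout.

## Confidences and penalty weights (phase 2)

For target sample m and feature f with predictive mean mu and standard
deviation sigma, the confidence is the two-sided normal tail probability

    c = 2 Phi(-|x_mf - mu| / sigma),

1 at zero deviation, strictly decreasing in the standardized deviation.
(The measure is sometimes written without the negation, which would land in
[1, 2] and make the weight law negative; the tail form is the meaningful
one.) Sigma is floored at 1e-12; a zero-variance prediction that matches
the observation exactly has confidence 1.

**Observation noise.** The predictive *latent* variance
`diag(K** - K* K^-1 K*^T)` excludes the noise term. Observed target values
do contain noise, so comparing them against a nearly noise-free predictive
spread would drive all z-scores up and all confidences toward 0, erasing the
contrast between stable and shifted features. The confidence computation
therefore uses the observation-level spread `sqrt(latent variance +
sigma_eps^2)` by default; `include_noise_in_confidence=False` restores the
noise-free variant.

Confidences are averaged per target group (tissue) and mapped to penalty
weights `w_f = (1 - c_f)^k`, `k > 0` (default k = 3). Well-modeled features
have calibrated z-scores, hence c roughly uniform on [0, 1] and mean weight
around (1/2)^k; shifted features have c near 0 and weight near 1.

## Weighted elastic net (phases 3-4)

Objective on pooled source data (RSS deliberately *unnormalized*, so λ is on
the pooled-RSS scale; the unpenalized intercept absorbs the label offset):

    J(beta) = ||y - b - X beta||^2
              + lambda [ alpha sum_f w_f |beta_f|
                         + (1-alpha)/2 sum_f w_f beta_f^2 ],   alpha = 0.8.

**Federated training.** FedAvg: 100 global rounds × 20 local full-batch
epochs, learning rate decaying exponentially 1e-4 → 1e-5 across rounds.
Local epochs are forward–backward (proximal-gradient) steps: explicit
gradient on the smooth part, exact soft-threshold at `lr·λ·α·w_f` on the L1
part. A raw sign-subgradient step oscillates around zero coordinates with
objective increase ~`lr·(λαw)^2` per epoch at large λ, which is incompatible
with monotone local training; the proximal step is monotone for
`lr < 1/L`. Each local slice must not increase the local objective, else the
learning rate is halved (≤ 5 times) and the slice retried; persistent
increase raises a training error. Model averages are weighted by local
sample counts and computed through the secure sum.

**Local objective scaling.** Each client's local objective is
`(n_pool/n_local)·RSS_local + λJ(beta)`: the local RSS is lifted onto the
pooled scale so that the sample-weighted FedAvg target is exactly the pooled
objective. Without the lift the implicit target is `RSS_pool/N + λJ`, i.e.
regularization inflated by the client count, and convergence slows by a
factor N. With the lift the measured pooled-objective gap to the exact
optimum is < 0.2% for 1–8 clients under the default schedule; with one
client the scale is 1 and federated training *is* centralized gradient
training, step for step.

**Oracle.** `centralized_wen_oracle` solves the same objective by cyclic
coordinate descent with exact soft-thresholding (update
`S(2ρ_j, λαw_j) / (2||x_j||^2 + λ(1-α)w_j)`), stopping when the maximum
subgradient-optimality (KKT) residual falls below 1e-9; measured residuals
are < 1e-9 on random instances. It doubles as the non-federated reference
path for λ-grid comparisons in tests.

**Baseline.** `en_ls_baseline` is the classic non-adaptive epigenetic-clock
recipe: elastic net with 10-fold CV over the λ grid (scikit-learn, exact
objective mapping `alpha_sklearn = λ/(2n)`, `l1_ratio = α`), then ordinary
least squares restricted to the selected support (ridge-stabilized at 1e-8
if singular; intercept-only if the support is empty).

## Lambda selection (phase 3)

Default grid: 15 log-spaced values on [1e-3, 1e2] (the desk-scale validation
studies use 8 values on [1e-2, 1e2] to keep 60-run Monte-Carlo studies
tractable). For each labeled target group, the grid argmin of MAE — always
in chronological years, after the inverse age transform, with predictions
clipped to the transform's image — is selected, ties to the smaller λ. A
least-squares line of log10(λ) on similarity (λ spans orders of magnitude,
so the log scale is the natural one for a "simple linear model") is fitted
on the labeled groups and predicts λ for held-out groups, clipped to the
grid range. By default the first and last group (sorted) are the labeled
fitting groups. The similarity-free fallback selects λ per group by K-fold
CV on the source side, folds stratified within clients, the weighted elastic
net retrained federatively per fold and grid point.

## Age transform

`horvath_transform(a) = log((a+1)/(adult+1))` for `a ≤ adult`, else
`(a − adult)/(adult+1)`; continuous, strictly increasing, `adult = 20`. The
inverse maps model outputs back to years for all MAE reporting; round-trip
error is < 1e-10 over the full age range.

## Synthetic data generator

The generator emulates the structural features the method depends on, at
desk scale:

* **Shared linear dependencies.** `X = Z W + eps` with latent factors
  `Z ~ N(0, I)` (rank 6 by default), loadings `W` shared by all domains,
  feature noise sd 0.1 — strongly collinear, like co-methylated CpG blocks.
* **High-dimensional, small-n.** Default P = 100 features against a pooled
  source of 80 samples (4 clients × 20); the pooled sample count is below P
  so the regression is not identifiable without regularization, which is the
  regime where covariate shift can hurt a non-adaptive model at all. (With
  n >> P the true coefficients are identifiable and shift is harmless — an
  early generator draft in that regime showed no adaptation signal, by
  construction rather than by implementation error.)
* **Planted covariate shift.** For the target domain, the loading vectors of
  a chosen 20% of features are rotated: `w'_j ∝ w_j + s·u_j` rescaled to
  keep `||w'_j|| = ||w_j||`, with per-group magnitudes
  `s ∈ strength × (1.0, 0.5, 0.25)` over three groups (strength 3 by
  default). Marginal feature variances are preserved; cross-feature
  dependencies break — exactly what the per-feature GPRs can detect. The
  implied similarity score of a group is `1/(1 + s)`, supplied to the
  λ-prediction step as the analogue of an external tissue-similarity table.
* **Labels.** `y = 1 + X beta + nu` in transformed-age space (`nu` sd 0.2),
  with `beta` supported on 10 *stable* features, unit norm, so `sd(y) ≈ 1`
  (≈ 21 years per transform unit around the adult threshold) and a model
  that avoids shifted features can generalize. Target labels are generated
  but returned only in the ground-truth record, never on the target dataset
  object, so unsupervised stages cannot touch them.

What the generator does **not** emulate: bounded beta-distributed
methylation values, probe-level measurement error, batch effects, realistic
age distributions, tissue-specific mean shifts, or the 466k→13k feature
preprocessing of real methylation studies. Passing tests therefore
demonstrate correctness of the algorithms and the claimed protocol
identities, and the *existence* of the adaptation effect under the stated
covariate-shift model — not clinical-grade age prediction.

## Numerical choices

* Cholesky jitter ladder: `1e-8 × mean(diag)`, escalating ×10 up to 3 times;
  failure raises a numerical error.
* Predictive variances clipped at 0; values below −1e-6 (relative) raise.
* Fixed point: 32 fractional bits in a 2^64 ring; overflow raises.
* Row mask condition number capped at 1e8.
* Predictions are clipped to the age-transform image before inversion.
* Client ordering is fixed (sorted ids) for reproducible reductions;
  identical seeds give bit-identical runs.
* MAE ties in λ selection go to the smaller λ.

## Study sizes and runtimes

The validation studies (`freda.evaluation`, also driven by
`scripts/acceptance.py`) use: 100 random instances for the masked-product
identity; 2–8 parties for secure sums; P=50, n_S=200, n_t=60 with 2/4/8
clients for federation transparency; n=200 with 100 signal dimensions and 10
seeds for hyper-parameter recovery (the dimension is chosen so the MLE's
~14% sampling error sits well inside the 25% recovery band — the study tests
the estimator, not draw luck); 20 runs at the default generator conditions
for shift detection; n=200, P=50, 1/2/4/8 clients for federated convergence;
and 20 seeds × 3 partition schemes (uniform, [0.5, 0.2, 0.2, 0.1],
[0.533, 0.266, 0.133, 0.068]) for the adaptation-gain comparison with
en-ls. A full pipeline run at default conditions takes ~7 s on one CPU; the
complete study suite runs in ~10 minutes.

## Known limitations

* Semi-honest model only: no malicious security, no differential privacy,
  no dropout-robust aggregation, in-process message passing rather than real
  transport (the message layer is an interface a transport could implement).
* Linear kernels only; no sparse/inducing-point GP approximations, so
  phase 1 is O(P · n_S^3) at worst.
* FedAvg's λ-grid retraining is from scratch per grid point (no warm
  starts).
* The similarity→λ line assumes a monotone log-linear relation; with many
  groups and a non-monotone relation the prediction degrades gracefully via
  grid clipping but is not revisited.
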