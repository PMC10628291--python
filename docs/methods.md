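# Methods

## The model

`toxgan` learns a map from a chemical treatment condition to the joint
distribution of a rat's 38 clinical-pathology measurements (21 clinical
chemistry, 17 hematology). A condition is

    c = concat(s, d, t)

where `s` is a fixed-length molecular-descriptor vector for the compound,
`d ∈ {1, 3, 10}` the relative dose level (low : mid : high = 1 : 3 : 10,
anchored at the maximum tolerated dose), and `t ∈ {3, 7, 14, 28}` the
treatment duration in days. All condition features and all endpoint values
are min–max scaled per feature to [−1, 1] on the training partition.

The generator `G(c, z)` is a five-hidden-layer MLP
(4096/2048/1024/256/64 by default, LeakyReLU + batch normalization per
hidden layer, tanh output) fed with the scaled condition and an equally
long standard-normal noise vector `z`; for the 1826-descriptor
representation the input is 3656-dimensional and the output has 38 nodes.
The critic `D(x, c)` scores (profile, condition) pairs with a five-hidden-
layer MLP (2048/1024/256/64/32, LeakyReLU slope 0.2, dropout 0.4 after
each hidden layer, scalar output; 1866 inputs at full scale).

Two objectives are implemented:

* `wgan_gp` (default): critic loss `mean D(x̃,c) − mean D(x,c)` plus a
  gradient penalty `gp_weight · E[(‖∇_x̂ D(x̂,c)‖ − 1)²]` on interpolates
  x̂ between real and generated profiles (condition held fixed); generator
  loss `−mean D(x̃,c)`. The Wasserstein critic avoids the vanishing-gradient
  and mode-collapse failure modes of the saturating log loss on small
  tabular samples.
* `log_gan`: the classic conditional log-loss (scores through a sigmoid,
  clamped logs), kept as a literal alternative.

### Condition-smoothness regularizer

Because the condition space is continuous and sparsely sampled (a study
grid of compound × dose × time), the generator loss carries an additional
term

    L_GR = E_{z, c} [ min( ‖G(c+Δc, z) − G(c, z)‖ / max(‖Δc‖, ε), τ ) ]

with `Δc ~ N(0, σ² I)` drawn in scaled condition space over the full
condition block (descriptors + dose + time jointly). The term bounds the
generator's local Lipschitz ratio in the condition directions, encouraging
interpolation between neighbouring conditions rather than memorization of
the training grid; `τ` caps the ratio for numerical stability. Defaults:
`λ = 1.0` (weight), `σ = 0.01`, `τ = 10`, `ε = 1e−8`.

### Training and checkpoint selection

Adam (lr 1e−4, betas (0.5, 0.9)), batch size 128, five critic updates per
generator update; one epoch is one pass over the treated records. Every
`checkpoint_every` epochs the generator weights are snapshotted and scored
on the training set with the same 100-valid-draw rule used at inference;
the selected checkpoint maximizes mean cosine similarity (ties: minimal
mean RMSE, then latest epoch). Batch normalization uses evaluation-mode
running statistics at inference. Training aborts on a non-finite loss,
retaining the checkpoints taken so far.

The networks and both objectives (including the double backpropagation
needed for the gradient penalty) run on a small reverse-mode autodiff
module (`toxgan.nn`) whose vector–Jacobian products are themselves tensor
expressions; its gradients are verified against central finite differences
in the test suite.

## Validity filtering and profile reporting

Five endpoints (Neu, Eos, Bas, Mono, Lym) form the white-blood-cell
differential; their percentages must plausibly total ~100. Accounting for
bench counting and rounding, a draw whose five components sum to more than
105 is an invalid record and is rejected. A condition's reported profile
Ḡ is the element-wise mean of the first 100 valid draws (draw-until-100
semantics; a draw-100-and-average-survivors switch exists). Virtual
cohorts keep every accepted draw as one subject and enforce validity per
subject; noise is consumed in fixed-size blocks so results are independent
of output chunking.

## Evaluation

Per condition, cosine similarity and RMSE are computed between Ḡ and the
real mean profile R̄ (treated animals averaged first), in natural units.
The null reference is the background control: the same metrics between
the real mean profiles of every unordered pair of conditions (C(n,2)
pairs). Model-vs-real metric distributions are compared to the background
with a two-tailed Wilcoxon rank-sum test, exact (permutation) for the
smaller sample ≤ 8 without ties, tie-corrected normal approximation
otherwise, with no multiplicity adjustment. Per-endpoint error summaries
report Pearson correlation across conditions and error quantiles.

A conventional per-endpoint structure–activity baseline harness fits 12
regressor families (k-NN, decision tree, extremely randomized trees,
random forest, ε-SVR, linear SVR, SGD, AdaBoost, gradient boosting,
Bayesian ARD, Gaussian process, MLP; scikit-learn implementations) on the
same features the GAN conditions on, with 5-fold cross-validated
hyperparameters, reporting test MSE per endpoint × family.

## Toxicity assessment

For one condition and endpoint, the treated group is compared to its
time-matched vehicle controls: Shapiro–Wilk normality screen (α = 0.05)
per group; both normal → unpaired pooled-variance t-test (equal
within-group variances assumed); otherwise two-sided Mann–Whitney U.
`p < 0.05` flags toxicity. The synthetic side tests the 100 individually
valid generated draws as the treated group (a group test needs
within-group variance; testing the averaged profile instead is available
as a variant). Consistency per endpoint is the fraction of conditions
whose real and synthetic flags agree; rollups report min–max over the
hepatotoxicity panel (ALT, AST, LDH, ALP, GTP, TBIL, DBIL) and the
nephrotoxicity panel (BUN, CRE, Na, K, Cl, Ca, IP).

The ULN of an endpoint is the maximum over a designated control
population (28-day vehicle-treated rats); exceedance is strict (`>`), and
Hy's-law counting over a cohort tallies subjects with
(ALT > ULN or AST > ULN) and TBIL > ULN.

## The synthetic study generator

`toxgan.fixtures` emulates the structure the method assumes, with no
external data: compounds with i.i.d. standard-normal descriptor vectors;
the full condition grid compound × {3,7,14,28} days × {low,mid,high};
5 treated animals per condition and 10 time-matched controls per time
point. The ground-truth map is

    profile(s, d, t) = baseline · (1 + effect_scale · a(s, d, t)),
    a = sigmoid(wᵀ P s) · (d / 10) · log(1+t) / log(1+28)

— linear in a 2-D projection of the descriptors, multiplicative in
relative dose and log time, monotone non-decreasing in both for the
designated toxic endpoints (hepatic and renal markers, maximal relative
shifts 0.6–3.0). The WBC differential is generated on a simplex scaled to
exactly 100 before noise, so per-animal noise places sums near 100 and
occasionally past the 105 boundary, exercising the validity filter.
Per-animal noise is Gaussian with sd = 5% of each endpoint's baseline
(a typical analytic coefficient of variation); baselines are plausible
healthy-rat values in the panel's natural units.

What the fixture does **not** emulate: real marginal distributions and
units of any public study database, inter-laboratory shifts,
heteroscedastic or skewed endpoint noise, missingness patterns, and
correlated multi-organ effects. Passing the recovery tests therefore
shows the pipeline can learn a smooth condition→profile map under its own
stated assumptions — not that it reproduces any particular study's
numbers, which require the corresponding full-scale data and training.

## Problem sizes used in tests and the acceptance script

Desk-scale runs use the scaled-down study conditions: 20 compounds,
descriptor dimension 8, hidden layers [64, 32] for both networks, 16/4
compound train/held-out split, and 400 epochs × 10 minibatches = 4000
generator steps — set to the point where the checkpoint cosine/RMSE
series flatten, mirroring the full-scale practice of training to
checkpoint-metric convergence. Recovery is judged against the fixture's
own background control: the generated profiles of held-out conditions
must beat the background median cosine and RMSE, averaged over three
training seeds. The acceptance script additionally runs the toxicity-
consistency assessment over the 48 held-out conditions and a 100,000-rat
virtual cohort (high dose, 28 days, the most susceptible held-out
compound) with ULN from 1000 simulated control rats.

## Numerical choices and degenerate inputs

* Min–max scaling: constant features map to 0; out-of-range inference
  inputs clip at ±1; the inverse transform maps constants back exactly.
* Non-finite descriptor entries (3-D descriptor failures) are imputed
  with 0 before scaling, with a logged count.
* Cosine similarity rejects zero-norm profiles (lab values are strictly
  positive); norms inside the regularizer and penalty carry small
  epsilons so gradients at zero stay finite.
* Structural similarity is cosine on per-feature z-scored descriptors
  (robust to heterogeneous descriptor scales); all-zero standardized
  vectors get similarity 0 to others, warned. Ranking ties in the
  similarity split break lexicographically by compound id.
* Identical constant treated/control groups short-circuit to p = 1; a
  constant sample fails the normality screen (Shapiro–Wilk is undefined
  on it) and routes to the rank test.
* Rejection sampling aborts when the observed validity rate falls below
  1/max_attempts_factor (default 1/10).

## Known limitations

* The default descriptor engine is RDKit's ~210-descriptor 2-D catalogue;
  the original 1826-descriptor configuration is supported through the
  same provider interface when such an engine is available.
* Desk-scale networks and the synthetic study are deliberately small;
  headline numbers from full-scale studies on public databases are out of
  reach without those data and a long training run.
* Adversarial training quality depends on seed and length; the checkpoint
  selector mitigates but does not remove this variance.
* "Non-drug-like" is an explicit user-supplied flag, not inferred; ATC
  codes and approval years likewise come from the compound table.
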