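# Methods

## Model

Two domains over one feature space are assumed to share a low-dimensional
non-negative structure: a source matrix `Xs` (n_s × d, rows are samples)
and a target matrix `Xt` (n_t × d) are modeled as `Xs ≈ Ws H`,
`Xt ≈ Wt H` with a common basis `H ∈ ℝ₊^{r×d}` and per-domain,
per-sample coefficients `Ws ∈ ℝ₊^{n_s×r}`, `Wt ∈ ℝ₊^{n_t×r}`. The fit
minimizes the weighted squared Frobenius loss

    J(Ws, Wt, H) = αs ‖Xs − Ws H‖² + αt ‖Xt − Wt H‖²,  αs + αt = 1,

by multiplicative updates. Classification then happens in the augmented
space `[x; Hx]` with a soft-margin linear SVM trained on labeled source
samples only; the learned weight vector splits into an original-space part
`w` and a subspace part `v`, so `f(x) = wᵀx + vᵀHx + b`.

Orientation note: with samples as rows, `H` spans the *feature* space and
is the object shared between domains; the per-domain matrices carry one
coefficient row per sample, which is what lets the two domains have
different sample counts while sharing `H`, and what makes `Hx` a valid
per-sample projection.

### Why augmentation can transfer

`[x; Hx]` is a linear image of `x`, so the hypothesis class of the linear
SVM is unchanged. What changes is the regularization geometry: writing the
effective weight as `w + Hᵀv`, the L2 penalty on `(w, v)` makes directions
inside the row space of `H` cheaper than directions outside it. Since `H`
is fitted jointly on both domains, it concentrates on structure the
domains share; the margin optimizer is therefore biased toward
domain-invariant discriminative directions and away from source-specific
noise directions. The benefit is consequently largest when the raw feature
space is high-dimensional and noisy relative to the rank of the shared
structure, and it vanishes when `r = 0` (the model provably degenerates to
a plain linear SVM, asserted in the tests).

## Optimization

* **Updates and order.** Per iteration: the shared basis `H` first, then
  `Ws`, then `Wt`. Plain one-matrix NMF (`nmf_factorize`) uses the same
  multiplicative rules and, by default, the same basis-first order; with
  identical domains, equal weights and shared initialization the joint
  iteration then coincides with the plain one bit-for-bit (the joint
  numerator `αs·A + αt·A` is parenthesized so it evaluates to exactly `A`
  in floating point). A flag restores the coefficient-first order.
* **Initialization.** All factors start from seeded uniform(0.1, 1.1)
  draws. Strict positivity matters: a zero entry is absorbing under
  multiplicative updates.
* **Stopping.** Default: the maximum entry-wise change across `H`, `Ws`,
  `Wt` falls below `eps` (default 1e-6), or `max_iter` (default 1000)
  iterations. A stop-on-any-factor rule is available behind
  `stop_rule="any"` but can trigger prematurely when one factor stalls
  while the others still move.
* **Degeneracies.** Every denominator gets `δ = 1e-12` added, so
  zero-denominator entries yield a finite (and, with a zero numerator,
  unchanged) update rather than NaN. The objective trace is recorded every
  iteration; monotone non-increase within 1e-9 relative is asserted in the
  tests and holds across all seeded runs.
* **Non-uniqueness.** The factorization is at best unique up to
  permutation and positive diagonal rescaling of the factors (`Ws D`,
  `Wt D`, `D⁻¹H` leaves the loss unchanged — asserted numerically); all
  downstream uses (projection, recovery scoring) are invariant to, or
  scored modulo, that class.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `r` | min(10, d) | shared-subspace dimension; capped at d |
| `alpha_s` | 0.5 | source weight in the joint loss (target gets 1 − αs) |
| `C` | 1.0 | SVM margin cost on the augmented space |
| `eps`, `max_iter` | 1e-6, 1000 | optimizer stopping controls |
| `denom_guard` | 1e-12 | additive guard in multiplicative ratios |

None of these have field-established values for this method; the defaults
are the package's own choices and everything is configurable. `alpha_s`
deliberately does not compensate for unequal sample counts: with
`αs = 0.5` the (usually smaller) target domain carries equal weight, which
is what a transfer setting wants.

## Feature extraction

Raw single-channel segments (Bonn-format text, 173.61 Hz) are reduced by
one of three extractors, all parameter choices being conventional rather
than prescribed:

* **WPD** — wavelet-packet decomposition, Daubechies-4, level 3,
  periodization mode; the energies of the 8 frequency-ordered terminal
  subbands. The signal is truncated to the largest multiple of 2³ samples
  (4096 of a 4097-sample Bonn segment) so the transform is exactly
  orthonormal and subband energies sum to the analyzed energy (Parseval,
  asserted at 1e-6 relative).
* **STFT** — periodic Hamming window of 256 samples, 50% overlap, no
  padding (tail frames dropped); squared-magnitude spectra averaged over
  frames and summed into 8 equal-width bands over 0–fs/2. The periodic
  window makes a pure-DC signal's spectrum exactly zero outside bins
  {0, ±1}, so the DC-isolation property is exact rather than approximate —
  the reason the framing is done directly instead of through a padded
  high-level spectrogram API.
* **KPCA** — kernel PCA (RBF, γ = 1/d unless set, 10 components) via
  scikit-learn, fitted on whichever matrix is passed as training data;
  fitting on pooled source+target is the transductive option consistent
  with the subspace learner's assumptions.

Because WPD energies are non-negative but KPCA scores (and general CSV
input) are not, the pipeline applies per-feature min–max scaling to [0, 1]
with statistics pooled over both domains (both are available when the
subspace is learned). Pooled min–max was chosen over abs() or shifting
because it simultaneously equalizes feature scales, to which the
multiplicative updates are sensitive. Constant features map to 0.

## Synthetic data

`gen_domain_pair` plants the model's own assumption: a shared basis
`H* = |N(0,1)|^{r_true×d}`, per-class coefficient centers spaced by
`class_separation`, target centers additionally shifted by `domain_shift`
on a random half of their coordinates (so the shift is partial, not a pure
translation), coefficients `|center + N(0,1)|`, and
`X = W H* + N(0, noise_sd)` clipped at zero. Coefficients use absolute
value rather than clipping to avoid an atom at zero; the data clip is
forced by the non-negativity precondition. Defaults (d=12, 150/50 samples,
separation 2, shift 1, noise 0.3) mirror a small two-class EEG feature
study.

What this generator does *not* emulate: feature correlations beyond the
planted low-rank structure, non-Gaussian heavy-tailed EEG artifacts,
label noise, and class imbalance. Tests passing on this generator show
the machinery is correct and the transfer mechanism operates when the
model's assumptions hold; they do not certify performance on real EEG.

`gen_eeg_segments` produces Bonn-shaped signals (4097 samples at
173.61 Hz): background = alpha/beta-band sinusoids with random phases in
Gaussian noise; "ictal-like" adds a dominant 3.5 Hz rhythm (spike-wave
range) scaled by `ictal_amplitude_factor`, guaranteeing a variance gap.
It is a caricature for end-to-end plumbing tests, not a neural-mass
simulation.

### The domain-shift study conditions

The transfer-benefit experiment in the test suite and acceptance script
uses d=20, r_true=4, 150/50 samples, separation 2.0, shift 1.0, noise 0.8,
with the method at its defaults and the baseline (a plain linear SVM on
the raw, unscaled features — everything the transfer pipeline adds is
part of the method under test) run to full convergence. The regime —
many noisy features over a rank-4 shared structure — is where the
augmentation mechanism has room to act; at these conditions the measured
mean target-accuracy gain is about +3 accuracy points. The per-seed
win/loss indicator is noisy at 50 target samples (accuracy granularity
0.02), so the mean gain is the robust summary; the directional test counts
wins, ties included, across its 10 fixed seeds.

## Evaluation protocols

* **Scenario 1 (matched distributions):** stratified 10-fold CV; per fold
  the full pipeline is refitted with the held-out fold exposed, unlabeled,
  as the target domain (transductive), and metrics are averaged over
  folds.
* **Scenario 2 (shifted distributions):** per round, a stratified 75%
  subsample of the source trains a classifier scored on a stratified 25%
  subsample of the target; the roles are then swapped; the round averages
  both directions, and 10 seeded rounds are averaged (exactly 20 fits).
  All resampling derives from a single seeded generator, so reports are
  bit-reproducible.
* **Metrics:** accuracy plus precision/recall/F1 with respect to a
  designated positive class (binary) or macro-averaged one-vs-rest
  (multiclass). Precision is defined as 0 when nothing is predicted
  positive, making F1 0 rather than undefined.
* **Method comparison:** the Friedman rank test
  `χ²_F = 12N/(k(k+1)) Σ_j (R̄_j − (k+1)/2)²` with rank 1 for the best
  score and average ranks on ties, p-value from χ² with k−1 degrees of
  freedom; the Nemenyi critical difference
  `CD = q_α(k) √(k(k+1)/(6N))` with tabulated q for α ∈ {0.05, 0.10},
  k ≤ 10. (An independent SciPy computation cross-checks the Friedman
  statistic in the tests; the implementation itself is the closed form.)

## Known limitations

* The joint loss is non-convex; multiplicative updates find a local
  optimum that depends on the seeded initialization, and basis recovery is
  only expected (and only asserted) up to row permutation and scaling, in
  the mean across seeds.
* Multiplicative updates converge slowly near the optimum; exact-recovery
  assertions use 2000 iterations with a tight entry-change threshold.
* No KL-divergence objective, no sparsity or graph regularization, no
  kernelized decision function, and no use of labeled target samples
  during subspace learning (the factorization is fully unsupervised).
* The Nemenyi table stops at 10 methods; larger comparisons need a
  studentized-range source.
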