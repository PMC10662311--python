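# Methods

## Problem setting

Cross-subject generalization: a classifier trained on feature tables from
several subjects must predict labels for a subject whose data was never
seen (domain generalization, DG) or for which only unlabeled features are
available (local domain adaptation, LDA).  The motivating application is
EEG emotion recognition from differential-entropy features, where per-class
distributions are multimodal and every subject's features are shifted
relative to the others.

## Local domains

For one binary (one-vs-rest) problem with labels ±1, a *local domain* is
built around every positive sample: the exemplar plus its k₁ nearest other
positives and k₂ nearest negatives in Euclidean distance.  Ties are broken
toward the lowest sample index, so construction is deterministic.  When
fewer candidates than requested exist, all of them are used and the
shortfall is logged rather than raised.  Each local domain carries a kNN
graph over its members: weights `exp(−‖x_i−x_j‖²/σ_v)` between points that
are within each other's k_graph neighbourhoods (either direction suffices),
zero diagonal, with σ_v the median of the nonzero pairwise squared
distances inside the block (σ_v = 1 when all points coincide; a fixed
numeric bandwidth can be supplied for testing).  The symmetric normalized
Laplacian `L_v = E^{−1/2}(E−S_v)E^{−1/2}` has spectrum in [0, 2]; isolated
nodes use the convention 0^{−1/2} = 0, zeroing their row and column.  The
exemplar participates in its own graph as an ordinary node.

## Objective and solver

The objective (README, "The model") is minimized by alternating closed-form
block updates.  For each local domain v in turn, the solver repeats:

1. λ ← softmax(−t/μ) with t_u = tr(w̃ᵀX_uL_uX_uᵀw̃) (max-subtracted for
   overflow safety) — the exact minimizer of its entropy-regularized block;
2. θ_u ∝ 1/(res_u + 1e−12) with res_u the local regression residuals — the
   exact simplex minimizer for the default exponent r = 2;
3. a joint closed-form solve of the quadratic in (f, f_v, w̃, w_v, b_v, b):
   the pseudo-label system for f is eliminated first, then f_v, then the
   global model w̃, the local model w_v and the two biases, by back-
   substitution of a block Gaussian elimination.  All inversions are linear
   solves; a ridge escalating from the configured jitter by factors of 10
   (up to 1e−2) rescues near-singular systems;
4. V ← (WWᵀ + εI)^{−1/2} — the iteratively reweighted majorizer of the
   trace norm (ε = `jitter`, default 1e−6).

The loop stops when the relative objective change over the last two
iterates falls below `tol` (default 1e−4), or at `max_iter`.  Global blocks
(W, V, f, w̃, b) are shared across the domain loop, not reset; a `sweeps`
option repeats the whole domain loop (default 1).  Initialization is
deterministic — models at zero, pseudo-labels at the labels, uniform
simplex weights, V = I — with a seeded random option.

Three implementation details matter for correctness and speed:

* **Full Laplacian sum in the global-model system.**  The system matrix of
  the w̃ update inside the fitting loop carries the complete λ-weighted sum
  Σ_u λ_u X_u L_u X_uᵀ, matching the objective's own derivative.  (The
  single-domain form of this matrix is exposed by the public per-equation
  update function and is what the stationarity tests check; using it inside
  the loop would leave the other domains' smoothness terms outside the
  update and break monotone descent.)
* **The recorded convergence trace is the solver's exact Lyapunov
  function**: the objective with the model-alignment term restricted to the
  domain currently being relaxed (the only alignment term its updates
  carry) and with the trace norm in the smoothed majorized form
  `2β·tr((WWᵀ+εI)^{1/2})` — the quantity the ridge βV majorizes.  Every
  step is then an exact block minimization or majorization step, and the
  trace is non-increasing to machine precision; the literal objective value
  is recorded alongside (`full_objective_trace`), and `compute_objective`
  evaluates the literal objective term by term.
* **Low-rank pseudo-label solve.**  The n×n system for f is the identity
  plus a centering term minus a rank-(d+1) correction; for n large relative
  to d it is solved through a Woodbury identity in O(nd²) rather than
  densely, which keeps a 160-domain fit on ~500 samples under a second.
  The f_v system is structurally singular (every term is flanked by the
  centering matrix, so constants are in its null space; the constant
  component of f_v is absorbed by the bias b_v); it is pseudo-inverted with
  an eigenvalue cutoff of 1e−8 relative, which also keeps near-null noise
  out of the descent check.

## Hyperparameters

| name | meaning | default |
|---|---|---|
| α | ridge on each local model | 1.0 |
| β | trace-norm / global-model weight | 1.0 |
| μ | entropy temperature of λ | 1.0 |
| r | exponent on θ | 2 |
| k₁, k₂ | positive / negative neighbours per exemplar | 5, 5 |
| k_graph | kNN size of the local graphs | 5 |
| kernel | linear, one of 4 kernel families, or "mkl" | linear |
| tol | relative-objective stopping tolerance | 1e−4 |
| max_iter | inner-iteration cap per domain | 100 |
| jitter | majorizer smoothing / ridge rescue | 1e−6 |

Grid-search practice in this field tunes α, β, μ over {10⁻⁴ … 10⁴} and the
neighbour counts over {3, 5, 7, 9, 11, 13}; `grid_search` performs the
exhaustive p-fold search with folds formed by grouping source *subjects*
(p = 5 by default), since no target labels exist for ordinary
cross-validation.  Kernel bandwidths default to σ = 1/d ("auto"); the MMD
used for LDA weighting uses a Gaussian kernel with the median heuristic
over the pooled pairwise squared distances.

## Prediction

DG fusion uses θ_v² exactly (independent of the training exponent r); LDA
weights ζ_v ∝ exp(−Ψ_v) use the biased kernel-MMD estimator
`Ψ = sqrt(mean K_vv − 2 mean K_vt + mean K_tt)` (clipped at zero before the
root).  Multiclass decisions take the argmax of the raw one-vs-rest scores,
ties to the first class in sorted order; no calibration is applied.  In
kernel mode, unseen samples are first mapped through the empirical kernel
map against the stored training reference block.

## Synthetic data

The generator emulates the structure the method assumes: all subjects share
the same class semantics (cluster centers drawn once), classes are
multimodal (`clusters_per_class`, default 2, centers dispersed with spread
1.5σ around the class center), class center groups sit at the vertices of a
regular simplex with pairwise distance `class_separation·σ` (default 6σ),
and each subject adds a mean-shift vector with standard deviation
`subject_shift_scale` (default 1) — the simplest mechanism producing the
covariate shift the method targets; samples add isotropic noise σ
(default 1).  Defaults give 4 subjects × 3 classes × 40 samples in 6
dimensions.  Classes are balanced within every subject and samples cycle
through the class's clusters.  Everything is reproducible from one seed.

What the generator does *not* emulate: covariance rotations between
subjects, label noise, class imbalance, temporal autocorrelation, channel
structure, or any statistic of real EEG corpora.  Passing tests therefore
demonstrate the algorithm's internal correctness and its behaviour under
idealized additive shift, not performance on recorded EEG.  A minimal
differential-entropy utility (`½·ln(2πe·σ̂²)` of a Fourier-mask-filtered
window) lets the full signal-to-feature-to-classifier pipeline be exercised
synthetically.

## Evaluation protocols

Leave-one-subject-out: each subject in turn is the test domain; the
multiclass model is fitted on the rest and accuracies are aggregated as
mean ± standard deviation.  The empirical chance level repeats uniformly
random predictions over the test labels (1000 repeats by default); its
upper bound (UBCL) is the upper end of the 95% interval of the repeat
distribution under a normal approximation.  LDA-mode evaluation passes only
the held-out features to the weighting — labels cannot leak by
construction of the interface.

The acceptance script runs the solver on ten generated datasets under the
default study conditions and reports the median inner-iteration count
(typically 2–3, far below the ~30 observed for this family of alternating
solvers) and the three-class empirical chance level (~33.33%).

## Known limitations

* Fitting cost grows with the number of positive samples (one local domain
  each); thousands of positives per class will be slow in pure Python.
* The θ update implements the inverse-residual rule, which is the exact
  simplex minimizer only for r = 2; other r values reuse the same rule.
* With kernel maps the effective dimension equals the number of training
  samples, and the d×d solves become n×n; kernel mode is intended for
  small-to-moderate n.
* The monotone-descent guarantee applies to the recorded surrogate; the
  literal objective can fluctuate at ~1e−3 relative across domain blocks
  because each block optimizes its own alignment term.
* A_v is positive definite in exact arithmetic (its subtracted term is
  dominated); jitter escalation guards the finite-precision case.
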