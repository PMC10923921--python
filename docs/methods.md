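# Methods

This note documents the models, numerical choices and limitations behind
`reprt`, in the order the pipeline runs.

## Retention-time projection (GP regression)

A projection model maps calibrant RTs measured on a source CM to the same
molecules' RTs on a target CM. The relation is smooth and monotone in
practice (gradient elution warps a shared hydrophobicity ordering), but its
local curvature varies along the gradient — flat near the dead time and the
final hold, steep mid-gradient. We therefore use a 1-D Gaussian process with

* a **constant mean** (the training-target mean, in minutes),
* a **rational-quadratic kernel**
  `k(x, x') = σ_f² (1 + (x−x')²/(2αℓ²))^(−α)` — a scale mixture of squared
  exponentials whose shape parameter α lets short- and long-range structure
  coexist; as α → ∞ it degenerates to one squared-exponential length scale,
* a **fitted white-noise term** with a floor of 1e-6 (standardized units).
  Calibrant RTs are noisy measurements, so exact interpolation would chase
  replicate noise; the floor also keeps the kernel matrix well conditioned.

Inputs and targets are standardized to zero mean / unit variance before
fitting because marginal-likelihood optimization is scale sensitive and CMs
range from 10 to 100 min; predictions are de-standardized back to minutes.
Hyperparameters maximize the log marginal likelihood with L-BFGS from
seeded restarts (default 5; the workflows use 2–3, which suffices for 1-D
data). The fit is deterministic given the seed. Minimum 5 calibrant pairs;
predictions outside the training RT range are returned but flagged as
extrapolation, since a GP reverts to its constant mean away from data. The
fit itself is delegated to scikit-learn's `GaussianProcessRegressor`; the
module owns the contract, the standardization, the serialization format,
and an independent closed-form `rq_kernel` used for verification.

## Post-projection calibration

Projection accuracy collapses when the two LC setups order molecules
differently — additive/mobile-phase changes reorder elution for whole
compound classes, which a 1-D map cannot express. The calibration step fits
a second GP (ReICM → OCM, the *ReProjection model*) on the same calibrants
and replaces the comparison reference for each unknown by its **RePRT**
(its ReICM RT pushed through the ReProjection model). Projected candidate
RT and RePRT then share the OCM-specific distortion, which cancels.

* **ReICM selection** is automated as the argmax of `r²_c`, the squared
  Pearson correlation of calibrant RTs between ICM and each locally
  available method (ties broken by lexicographic cm_id). `r²_c` is a
  validated proxy for elution-order similarity; contexts with
  `r²_c < 0.95` carry a low-similarity flag.
* **Quality bands** are advisory only: `r²_c ≥ 0.992` with a
  behavior-representative calibrant set has been associated with
  calibration `RMSE_Ret` below ~3% of elution time; the estimate is
  explicitly marked unreliable for calibrant sets covering too few
  retention behaviors (shipped default: set name "E").
* **Mixed calibrant RTs**: when some calibrants lack experimental RTs on
  the ICM (e.g. the ICM is an external dataset), per-calibrant predicted
  RTs may be substituted on the ICM side only; calibrants missing anywhere
  are dropped and the usable count is logged.
* `err_before` (projected vs OCM experimental RT) exists only in
  validation mode; in application mode only `err_after` (projected vs
  RePRT) is defined.

Calibration is not free: between near-identical setups the ReProjection
step adds its own GP error, so `err_after ≈ err_before` (or slightly worse)
within a mobile-phase family. Its value is realized across families, where
direct projection errors of several percent of elution time drop to the
within-family level.

## Error metrics

Absolute errors in minutes are incomparable across 10–100 min gradients, so
all headline errors are percentages of the OCM's **elution time**, defined
as the maximum calibrant RT in the OCM (computed from the active calibrant
set, never from the programmed run time, which serves only as a sanity
bound). `RMSE_Ret` is the root-mean-square error, `MedE_Ret` the median
absolute error and `ME_Ret` the *signed* mean error (bias) — a flag
switches `ME_Ret` to mean-absolute for sensitivity checks, since signedness
conventions differ between reports. `r²` is always the squared Pearson
correlation, never a coefficient of determination of a fitted curve.

## Retention-behavior clustering and calibrant selection

Molecules' elution profiles (RT vectors over CMs, each CM divided by its
elution time so long and short methods weigh equally) are clustered with a
self-organizing map: rectangular grid (default 5×5, giving up to 25
behavior groups), Gaussian neighborhood, linearly decaying radius and
learning rate, prototypes initialized from seeded random samples, 5000
single-sample updates by default, mandatory seed (bit-reproducible). The
SOM is implemented in-package; it is a ~60-line algorithm and owning it
keeps determinism under our control.

Calibrants are selected greedily in two nested passes: (1) the medoid
(nearest-to-prototype molecule) of each non-empty behavior group, in
ascending group order; (2) molecules that most enlarge the per-CM RT span,
until the target size, aiming at ≥ 90% span coverage per CM. Ties always
break to the lexicographically smaller molecule id, and the selection is
nested — growing the target size appends, never reshuffles — which makes
group coverage monotone in the set size. No attempt is made to reproduce
any specific published group memberships: SOM partitions are
initialization-dependent, and the tests instead require agreement with
known synthetic group structure above a permutation baseline.

## QSRR module

A quantitative structure–retention relationship predicts RT on one CM from
precomputed 2-D molecular descriptors (descriptor computation is out of
scope; the module consumes a `molecule_id` × named-descriptor CSV). The
default regressor is a single-hidden-layer perceptron — 10 tanh units,
L-BFGS training, L2 regularization — with inputs and targets standardized
and zero-variance descriptors dropped. With `reg_strength="auto"` the L2
strength is chosen on an internal 75/25 validation split over the grid
1e-4 … 10; the wide upper end matters because a 10-unit network happily
interpolates training noise on a few hundred molecules when
under-regularized. Any tabular regressor honoring `fit`/`predict` with a
seed can be plugged in via `regressor_factory`. The train/validation split
utility forces a declared holdout (e.g. molecules overlapping an external
RT database) into the validation set and draws `floor(fraction · n)` of the
remainder for training, deterministically per seed.

## Candidate filtering and ranking

Per OCM, the RT-error threshold is **twice the OCM's `RMSE_Ret`**, computed
per stage from molecules with complete RT coverage; a candidate is positive
iff its error (% of elution time vs the unknown's reference RT) is at or
below the threshold — the boundary counts as positive, because only errors
*above* the threshold are rejected. Confusion counts follow the convention
that "positive" means accepted-by-filter: TPR = TP/(TP+FN),
FPR = FP/(FP+TN), TNR = 1−FPR, accuracy = (TP+TN)/total; unlabeled rows
are excluded with a logged count, and unknowns whose candidates are all
rejected are reported, never silently dropped. Ranking sorts candidates per
unknown by ascending RT error with lexicographic candidate-id tie-breaks, a
stable total order independent of input row order.

## Synthetic data generator

The generator is the test bed's ground truth, emulating exactly the
structure the method assumes:

* latent hydrophobicity `u ~ U(0,1)` per molecule;
* per-CM monotone sigmoid warp
  `RT = t0 + (T − t0) · sigmoid(a_c (u − b_c))` (dead-time plateau, steep
  mid-gradient, late plateau), with `a_c, b_c` drawn around family-level
  means so same-family methods share elution order;
* behavior groups: *non-retained* groups pinned just past the dead time
  (`t0 (1 + 0.2u)`), *outgeneral* groups receiving an additive
  group-by-family offset, *general* groups following the warp exactly;
* i.i.d. Gaussian noise (default 0.05 min) on every measurement, clipped
  to (0, run time].

The outgeneral offset is stored as a **fraction of each CM's gradient span**
and scaled to minutes per CM, rather than as one absolute minute value: a
single offset must remain feasible across 10–60 min methods. Offsets are
exactly shared by every molecule of a (group, family) pair — an offset that
would push any member outside (0, T] in any CM of its family is halved for
the whole pair until feasible (logged) — and are identically zero for the
first family, which acts as the reference frame. Defaults mirror a
realistic multi-CM RT database: 330 molecules, 30 CMs, 4 mobile-phase
families, 25 behavior groups.

What the generator does *not* emulate: physico-chemical retention theory
(no log K_ow or solvent-strength model), column-chemistry effects beyond
the family offsets, correlated (non-i.i.d.) measurement error, and
real descriptor–RT relationships (the QSRR benchmark uses a synthetic
linear map over noise descriptors). Passing tests therefore demonstrate the
statistical machinery — projection, calibration, selection, filtering —
under the method's assumed data structure, not chromatographic realism.

## Workflow conventions and problem sizes

OCM similarity classes A–D are declared through `additive_family` labels in
CM metadata: identical labels are class A; otherwise the distance between
trailing family indices maps 1 → B, 2 → C, ≥3 → D. With automatic ReICM
selection the chosen ReICM is excluded from the OCM pool, so an n-CM
validation produces n·(n−2) pairs. Every CLI run that writes an output
directory also writes a `manifest.json` (inputs, seeds, parameters,
version) sufficient for bit-identical re-runs.

The acceptance script runs the full pipeline at 150 molecules × 8 CMs ×
4 families with 35 calibrants, 40 unknowns × 12 candidates, and the QSRR
benchmark at 500 molecules × 50 descriptors averaged over 3 seeds — sizes
chosen so the complete reproduction stays in the tens of seconds on one
CPU while every class A–D is populated.

## Known limitations

* Projections are strictly 1-D (RT → RT); no covariates, no chaining
  through more than one intermediate CM.
* ReICM selection considers elution-order correlation only; a method could
  correlate well on calibrants yet diverge on chemistry the calibrants
  under-sample — the quality bands are advisory for exactly this reason.
* GP hyperparameter fits on < 10 calibrants can be unstable; the package
  enforces a floor of 5 pairs but more is better.
* The filter threshold inherits the uncertainty of the RMSE_Ret estimate it
  doubles; with few covered molecules it is itself noisy.
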