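# Methods

## The problem

In rapid event-related fMRI, trial-wise response amplitudes are often
estimated with a general linear model carrying one hemodynamic-response
(HRF) regressor per trial. When inter-stimulus intervals are short relative
to the ~30 s extent of the HRF, neighboring trial regressors overlap, and
the joint least-squares estimates ("LS-A") become serially correlated and
noisy. The popular workaround ("LS-S") fits one two-regressor model per
trial — this trial versus all other trials — which damps the correlation at
the price of one model fit per trial and a biased covariance treatment.

`itemsl` instead keeps the LS-A estimates and models their correlation
analytically. For a session with trial-wise design `Xt` (scans × trials)
and scan covariance `V`, the LS-A estimates

    Γ̂ = (Xtᵀ V⁻¹ Xt)⁻¹ Xtᵀ V⁻¹ Y

follow a trial-level linear model `Γ̂ = T B + H` whose design matrix is the
trial-to-condition transformation matrix `T` (indicator columns for
conditions, real-valued columns for parametric modulators, `X = Xt T`) and
whose temporal covariance is the **uncorrelation matrix**

    U = (Xtᵀ V⁻¹ Xt)⁻¹.

Decoding inverts this model: on the training sessions, generalized least
squares gives the weight matrix

    Ŵ = (Γ̂ᵀ U⁻¹ Γ̂)⁻¹ Γ̂ᵀ U⁻¹ T,

and the held-out session's design variables are predicted as `T̂ = Γ̂ Ŵ`
under leave-one-session-out cross-validation. Classification takes the
argmax across indicator columns of `T̂` (ties resolve to the lowest column
index); regression scores a parametric column by the Pearson correlation of
predicted and actual values. Balanced accuracy and median absolute error
are exposed as secondary measures. Predictions are pooled over folds and
scored once.

The voxel-by-voxel (spatial) covariance of the multivariate model is never
materialized: it is absorbed into the decoding weights, which is exactly
what the GLS inversion above does.

## Design matrices

* **HRF.** Double-gamma kernel: gamma-density response with shape 6,
  undershoot with shape 16, unit dispersions, response:undershoot ratio
  6:1, 32 s support, peak-normalized to 1. The peak sits at 5.0 s, within
  the conventional "around 6 s" description of the canonical response.
* **Convolution.** Events are boxcars of their duration on a microtime
  grid of TR/16; regressors are the continuous-time (Riemann-sum, i.e.
  `conv × dt`) convolution of the boxcar with the unit-peak kernel, sampled
  at the mid-TR time point of each scan (middle reference slice). Under
  this convention regressor amplitudes are independent of the microtime
  resolution, a 2-s stimulus peaks at ≈ 1.74, and an indefinitely
  sustained stimulus saturates at the kernel's time integral. Onsets are
  seconds from first-scan start and need not align with acquisition.
* **Nuisance terms.** Conditions not broken into trials get one pooled
  regressor per condition; a per-session constant is appended by default.
  `U` is computed as the trial block of the full `(Xᵀ V⁻¹ X)⁻¹` including
  nuisance columns, so trial–nuisance covariation is accounted for.
* **Scan covariance.** `V` defaults to identity (white noise); any
  symmetric positive-definite `V` is accepted and handled by Cholesky
  whitening.
* Designs with condition number above 1e8 are rejected loudly, naming the
  most collinear columns; there is no silent regularization in the
  estimation path.

## ReML calibration of the trial covariance

Raw LS-A estimates mix two variance sources: natural trial-to-trial
variability of the underlying amplitudes (isotropic) and the
design-induced correlation (shaped like `U`). Before decoding, each
session's covariance is recalibrated as

    Cov = λ₁ I + λ₂ U,

with `(λ₁, λ₂)` fitted by Fisher scoring on the restricted log-likelihood,
treating voxels as replicates and `T` as the fixed-effects design.
Because both components are diagonal in `U`'s eigenbasis, each iteration
is exact and O(t²). Numerical choices: moment-matched initialization,
non-negativity floor at 1e-10 of the data scale, step halving to keep the
restricted likelihood non-decreasing, at most 32 iterations, convergence
at 1e-6 relative change, and a small Levenberg-style ridge on the Fisher
matrix so the degenerate case `U = I` (components indistinguishable, total
covariance still identified) stays solvable. Non-convergence returns the
last iterate with a warning. Only training-session covariances enter the
weights; the test session's covariance is not used by prediction.

## Baselines

* **LS-S** is implemented exactly as t separate GLS fits (this-trial,
  all-other-trials, nuisance), keeping the first coefficient of each.
* **Fractional ridge** parameterizes per-voxel ridge solutions by the
  fraction of the unregularized coefficient norm retained (grid 0.05–1.00
  in steps of 0.05). With the design SVD, coefficient norms over a dense
  log-spaced α grid are cheap, and the α achieving each requested fraction
  is found by interpolating the monotone fraction–α curve. The per-voxel
  fraction is selected by cross-validation across sessions: amplitudes
  estimated on the training sessions are collapsed to condition means,
  mapped onto the held-out session's trials, and scored by time-series
  prediction R²; this mirrors how regularization strength is tuned via
  amplitude consistency of repeated stimuli in single-trial toolboxes.
  Nuisance columns are projected out before ridge shrinkage. The baseline
  is labeled "fracridge-only" in outputs: voxel-wise HRF libraries and
  data-driven noise regressors are deliberately out of scope.
* **Classifier for the baselines.** A linear support-vector classifier
  (C = 1) on trial estimates, per-voxel standardized with training-fold
  statistics, trained on one session and tested on the other(s), both
  directions, accuracies pooled over all test trials.

## Searchlights

Searchlights collect, for every in-mask voxel, all in-mask voxels whose
centers lie within the given radius (Euclidean distance in mm, inclusive
boundary; anisotropic voxel sizes supported). Boundary voxels keep
truncated spheres. On an isotropic grid a radius of 2 voxels yields 33
voxels at interior centers. Per center, the trials × neighbors estimate
block is extracted and the cross-validated inversion above is run;
performance maps carry NaN outside the mask and at centers below the
minimum voxel count. Searchlights are independent work units: any
execution order produces identical maps. Maps are written as NIfTI-1 in
the input grid, one map per contrast to classify or regressor to predict.

When the number of searchlight voxels exceeds the pooled training trials,
the GLS system is singular; the default is a hard error, with an explicit
opt-in Moore–Penrose fallback (`allow_pinv`), since the decoder's behavior
in that regime is not part of the validated method.

## Synthetic data

`simulate_searchlight` emulates one searchlight in a two-condition rapid
event-related experiment. Per voxel j, condition means
`μ_A,j, μ_B,j ~ N(0, 1)`; only a proportion `r` of voxels is informative —
for the rest `μ_B,j := μ_A,j`. Trial amplitudes are
`γ_i,j ~ N(μ_cond(i),j, σ_γ²)` with `σ_γ = 0.5`; inter-stimulus intervals
are uniform (default `U(0,4)` s), stimuli last 2 s, TR = 2 s, labels are
exactly balanced and randomly ordered, and the signal is
`Y = Xt Γ + E` with iid Gaussian noise of variance `σ²`. Defaults: S = 2
sessions, t = 100 trials/session, v = 33 voxels, r = 0.2,
`σ² ∈ {0.8, 1.6, 3.2}` across study scenarios. Reconstructed details that
the study conditions leave open, declared once here: trial timing
`onset_{i+1} = onset_i + t_dur + ISI_i` starting at 0; scan count
`ceil((last offset + 32 s)/TR)` so the last trial's HRF tail is covered;
noise iid across scans and voxels; a non-integral `r·v` rounds to nearest
(logged). A master seed spawns per-simulation substreams, so increasing
the number of simulations extends rather than reshuffles an experiment.

`simulate_volume` embeds an informative sphere in an otherwise
uninformative volume with shared trial timing, for localization checks.

What the generator deliberately does **not** emulate: temporally or
spatially correlated noise, voxel-specific or nonlinearly saturating
hemodynamics, non-stationary responses, head motion, and physiological
confounds. Passing the simulation studies therefore shows correctness of
the estimators and of the covariance handling under the model's own
assumptions — not robustness of any method on real data.

## Study drivers and problem sizes

`noise_isi_study` runs the 3 × 3 grid of noise variances and ISI ranges;
`sweep_information_curves` sweeps voxels, trials and the information
proportion. The package's reference runs use 100–200 simulations per
scenario (500 for the single headline scenario), sizes at which median
accuracies are stable to about one percentage point; all drivers are
deterministic given their seed.

Under these conditions the decoder reproduces the expected pattern: all
methods near ceiling at long ISI and low noise; at short ISI the analytic
inversion leads LS-S by double-digit percentage points in median accuracy
and never trails it; the fracridge-only baseline sits between; with no
informative voxels every method decodes at chance (50% for two classes,
25% for four). The exact numbers are computed by `scripts/acceptance.py`
and the test suite, not quoted here.

## Known limitations

* The inversion assumes linear effects and matrix-normal errors with a
  covariance that factorizes into a trial part (known up to the two ReML
  weights) and an unconstrained spatial part constant over trials.
* The fracridge baseline reconstructs a stated simplified configuration of
  a larger single-trial toolbox; absolute numbers for that baseline should
  be read with that in mind.
* Group-level inference, spatial normalization and fMRI preprocessing are
  out of scope; empirical use expects preprocessed volumes and event
  tables.
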