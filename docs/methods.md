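# Methods

## Scope and model

`cvbms` implements voxel-wise Bayesian model selection for first-level fMRI
GLMs of a visual novelty / subsequent-memory encoding task, from
recognition-confidence behavior through a 19-model GLM space, analytic
cross-validated model evidence, group-level random-effects model selection,
and the downstream group statistics.  It assumes preprocessed (realigned,
normalized, smoothed) 4D data; preprocessing itself, random-field-theory
corrections and retrieval-session imaging are out of scope.

### First-level GLM and evidence

Per voxel, y = Xβ + ε with ε ~ N(0, τ⁻¹I) after AR(1) prewhitening.  The
conjugate normal–gamma prior β|τ ~ N(μ₀,(τΛ₀)⁻¹), τ ~ Gam(a₀,b₀)
(shape/rate) yields the closed-form posterior and log marginal likelihood
stated in `cvbms.evidence`.  The cross-validated log model evidence (cvLME)
uses contiguous folds (default 2, matching the single-session design; the
number is configurable): for each fold, the posterior from the remaining
data — started from the non-informative limit Λ₀ = 0, a₀ = b₀ = 0 — is the
prior under which the held-out fold's analytic evidence is evaluated, and
folds are summed.  Correctness of the analytic evidence is anchored by a
brute-force quadrature oracle (dense trapezoid over weights and precision)
in the test suite and acceptance script.

Serial correlation: a single AR(1) coefficient per subject is estimated
from pooled least-squares residuals of the baseline model and applied as an
exact inverse-square-root transform to the data and *all* design matrices,
so evidence differences between models remain comparable.  The analysis
mask is the intersection of voxels whose mean signal exceeds a configurable
fraction (default 0.5) of the grand mean in every subject.

Family evidence is the log-mean-exp of member evidences (uniform
within-family prior); log Bayes factors are evidence differences.

### Design matrices

Event regressors are boxcars (sticks at zero duration) scaled by per-event
amplitudes, convolved with the canonical double-gamma HRF (nilearn's
glover model, 16 microtime bins per scan) and sampled at scan times
t = 0, TR, 2·TR, ….  Every design carries six motion regressors, a
discrete-cosine high-pass basis with 128 s cutoff (identical across models
so comparisons stay fair; the count rule K = ⌊2T/cutoff⌋ gives 8 columns at
206 × 2.58 s) and a constant.  Parametric modulators are mean-centered
across novel trials before convolution and not serially orthogonalized
against the unmodulated novelty regressor; centering alone separates main
effect from modulation, and the resulting column is numerically
near-orthogonal to the constant (|mean| ≲ 0.2% of its SD in practice).
The master regressor always stays a single unmodulated regressor.
Categorical models require at least one trial per category; the
five-category model therefore only exists for subjects who used the full
response range, and a parametric model whose modulator is constant across
trials is flagged degenerate.  The frequency-proportional neutral split
(GLM_2ns) is seeded per subject.

### Empirical modulators

The two probability-curve modulators are P(rating|old) and P(old|rating);
published descriptions of which of the two the "-ip" model uses conflict
between the figure definition and the results text, so both are exposed and
the assignment is a module flag (`behavior.SWAP_EMPIRICAL_NAMING`, default:
the figure convention, ip = P(rating|old)).  Empirical curves are affinely
rescaled v → 2v − 1 so all six modulator types share the [−1, 1] scale of
the theoretical transformations; empty conditional-probability cells are
imputed at the uninformative 0.5.  The logistic modulator is the ML fit of
oldness on the numeric rating, falling back to clipped empirical
probabilities under complete separation.

### Group-level BMS

The variational fixed point for the Dirichlet posterior over model
frequencies iterates subject attributions g_nm ∝ exp(LME + ψ(α_m) − ψ(Σα))
and α = α₀ + Σg, with flat α₀ = 1, convergence at max|Δα| < 1e-6 or 200
sweeps (non-converged voxels are counted and reported).  The likeliest
frequency is the mode of the marginal Beta(α_m, Σα − α_m) distribution,
(α_m − 1)/(Σα − 2), with the posterior mean as fallback where the mode is
not interior; the joint Dirichlet mode (α_m − 1)/(Σα − M) is available
behind a flag since the published convention is not stated.  Winner maps
break ties toward the lowest candidate index and record the tie count.
Family-level selection runs the same machinery on family-evidence matrices.

### Group statistics

Voxel counts use a strict LBF threshold within the analysis mask.  The
ANCOVA is the type-II partial F for the group factor in an OLS model with
dummy-coded site and gender plus continuous age, education and employment.
The JZS two-sample Bayes factor integrates the Zellner g-mixture
representation of the Cauchy(0, √2/2) effect-size prior by adaptive
quadrature; the posterior median effect size comes from the noncentral-t
likelihood times the Cauchy prior on a dense grid.  SVM classification
standardizes the 8 count features (4 thresholds × 2 contrasts), draws
balanced subsamples of the smaller class size, and summarizes stratified
k-fold balanced accuracy as the subsample mean with the 5th/95th percentile
interval — the published phrase "interval obtained as averages across
subsamples" is ambiguous, and percentiles of subsample accuracies are the
chosen reading.  Familywise error for second-level one-sample F-tests uses
sign-flip permutation of the maximum statistic with the (1 + #exceed)/(B+1)
p-value convention, which is valid (slightly conservative) under symmetric
errors, plus a cluster-extent filter (face connectivity, default k = 10);
Bonferroni is available as a fast fallback.  The number-of-regressors
analysis is a within-subject linear contrast over levels (1, 2, 3, 5) with
centered weights, conjoined with the mean-LBF memory test by the
minimum-statistic (maximum-p) rule.

## Synthetic cohort generator

The generator emulates the encoding session of a multi-group memory-clinic
study: 88 novel scenes (44 indoor / 44 outdoor) and 44 master repetitions
within 206 scans at TR 2.58 s, trial duration 2.5 s, randomized order,
onset-to-onset intervals uniform on [3.2, 3.8] s starting at 8 s (onsets
are not published; this schedule fits all 132 trials in the session).
Recognition responses are drawn per group from five built-in profiles
grading the hit rate P(rating 4–5 | old) from ≈0.75 (HC, SCD, AD-rel)
through ≈0.55 (MCI) to ≈0.40 (AD), with correspondingly flattening
rating–oldness coupling — the qualitative behavioral gradient of the
clinical groups, whose exact probabilities are unpublished.

The default 12×12×4 voxel grid is split into four equal slabs: novelty-only
(novel > master activation), novelty-plus-memory (novelty plus an
arcsine-modulated subsequent-memory effect), deactivation, and null.
Signal is the generative design times true amplitudes over a baseline of
100, with stationary AR(1) noise (SD 1.0, coefficient 0.3).  Amplitudes
grade by group: novelty 1.0 (HC/SCD/AD-rel), 0.8 (MCI), 0.5 (AD); memory
0.5 / 0.15 / 0.0; deactivation −0.8 / −0.6 / −0.4 — the AD group thus has a
diminished novelty response and *no* memory effect, mirroring the reported
clinical gradient.  Motion parameters are smooth low-amplitude random walks
that do not enter the signal; demographics are drawn independently of BOLD
(covariates of no interest) from group-wise age/gender distributions in the
published ranges.  The generator shares the HRF and design code with the
analysis side, so with σ → 0 first-level estimation recovers the true
amplitudes to machine precision — a forward/inverse consistency the tests
enforce at 1e-6.

What the generator does *not* emulate: anatomy and standard-space geometry,
physiological noise and scanner drift beyond AR(1), spatial autocorrelation
of noise, retrieval-session BOLD, and between-subject variability of HRF
shape.  Passing recovery tests therefore show that the selection machinery
is correct and well calibrated under its own assumptions, not that those
assumptions hold in real data.

## Problem sizes and numerical choices

Acceptance-grade computations run at desk scale by design: the recovery
cohort uses 12 control-like and 12 impaired-like subjects on the default
grid; frequency recovery uses 100 repetitions of 40 subjects with a fixed
28/12 composition (the standard recovery design: the composition realizes
the true frequencies exactly, evidences are well-separated with margin
N(8, 2²)); familywise-error calibration uses 400 null datasets of 8
subjects × 64 voxels at 299 sign flips, asserted against the nominal level
up to one-sided Monte-Carlo error; ANCOVA calibration uses 1000 label
permutations of 100 subjects.  Quadrature oracles: 301² × 300 trapezoid
grid for the GLM evidence (agreement ≤ 1e-3), 200 001-point transformed
grid for the JZS integral (relative agreement ≤ 1e-4).  Ties in winner
maps, empty families, improper priors, rank-deficient designs and
non-cross-validatable categorical splits (a category confined to one fold)
are all rejected or recorded as missing rather than silently repaired.

## Known limitations

Evidence values are computed in whitened space, so absolute cvLMEs depend
on the estimated AR(1) coefficient; only differences within subject are
interpretable.  The global-AR(1) noise model is deliberately simple.
Exceedance probabilities are not implemented (likeliest frequency is the
reporting statistic).  The SVM feature layout and several published
conventions (mask, LF formula, interval summary) are configurable
reconstructions, not verbatim specifications.
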