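# Methods

## Model and procedure

Common spatial patterns (CSP) finds channel-weight vectors `w` that
maximize the variance ratio of two classes of epoched, band-limited EEG:

    J(w) = w' C1 w / w' C2 w,

with `C1`, `C2` the class spatial covariance matrices. The maximizer is
the top generalized eigenvector of `C1 w = λ C2 w`; the mirrored problem
`(C2, C1)` supplies filters favoring the other class, and the top `l`
eigenvectors of each side form the `2l`-filter set.

Regularized CSP adds a quadratic penalty to the denominator,

    J_P1(w) = w' C1 w / (w' (C2 + α K) w),

with `K = I` giving Tikhonov-regularized CSP (TRCSP). The correlation
penalty (CCSP) instead uses the temporal similarity of the two classes:
form the class-average trial `X̄_i` of each class, compute the `c × c`
matrix `R` of Pearson correlations between channel `i` of `X̄_1` and
channel `j` of `X̄_2`, and set

    K1 = diag(a),  a_i = mean_j |r_ij|     (JP1 denominator),
    K2 = diag(b),  b_j = mean_i |r_ij|     (JP2 denominator).

`R` is generally not symmetric, so `a ≠ b`; the asymmetry is inherent to
the construction and is kept. Channels whose time courses look alike in
the two classes get larger denominators and hence smaller filter
coefficients as `α` grows. Using class averages instead of all trial
pairs keeps the correlation cost at `O(n·c)`.

For `G ≥ 3` classes the one-versus-rest (OVR) form pits each target class
against the pooled rest: `JP1 = (C_g, Σ_{m≠g} C_m + α Σ_{m≠g} K1^{(g,m)})`
and the mirrored JP2, with the pairwise penalty diagonals summed without
normalization. One `2l`-filter bank and one binary linear SVM per class;
prediction is the argmax of the per-class decision values, with ties
broken toward the lowest class id (logged).

The full pipeline: optional time-segment extraction → zero-phase 8–30 Hz
Butterworth band-pass (order 5 per band edge, i.e. a 10th-order transfer
function, squared again by the forward–backward pass) → filter fitting at
an `α` chosen by stratified cross-validation on the training set →
log-variance features `f_j = log(var(z_j) / Σ_k var(z_k))` → linear-kernel
SVM. `Σ_j exp(f_j) = 1` by construction and the features are amplitude
invariant.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `l` | 3 | filter pairs; `2l = 6` features per trial |
| `band` | (8, 30) Hz | sensorimotor mu/beta band |
| `filter_order` | 5 | Butterworth design order per band edge |
| `alpha_grid` | 1e-6 : 5e-5 : 1e-3 (20 values) | regularization weights searched by CV |
| `cv_folds` | 5 | stratified folds for both α and the SVM cost |
| `normalization` | trace-normalized per-trial mean | covariance policy (below) |
| `svm_c_grid` | 0.01 … 100 | SVM cost grid for the inner CV |

Covariance policy: the default forms `X'X / trace(X'X)` per trial and
averages within class. Trace normalization makes every trial contribute
on the same scale and makes `α` dimensionless across datasets; it also
makes the fitted filters exactly invariant to a global amplitude rescale.
`raw_sum` (`X'X` summed contributions, no normalization) is retained as
an option for literal fidelity to the plain covariance definition.

## Numerical choices

- The generalized eigenproblem is solved with the symmetric-definite
  routine (`scipy.linalg.eigh(A, B)`) rather than forming `B⁻¹A`;
  eigenvectors come out satisfying the Lagrangian constraint
  `w' B w = 1` directly. If `B` is not positive definite a ridge
  `1e-10 · trace(B)/c · I` is added once and logged; failure beyond that
  raises with the condition number.
- Sign canonicalization: each filter's largest-magnitude coefficient is
  made positive, so filter sets are reproducible across LAPACK builds.
  Equal eigenvalues are ordered by a stable sort then lexicographically
  by coefficients — arbitrary but deterministic.
- Pearson correlation of a zero-variance channel is undefined; such
  entries are set to 0 (no similarity evidence) with a warning, and the
  `a`/`b` means still divide by the full channel count.
- α ties in cross-validation go to the smallest value (least regularized
  model at equal evidence). During the α search the SVM cost is fixed at
  `C = 1`; the final classifier re-tunes `C` on the selected α. This keeps
  the search linear in the grid size without changing its ranking in
  practice.
- Band-pass filtering is zero-phase (forward–backward) because the
  pipeline is offline and the filter's job is a zero-mean band-limited
  signal for covariance estimation. Time windows are converted to
  0-based half-open sample ranges by flooring `t·fs`.
- The pipeline order is segment-then-filter (they do not commute
  exactly); tests pin that order.

## Synthetic data

The generator emulates what the method assumes about motor-imagery EEG:
trials are `X = S A' + noise` with band-limited (8–30 Hz) Gaussian
sources. Sources are noise, not sinusoids, so variance — the statistic
CSP detects — is the only class signal. Discriminative sources carry
variance 4 in their own class and 1 elsewhere (a mirrored pair for two
classes, one per class for multi-class); shared background sources mix a
fixed per-dataset waveform (variance share `shared_corr`, default 0.5)
with fresh per-trial noise, so the common waveform survives class
averaging and drives exactly the cross-class correlation the penalty
measures. Sensor noise is spatially white and broadband at 10 dB SNR
(per-channel average signal-to-noise power). Defaults: 8 channels
(10 for four classes), 2 s trials at 250 Hz, 100 trials/class.

The mixing matrix has random *orthonormal* columns (QR of a Gaussian
matrix). This makes the ideal unmixing `pinv(A) = A'` well conditioned,
so filter-recovery checks measure the estimator rather than the
conditioning of an arbitrary head model; with ill-conditioned mixing,
sensor noise biases the top generalized eigenvector away from the
pseudo-inverse row by an amount that reflects the mixing geometry, not
the method.

What the generator does **not** emulate: realistic forward-model lead
fields (which are far from orthogonal), non-stationarity, artifacts,
1/f background spectra, or inter-subject variability. Passing tests show
the estimator recovers the generating model under its own assumptions —
they do not certify performance on competition EEG recordings.

Problem sizes in the test and acceptance runs — 200 trials/class
(two-class) and 100 trials/class (four-class), 500-sample trials, 20
recovery seeds — were chosen as the smallest sets at which the measured
quantities are stable across seeds.

## Null behavior

Permuting training labels leaves a residual class contrast (a random
permutation of balanced labels agrees with the truth on about half the
trials), and even a weakly oriented hyperplane classifies cleanly
separated test features well. The meaningful null is therefore measured
on the permuted labels themselves: permute all labels, split, fit on one
half and score the held-out permuted labels — that accuracy is chance up
to binomial noise.

## Known limitations

- The OVR decision uses signed decision values of per-class linear SVMs,
  not calibrated probabilities; argmax subsumes majority voting but the
  scores of different per-class classifiers are compared on a common
  scale only heuristically (standard OVR practice).
- A single shared `α` is selected for all OVR banks by default
  (per-bank selection is possible through the library surface by fitting
  banks separately).
- Covariance shrinkage and non-quadratic penalties are out of scope.
- GDF/EDF ingestion requires the optional `mne` dependency and trusts
  the caller's event-name-to-class mapping.
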