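# Methods

## Problem and model

The pipeline classifies single heartbeats from an annotated ECG record into
three classes: normal beats (NB), premature ventricular contractions (PVC)
and all other annotated beat types (OB).  R-peak positions are taken from
the annotations; the package deliberately does no R-peak detection, no
filtering and no resampling (records whose header does not supply a
sampling rate compatible with the requested window simply produce windows
of the corresponding length; non-WFDB inputs can enter as delimited text).

Classification is fully generative.  Each class k is modeled as a Gaussian
over the 80-dimensional feature vector with empirical prior
`p(q_k) = n_k/N`, and a beat is assigned to the class maximizing the log
posterior.  The three model variants differ only in their covariance
structure — diagonal per class (GNB), one pooled matrix (LDA), full per
class (QDA) — which makes the fitted parameters directly interpretable as
per-class feature means and (co)variances.  Scoring is entirely in the log
domain; the marginal `p(x)` and the class-constant `(d/2)·log 2π` are
dropped from the LDA/QDA discriminants because they never affect the
argmax (GNB keeps the full univariate log-density, which differs from the
dropped-constant form by the same class constant).  Ties at the argmax go
to the first class in the fixed order NB < OB < PVC.

## Segmentation and normalization

The beat window is 0.2 s before to 0.46 s after the R peak — 0.66 s,
roughly one cardiac cycle.  Sample counts are `floor(duration·fs)` with the
R sample counted once, so 72 + 1 + 165 = 238 samples at 360 Hz.  Beats
whose window would leave the record are dropped with a logged warning
rather than failing the run.

Normalization is applied **per beat** after segmentation:
`(x − mean(x)) / (max(x) − min(x))`.  The per-beat choice (over per-record)
makes each beat's descriptor invariant to slow gain and baseline drift
between beats, which is the variation the classifiers should not see.  A
constant (flat-line) beat has zero range and maps to the all-zero vector by
convention, flowing on to the outlier filter instead of raising.

## Features

Each beat is quartered at boundaries `floor(i·L/4)`; the quarters
concatenate back to the beat exactly (lengths 59/60/59/60 at L = 238).
Per quarter, 20 features:

* **FSC** — mean, sample standard deviation (n−1 divisor; the divisor is a
  free choice and n−1 keeps FSC consistent with every other covariance in
  the package), maximum, minimum;
* **SFE** — the samples at indices `round(k·(m−1)/5)`, k = 0..5, with
  round-half-away-from-zero: the two endpoints anchor the grid and four
  interior samples are equally spaced between them;
* FSC and SFE again on the quarter's **DFT magnitude spectrum**.  The
  magnitude (not the complex spectrum) is used because order statistics of
  complex values are undefined; the full-length spectrum (not the half
  spectrum) keeps SFE's "beginning and ending" well defined on a vector the
  same length as the quarter.  For real input the magnitude is symmetric,
  so the retained features carry the half-spectrum's information plus the
  DC and (implicitly repeated) band samples.

Serialized order is fixed as `[FSC_time, SFE_time, FSC_freq, SFE_freq]` per
quarter, quarters in order — the classifiers are order-invariant but the
text interchange format needs a defined layout.

## Outlier removal

Mean and covariance are estimated once from the pooled dataset (all
classes together, n−1 divisor); each row's squared Mahalanobis distance is
computed by Cholesky solve (no explicit inverse), and rows above
`χ²⁻¹(0.975; 80) ≈ 106.63` are removed in a single pass.  Pooled and
single-pass semantics are deliberate: the filter models the dataset as one
multivariate normal and performs one reduction step, so re-filtering kept
Gaussian data removes no larger a fraction than the first pass.  On truly
Gaussian data the removed fraction calibrates to ≈ 2.5%; on realistic beat
features — including the package's own synthetic beats — heavy tails push
the removed fraction well above the nominal level (≈ 9% in the shipped
end-to-end run), which is expected behaviour, not a defect.

Covariance regularization (used everywhere a covariance is inverted): if
the condition number exceeds 1e12, add `1e-8·trace(Σ)/d` to the diagonal
and log the event.  Near-collinear feature columns do occur (e.g. SFE
endpoint samples of adjacent quarters are nearly equal on smooth beats).

## Display projection

For visualization only: whiten the data to identity total covariance
(eigendecomposition of the total covariance, `X → (X−μ)V Λ^{-1/2}`), build
a Gram–Schmidt orthonormal basis from the whitened class means (with a
re-orthogonalization pass; vectors with residual norm < 1e-10 are dropped),
project samples into that ≤ K-dimensional subspace, and there solve the
symmetric generalized eigenproblem `S_b v = λ S_w v`.  Coordinates are read
off the leading eigenvectors (eigenvalues descending; the sign convention
makes each eigenvector's largest-magnitude component positive).  Working
inside the mean subspace keeps `S_w` full rank, which the 80-d ambient
space would not after the rank-≤ K projection.  The pipeline order
(whiten → mean projection → Fisher axes) is fixed; whitening first makes
the result invariant to rotations of the input features, which a test
verifies numerically.

## Model fitting details

* Priors `n_k/N`; per-class means; GNB per-feature variances floored at
  `1e-9 ×` the largest per-feature variance in training so constant
  features cannot produce infinite densities (logged when triggered).
* LDA pooled covariance `Σ = Σ_k (n_k−1)S_k / (N−K)` — the standard
  unbiased within-class pooling.
* QDA log-determinants via Cholesky factors, never explicit determinants;
  the same ridge rule as the outlier filter guards ill-conditioned
  per-class covariances.
* Model serialization is versioned JSON; Python's shortest-round-trip float
  encoding makes save/load exactly score-preserving.

Two exact degeneracies pin the three implementations together and are
tested: QDA forced to one shared covariance predicts identically to LDA
(the quadratic terms become class-constant), and QDA restricted to
diagonal covariances predicts identically to GNB.

## Evaluation protocol

Confusion matrices use rows = true class, columns = predicted — the unique
orientation under which the published confusion matrix reproduces its
published per-class metrics (e.g. Se(PVC) = 1 requires the PVC *row* to be
zero off the diagonal).  Se/PPV/F1 are one-vs-rest per class with the
zero-denominator convention `0`, making them total functions.  Reports
print at 3 decimals.

The 70/15/15 split and the 10-fold CV are both **stratified** with a
seeded RNG: per class, indices are shuffled and dealt round-robin (CV) or
cut at `floor(fraction·n_c)` with the remainder going to train (split).
Stratification is a deliberate choice so the smallest class survives
10-fold CV; the protocol itself (fold counts, fractions, mean-of-means F1
selection, refit on train+validation, single test-set evaluation) is fixed.

## Synthetic data

`generate_beats` emits beats as sums of Gaussian bumps (P, Q, R, S, T) at
360 Hz on a regular 0.8 s RR grid with timing jitter (SD 5 ms), per-beat
amplitude jitter (SD 5%) and additive white noise (SD 0.02 mV ≈ 2% of the
R amplitude) — realistic magnitudes for clean ambulatory recordings.  The
class morphologies encode the clinical contrasts the classifier should
exploit: NB has a P wave and narrow QRS (< 120 ms at half R amplitude);
PVC has no P wave, a wide QRS (half-amplitude width ≈ 141 ms > 120 ms) and
an enlarged T wave; OB is a distinct perturbed shape (no P, smaller QRS,
inverted T).  What the generator does **not** emulate: baseline wander,
powerline interference, muscle artifact, rhythm context (prematurity
itself — RR intervals are regular), beat-to-beat morphology evolution, and
the label noise of real expert annotations.  Passing end-to-end tests
therefore demonstrate that the pipeline's stages compose correctly and
that the features separate morphologically distinct beat classes; they do
not certify performance on real ambulatory ECG.

`generate_features` draws class-conditional multivariate normals — the
classifiers' own working model — for calibration-style tests (parameter
recovery, chance-level behaviour with identical means, perfect separation
at 10 SD spacing).

## Problem sizes and numerical tolerances in the tests

The shipped end-to-end runs use 800 beats (400/200/200), large enough that
every CV training part holds > 150 beats per class — comfortably above the
80 samples a full-rank per-class covariance needs — while keeping the whole
suite fast.  QDA genuinely degrades when a class's training count
approaches the feature dimension (its 80×80 covariance estimate becomes
ill-conditioned), so feature-space fixtures use 400 samples/class; this is
a property of QDA, not of the implementation.  Statistical assertions use
calibrated bounds: Monte-Carlo outlier fractions over 20 seeds within
±0.006 of 2.5%; mean recovery within 3 standard errors (or the joint
chi-square 99.9% bound where many coordinates are compared); covariance
recovery within 10% of each entry's natural scale `√(σ_ii σ_jj)`, since
relative error on a near-zero off-diagonal entry is not statistically
meaningful at any finite n.  Exact identities (scatter conservation,
discriminant-vs-density, degeneracies) are asserted at 1e-8.

## Known limitations

* The WFDB reader covers the MIT-BIH dialect (format 212 and 16, MIT
  annotation streams); other signal formats and multi-segment records are
  out of scope and rejected with a clear error.
* The label mapping `'N'`→NB, `'V'`→PVC, rest→OB is the simplest faithful
  three-class scheme; finer AAMI-style groupings are not provided.
* The outlier filter assumes one pooled Gaussian; robust estimators (MCD)
  and per-class gating are deliberately not implemented.
* No denoising is applied anywhere; the outlier filter is the only defence
  against corrupted beats.
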