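# Methods

## Model and decision rule

The classifier is a two-stage construction on binary-labelled feature
vectors x ∈ ℝᵈ.

**Projection.** With labels coded t ∈ {−1, +1} (class 1 → −1 by
convention; the coding is configurable and every downstream formula uses
the actual codes), the affine map y(x) = w0 + wᵀx is fitted by least
squares on the augmented design A = [1, X]. The minimizer of ‖AW − t‖² is,
up to scale, the Fisher discriminant direction, so y is the standard LDA
projection ("weight sum"). Rank-deficient designs take the minimum-norm
pseudo-inverse solution by default; callers who would rather fail get
`allow_rank_deficient=False`, and an optional ridge penalty (on the
weights, never the bias) is available for collinear features such as CSP
log-variances. Only the least-squares route is implemented: the
Fisher-criterion eigen-solution yields an equivalent projection for binary
problems and would duplicate it.

**Decision.** Training weight sums are summarized per class as Gaussians
(μᵢ, σᵢ, nᵢ), with the sample (n−1) SD by default (`ddof` configurable).
A sample with weight sum y is assigned to the class with the smaller
z-score zᵢ = |y − μᵢ|/σᵢ; ties go to class 1 (a measure-zero event, fixed
for determinism). The rule is applied literally rather than as a single
threshold: when σ₁ ≠ σ₂ the locus z₁ = z₂ has *two* crossings, and the far
tail on the small-σ side is assigned to the large-σ class, because distance
measured in the tight class's units grows faster. The closed-form value

b = (σ₂μ₁ + σ₁μ₂)/(σ₁ + σ₂)

is the unique crossing strictly between the means and is exposed as a
diagnostic (`zlda_boundary`); it is what moves toward the small-σ class
and reduces to the midpoint — hence to conventional LDA with balanced
classes — when σ₁ = σ₂.

Two deliberate readings are worth flagging. First, b is the z-equality
point, which is *not* the exact equal-density intersection of the two
Gaussians when σ₁ ≠ σ₂ (the density crossing carries an extra
log(σ₂/σ₁) term); the z-score definition is taken as authoritative and the
discrepancy is accepted. Second, the per-class confidence
rᵢ = φ(zᵢ)/(φ(z₁)+φ(z₂)) — the standard normal density at each z-score,
normalized to sum to one — is one reasonable formalization of
"reliability derived from the z-score"; it is a heuristic ranking value,
not a calibrated posterior probability (it ignores class priors and the
σ-dependent density normalization).

**Degenerate inputs.** A class SD of zero (constant features) raises
`"degenerate class distribution"` rather than being silently floored; an
explicit `sigma_floor` option (default off) exists for callers who want a
floor. A class with fewer than two samples cannot yield an SD and raises.

## Simulation study

`run_study` draws two bivariate Gaussian classes — means (−1, −0.6) and
(1, 0.6), per-dimension SD 0.3 — and sweeps heteroscedasticity by adding
δ ∈ {0.0, 0.1, …, 0.9} to each component of the class-2 SD (so the norm of
the SD-difference vector is δ√2). Per repetition a fresh 100-per-class
training set and an equal-sized test set are generated, both classifiers
are fitted on the training set, and percent test accuracy is recorded;
100 repetitions per level give the reported mean ± SD, and a two-sided
paired t-test (df = n−1) on the per-repetition accuracy differences tests
the LDA/Z-LDA contrast. Repetition seeds are spawned from
`SeedSequence((master_seed, level_index, repetition))`, so any single
repetition is reproducible in isolation and the whole table is
deterministic in the master seed. A level where every repetition ties
(typically δ = 0) has no defined t statistic and reports NaN.

These sizes (200 + 200 samples, 1000 total fits for the full table) run in
about two seconds; nothing is scaled down relative to the design above.

## CSP front-end

Preprocessing follows the standard motor-imagery recipe: trials whose peak
absolute amplitude exceeds 300 µV (strict exceedance) are discarded as
ocular-artifact-contaminated; the rest are band-pass filtered with a
4th-order Butterworth applied forward–backward (zero phase, so variance
features see no group delay), default band 8–30 Hz — the classical mu+beta
band. Per-subject optimal band selection is out of scope; the band is a
parameter.

CSP estimates each class's average trace-normalized per-trial covariance
C̄ᵢ (per-trial covariances are divided by their trace so high-amplitude
trials do not dominate) and solves the generalized eigenproblem
C̄₁w = λ(C̄₁+C̄₂)w. Under the normalization wᵀ(C̄₁+C̄₂)w = 1, eigenvalue
λₖ is the class-1 fraction of filtered variance, so the discriminative
filters sit at both ends of the spectrum; "most discriminative 3 pairs"
means the 3 largest plus 3 smallest λ (equivalently largest |λ − 0.5|),
giving 6 surrogate channels whose log variance is the feature vector.
Scalar shrinkage toward the identity (default 0) handles rank-deficient
covariances; a singular composite covariance raises rather than producing
meaningless filters.

## Synthetic EEG generator

`generate_synthetic_trials` emulates the *statistical* structure CSP
exploits: latent white-noise sources with class-dependent variances
(default: two sources whose variances flip 4:1 ↔ 1:4 between classes,
against a unit-variance background filling the remaining channels) are
mixed into 15 channels through a fixed random orthonormal matrix, scaled
to ~10 µV, with 1 µV white sensor noise. Because the discriminative
variance fraction is 4/(4+1), the fitted top CSP eigenvalue should be near
0.8, which is what the recovery tests check, and the pipeline is learnable
by construction. The generator does **not** emulate oscillatory band
structure, 1/f spectra, nonstationarity, volume-conduction geometry, or
real artifact morphology — passing tests demonstrate the pipeline's
correctness and internal consistency, not performance on recorded EEG.
Results on actual recordings depend on properties this generator has no
opinion about.

## Numerical choices

- Least squares via SVD (`lstsq`), minimum-norm under rank deficiency.
- Sample SDs with n−1 denominator; population (n) available via `ddof`.
- LDA threshold ties and z-rule ties both resolve to class 1.
- Confidence computed with a max-subtracted softmax over −z²/2 to avoid
  underflow at large z.
- Band edges validated strictly inside (0, Nyquist); CSP eigenvalues
  clipped to [0, 1] against rounding.
- Model JSON serializes floats at full double precision (Python repr), so
  save/load round-trips reproduce predictions bit for bit.

## Limitations

Binary classification only; no multiclass z-rule. The confidence value is
uncalibrated. The closed-form boundary b is reported for interpretation
but is not the Bayes-optimal threshold for unequal-variance Gaussians.
Heavily unbalanced classes shift the projected score means so that the
LDA label-midpoint threshold and the equal-σ z-rule no longer coincide
exactly. Native EEG container formats (GDF, BrainVision, competition
formats) are not read; trials enter as plain numeric files plus a
manifest, with epoching assumed done upstream.
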