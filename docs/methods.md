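# Methods

## The analysis problem

A Sensory Organization Test (SOT) session yields, per patient, twelve
centre-of-pressure (COP) time series: six test conditions of graded
difficulty, two axes (medio-lateral ML and antero-posterior AP), each 2000
samples at 100 Hz.  The device's own summary, the Equilibrium Score,
collapses each series to its two extreme sway angles.  The pipeline here
instead characterises each series by its Approximate Entropy (ApEn) after
removing the slow trend by Empirical Mode Decomposition (EMD), screens the
diagnosis classes for a separable pair, and evaluates standard classifiers
on the resulting 12-dimensional feature vectors.

## Approximate entropy

ApEn(m, r, N) = Φ^m(r) − Φ^{m+1}(r), with
Φ^m(r) = (N−m+1)⁻¹ Σ_{i=1}^{N−m+1} log C_i^m(r) and C_i^m(r) the fraction
of the N−m+1 length-m templates lying within tolerance r of template i.

Numerical conventions (all config-exposed, defaults in parentheses):

* distance between templates: Chebyshev, i.e. maximum coordinate
  difference — the canonical choice for ApEn;
* self-matches included, exactly as the counting definition reads, so
  every C_i is positive and the logs are finite;
* natural logarithm — values are in nats;
* embedding dimension m (2) and tolerance r (0.2), with r interpreted as a
  fraction of the series SD (population SD, ddof = 0, the convention of the
  standard entropy libraries) or as an absolute tolerance;
* a zero-variance series with relative r returns ApEn = 0 with a warning —
  the mathematically consistent constant-series limit.

ApEn is *not* guaranteed nonnegative: for short strictly periodic series
the finite-sample bias of the two averages can produce small negative
values (the alternating 0/1 series of length 8 at m = 1, r = 0.5 scores
≈ −0.0102 by direct enumeration, and the implementation reproduces that
closed form).  No clamping is applied.

The production path counts template matches with a k-d tree in the
Chebyshev metric; `apen_bruteforce` is a deliberately naive double-loop
transcription of the definition kept as the oracle, and the two paths are
asserted to agree to 1e−12 across seeded inputs.

The shuffle-surrogate test recomputes ApEn on uniform random permutations
of the same samples, resolving the tolerance once on the original series.
A series with genuine temporal dependence has lower entropy than its
shuffles; the reported exceedance (fraction of shuffles with higher ApEn)
is ≈ 0.5 for exchangeable noise and 1.0 for structured sway.

## Empirical mode decomposition

Sifting follows the classical scheme: find interior extrema (plateaus
contribute their midpoint index — a deterministic tie-break), interpolate
upper/lower cubic-spline envelopes through maxima/minima after mirroring
the two nearest extrema across each boundary, subtract the envelope mean,
and repeat until the detail stabilises.  The stop rule is the Cauchy-type
criterion on successive iterates

    Σ_t (d_prev − d_curr)² / Σ_t d_prev² < ε.

Note the normalisation: this is the *energy-ratio* form, not the pointwise
sum of squared relative changes for which 0.2–0.3 is the textbook
threshold.  On broadband signals the energy ratio collapses below 1e−2
after a single pass and then plateaus around 1e−5, so a threshold of 0.2
would stop after one pass and leave badly under-sifted, scale-mixed modes
(measured directly: with ε = 0.2 a synthetic COP trial yields 4–5 IMFs and
the slow trend leaks into the fifth).  The defaults are therefore
ε = 3e−5 with a 30-iteration cap per IMF, which in practice acts as a
deep-sifting scheme: trials decompose into 6–8 well-ordered IMFs and the
trend concentrates beyond the fifth.  Hitting the iteration cap is logged
as a warning, not an error, and the caps are counted in pipeline
summaries.  Decomposition stops when the residual has fewer than two
maxima or two minima (monotone or trend-only remainder) or after
`max_imfs` (12) extractions; the telescoping construction reconstructs the
input to floating precision by design.

Cubic-spline envelopes overshoot between knots, so the upper envelope is
not pointwise above the lower one everywhere — tests assert interpolation
exactness at the knots and ordering on the overwhelming majority of
interior samples, which is what spline envelopes can actually guarantee.

Detrending keeps the first five IMFs in extraction order (extraction order
is highest-frequency first); if a decomposition yields five or fewer IMFs
this equals input − residual, and a decomposition with no IMFs detrends to
the zero signal with a warning.

## Synthetic cohorts

Each trial is composed as

    x(t) = T(t) + A_cond · [(1 − λ)·q(t) + λ·n(t)]

with T a sum of three random sinusoids in the 0.01–0.08 Hz trend band
(slow drift that the low-frequency IMFs and residual absorb), q a
quasi-periodic sum of 2–4 sinusoids in the 0.3–1.5 Hz postural-sway band
(low entropy), and n Gaussian noise low-pass filtered at 10 Hz (high
entropy), both components normalised to unit SD.  λ ∈ [0, 1] is the
regularity dial: mean ApEn increases monotonically in λ, which is the only
physiological claim the generator makes.  Amplitude factors
(1.0, 1.2, 1.5, 2.0, 2.8, 3.5 for conditions 1–6) encode growing sway under
harder conditions; COP units are arbitrary.  The trend amplitude defaults
to 1.0 (per sinusoid, before the three tones sum), chosen so the drift is
comparable to condition-1 sway — large enough that undetrended entropy is
visibly biased, small enough that the five-IMF rule separates it cleanly.

Class sizes default to 130/185/103/57 (NormalBalance / Imbalance / TBI /
UVW Right, 475 total) and ages are truncated normals with per-class means,
SDs and ranges of the emulated clinic population (46.30 ± 14.27 [8, 84],
56.84 ± 19.48 [6, 89], 48.51 ± 15.71 [7, 81], 61.19 ± 13.17 [26, 85]
years).  Default per-class λ baselines (0.60/0.48/0.35/0.46, +0.02 per
condition step) place the impaired classes at lower entropy — less
adaptive systems are more regular — with Imbalance and UVW Right
overlapping.  The generator emits exactly one trial per (condition, axis),
twelve per patient.

What the generator does **not** model: inverted-pendulum biomechanics,
platform/visual-surround dynamics, inter-trial learning or fatigue,
hardware quantisation, or any validated link between diagnosis and sway
spectra.  Passing tests therefore demonstrate that the pipeline recovers
structure *of the kind it is designed to detect* under controlled
conditions; they say nothing about effect sizes in real clinical data.

Two helper profiles support calibration studies: `uniform_regularity`
(every class identical — the null) and `planted_separation_profile`, which
gives NormalBalance λ = 0.75, TBI λ = 0.20 on every condition while
Imbalance and UVW Right share an alternating high/low profile.  The
alternation matters: the ApEn-vs-λ response saturates above λ ≈ 0.6, so
any class placed "in between" at a fixed λ would still separate from both
extremes on all 12 features and the screening search would face ties at
mean D ≈ 1.  Alternating profiles make every pair involving the middle
classes overlap on half the features, leaving (NormalBalance, TBI) as the
unique pair significant across all conditions — a well-posed planted
truth.

## Screening

Patients strictly older than the age cut (47 years) form the older
stratum; classes with fewer than three such patients are excluded with a
warning.  For every remaining unordered class pair, each of the 12
features is compared with the two-sample Kolmogorov–Smirnov test (exact D
at the pooled points, asymptotic p).  A pair qualifies when all 12
comparisons have p < α (α = 0.05, no multiplicity correction — the
screening is exploratory by design); qualifying pairs are ranked by mean D
and the top one selected.  A config switch (`per_condition`) supports the
weaker reading where each condition need only be significant on one axis.
Shapiro–Wilk normality testing is exposed for the same exploratory step;
both elementary tests delegate to scipy.stats while stratification, pair
enumeration and ranking are own code.

## Classification

Feature vectors are the 12 ApEn values; patients missing any entry are
excluded (logged).  The train/test protocol is an own-code stratified
80/20 hold-out with a fixed seed — per class, indices are shuffled and
round(n·0.2) (clamped to [1, n−1]) go to the test set.  Model families are
scikit-learn logistic regression (L2), random forest, LDA and RBF-SVM at
library defaults with fixed seeds; no scaling or tuning is applied (the
features are already on a common scale of ≈0–2 nats).  Metrics are
computed from first principles: binary precision/recall against a declared
positive class (TBI, the clinically impaired class) with F1 their harmonic
mean; multiclass metrics are unweighted macro averages, with macro-F1 the
mean of per-class F1 rather than the harmonic mean of macro precision and
recall — the convention consistent with the published four-class rows.
Undefined precision (no predicted positives) is reported as 0 with a
warning.

## Problem sizes used in the automated checks

The acceptance computations run the pipeline at sizes chosen to make their
statistical claims decidable while keeping a full run in the minutes
range: oracle agreement on 100 series of length 50; reconstruction on 50
signals of length 500; the surrogate property on 30 trials (10 shuffles
each); screening recovery on a 48-patient planted cohort and a 20-seed
null calibration with 16-patient cohorts; classification recovery on 100
patients per class and a four-class null of 40 per class averaged over 8
split seeds.  Null cohorts are generated trend-free and their features
computed directly on the generated sway: detrending a trend-free signal is
an identity on the structure being measured, and those checks probe the
calibration of screening and classification, not the detrender.

## Known limitations

* The sifting depth (ε, iteration cap) trades runtime against mode purity;
  very aggressive settings can over-sift smooth modes into near-constant
  amplitude.  The defaults were set by inspecting trend/sway recovery on
  synthetic trials with known components.
* The EMD boundary treatment (two mirrored extrema) controls but does not
  eliminate end swings; correlation-based checks exclude the outer 5% of
  samples.
* ApEn values depend on (m, r, N) and on the SD convention; comparisons
  are only meaningful within one configuration, which is why every output
  file records the resolved parameters.
* The screening search reports a single best pair; with several genuinely
  separable pairs the mean-D ranking is a heuristic, and with small strata
  the KS p-values are themselves noisy.
* Sway-angle conversion for the Equilibrium Score (plate geometry, patient
  height) is out of scope; the EQS module consumes angle series directly.
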