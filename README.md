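# copbalance

Balance-disorder classification from Sensory Organization Test (SOT)
centre-of-pressure (COP) recordings.

Clinicians assess dizziness with the six-condition SOT on a posturography
force plate, which records the COP trajectory at 100 Hz for 20 s (2000
samples) per condition and axis but summarises each trial with a single
Equilibrium Score computed from just the two extreme sway angles.  This
package implements a pipeline that uses the *entire* trajectory instead:

1. **Detrending by Empirical Mode Decomposition (EMD).**  Each COP series
   is sifted into intrinsic mode functions (IMFs); the detrended signal is
   the sum of the first five (highest-frequency) IMFs, which discards the
   slow drift that would spuriously lower entropy estimates.
2. **Approximate Entropy (ApEn) features.**  Each detrended series is
   reduced to ApEn(m, r, N) = Φ^m(r) − Φ^{m+1}(r) with
   Φ^m(r) = (N−m+1)⁻¹ Σᵢ log Cᵢ^m(r), where Cᵢ^m(r) is the fraction of
   length-m templates within Chebyshev distance r of template i
   (m = 2, r = 0.2·SD by default).  Six conditions × two axes give a
   12-dimensional feature vector per patient.
3. **Surrogate validation.**  ApEn of each detrended series is compared
   against random permutations of its own samples; structured sway scores
   well below its shuffles, confirming the detrended series still carries
   temporal dynamics.
4. **Class-pair screening.**  Among patients older than 47 years, every
   diagnosis-class pair is compared feature-by-feature with the two-sample
   Kolmogorov–Smirnov test (D = sup |F−G|); the pair significant on all 12
   features with the largest mean D is selected.
5. **Classifier evaluation.**  Logistic regression, random forest, linear
   discriminant analysis and RBF-SVM are trained on the ApEn features under
   two approaches — binary (NormalBalance vs TBI, over-47 stratum) and
   four-class — and reported as accuracy / precision / recall / F1.

Because clinical SOT data are private, the package includes a first-class
synthetic cohort generator that emulates the study population (four
diagnosis classes of 130/185/103/57 patients with class-specific age
distributions) and exposes a regularity parameter λ per (class, condition)
that controls ApEn separability, so every downstream stage is testable
end to end.

## Worked example

```python
import numpy as np
import copbalance as cb

# one synthetic 20 s COP trial (TBI patient, SOT condition 4, ML axis)
cfg = cb.default_config(seed=1)
trial = cb.generate_trial(cb.DiagnosisLabel.TBI, 4, "ML", cfg,
                          np.random.default_rng(0))

# EMD detrending: keep the five highest-frequency IMFs
dec = cb.decompose(trial.samples)
detrended = cb.detrend(trial.samples, dec)

# approximate entropy before/after, and the shuffle-surrogate check
raw_apen = cb.apen(trial.samples).value
det_apen = cb.apen(detrended).value
report = cb.surrogate_test(detrended, cb.ApEnParams(), n_shuffles=20,
                           rng=np.random.default_rng(1))
print(f"IMFs: {dec.n_imfs}")
print(f"ApEn raw {raw_apen:.3f} -> detrended {det_apen:.3f}")
print(f"shuffled ApEn exceeds original in {report.exceedance:.0%} of shuffles")
```

prints

```
IMFs: 6
ApEn raw 0.622 -> detrended 0.624
shuffled ApEn exceeds original in 100% of shuffles
```

The trial decomposes into 6 IMFs; the trend removal leaves the sway-band
entropy essentially intact here (the trend is mild at condition 4), and
every one of the 20 shuffles has higher entropy than the original series —
the detrended signal is far from exchangeable noise, so the ApEn feature is
measuring real temporal structure.

The full pipeline (simulate → detrend → entropy → screen → train) runs in
one call or from the shell:

```bash
copbalance run --seed 1 --out results/run1 --no-raw
```

and writes per-stage artifacts (`apen.csv`, `features.csv`,
`screening.json`, `classifier_report.json`, resolved configuration) into
the output directory.

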