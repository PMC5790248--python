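# autoreg

Detection of impaired dynamic cerebral autoregulation (CA) from
spontaneous fluctuations of arterial blood pressure (BP) and cerebral
blood flow velocity (CBFV).

Dynamic CA is the mechanism that buffers cerebral blood flow against
changes in arterial pressure. Its efficiency can be graded from resting
recordings by treating BP as the input and transcranial-Doppler CBFV as
the output of a dynamic system. This package implements that chain for
researchers in cerebral hemodynamics:

- **Preprocessing** — zero-phase Butterworth filtering, beat-to-beat
  averaging over cardiac cycles, cubic resampling to a 5 Hz uniform
  grid (spectral analysis) and a 2 Hz normalized product (model
  fitting).
- **Transfer function analysis (TFA)** — Welch-averaged gain `|H(f)|`,
  phase `arg H(f)` and squared coherence of BP→CBFV, averaged over the
  very-low (0.02–0.07 Hz) and low (0.07–0.2 Hz) frequency bands, with
  the coherence acceptance threshold `1 − α^{1/(L−1)}`.
- **Nonlinear dynamic models** — ν-support-vector regression with RBF
  kernel in two structures, a finite-impulse-response form
  `v(t) = F(p(t), …, p(t−n_p))` (NFIR) and an autoregressive form
  `v(t) = F(v(t−1), …, v(t−n_v), p(t), …, p(t−n_p))` (NAR); trained
  one-step-ahead on half a recording, validated by *free-run*
  prediction of the other half (recurrences fed back from the model's
  own output), hyper-parameters chosen by grid search with segment
  swap and a physiological-plausibility filter on the model's step
  response.
- **Autoregulation indices** — the classic ARI (best-fitting
  second-order model template, continuous 0–9 grade by parameter
  interpolation) and the model-free mfARI, which summarizes a step
  response by a two-line fit (transient duration Δτ, steady-state
  level K_s, transient angle ϕ) mapped to the 0–9 scale by a
  template-calibrated regression.
- **Discrimination** — ROC curves over index values (integer
  thresholds) or continuous TF coefficients, trapezoidal AUC, and
  paired bootstrap comparison of two methods' AUCs.
- **Synthetic cohorts** — paired baseline/impaired recordings with
  known ground-truth grades, generated from band-limited BP
  variability driven through the second-order autoregulation model, so
  the whole chain is testable without clinical data.

## Worked example

```python
import numpy as np
from autoreg.synthetic import SyntheticSubjectConfig, generate_subject
from autoreg.pipeline import preprocess_recording, score_recording, transfer_function_bands

rec = generate_subject(SyntheticSubjectConfig(ari_true=6.0, seed=3))
pre = preprocess_recording(rec)

print(transfer_function_bands(pre))
scores = score_recording(pre, structure="NAR")
print(f"cc={scores.cc:.3f} plausible={scores.plausible} "
      f"mfARI={scores.mfari:.2f} ARI={scores.ari:.2f}")
```

prints

```
  band      gain     phase  coherence  accepted  threshold
0  VLF  0.444369  1.339072   0.805803      True   0.631597
1   LF  0.772858  0.450210   0.961930      True   0.631597
cc=0.936 plausible=True mfARI=5.52 ARI=5.50
```

The subject was simulated at true grade 6 with 5% observation noise.
The selected NAR model free-run-predicts the held-out half of the
recording with Pearson correlation 0.936, its step response passes the
plausibility rules, and both indices recover the generating grade to
about half a unit. Both TFA bands clear the five-window coherence
threshold (0.632), with the high VLF phase lead (1.34 rad here)
typical of working autoregulation.

A command-line surface mirrors the library:

```sh
autoreg simulate --n 10 --seed 1 --out cohort
autoreg fit-model --input cohort/subject000_baseline.csv --structure NAR
autoreg roc --baseline base_scores.csv --impaired hyper_scores.csv
```

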