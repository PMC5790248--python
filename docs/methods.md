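# Methods

## Signal model and preprocessing

Recordings are paired arterial pressure (BP, mmHg) and cerebral blood
flow velocity (CBFV, cm/s) series, nominally 5 minutes of rest. The
conditioning chain is: zero-phase (forward–backward) 8th-order
Butterworth low-pass at 20 Hz on the raw waveforms; beat-to-beat means
over cardiac cycles delimited by beat markers; cubic-spline
interpolation of the beat series onto uniform grids. Two products are
kept deliberately:

- a **5 Hz physical-unit** series (0.2 s grid) for spectral analysis —
  512-sample Welch segments then span 102.4 s exactly;
- a **2 Hz** series (0.5 s grid) for the dynamic models, normalized to
  [0, 1] per training segment. Since 5→2 Hz is not an integer ratio,
  the 2 Hz product is a direct re-interpolation of the beat series,
  not a decimation of the 5 Hz series (`decimate_to` refuses
  non-integer ratios by design).

Normalization constants are computed on the training half only and
reused on the validation half, so the validation range never leaks
into training. Beat detection from raw ECG is out of scope: markers
are an input column, or are synthesized by the cohort generator.

## Second-order autoregulation model and classic ARI

The forward model maps the normalized pressure deviation
`dP(n) = (P(n) − P_base)/(P_base − CrCP)` (critical closing pressure
CrCP = 12 mmHg, configurable) through the discrete second-order state
recursion

    x1(n) = x1(n−1) + (dP(n) − x2(n−1)) / (f T)
    x2(n) = x2(n−1) + (x1(n) − 2 D x2(n−1)) / (f T)
    V(n)  = V_base (1 + dP(n) − K x2(n))

with time constant `T` (s), damping `D`, and autoregulatory gain
`K ∈ [0, 1]`. The canonical ten-grade parameter table (grade 0:
T=2.0, D=0.0, K=0.0 … grade 9: T=0.65, D=0.50, K=0.98) is stored
verbatim as `TIECKS_TABLE`. `f T < 1` triggers a stability warning —
at 2 Hz the grade-9 recursion (f·T = 1.3) is coarse but stable;
cross-rate tests show the discretization difference is confined to
roughly the first second after a step.

The **classic ARI** of an observed response is the grade on a dense
0.1-step grid whose generated response (parameters linearly
interpolated between adjacent integer grades, driven by the observed
pressure series) minimizes the post-step mean squared error, ties
breaking toward the lower grade. Self-fits on the 0.1 grid are exact
by construction. The canonical step is 30 s of baseline, an
instantaneous −10% pressure step, and 20 s post-step; the response
grade is amplitude-invariant because the model is linear in `dP`.

## Model-free index (mfARI)

A step response normalized by its pre-step baseline is summarized by
the best pair of straight lines over the post-step samples: an
unconstrained least-squares *transient* line up to a breakpoint and a
horizontal *steady-state* line (mean of the remainder). Every
breakpoint on the sample grid between 1 s and 15 s is evaluated
(closed-form prefix/suffix least squares; the global minimizer of
e_T + e_S is exact, verified against an exhaustive `polyfit` oracle).
Descriptors: transient duration Δτ (s), steady-state level K_s
(dimensionless), and transient angle ϕ = arctan(slope) in degrees
measured against the pressure line — horizontal for the idealized
sustained step (`phi_mode = "flat_bp"`); a `fitted_bp` slope argument
exists for protocols where pressure genuinely recovers.

Grades are assigned by ordinary least squares of grade on
(1, Δτ, K_s, ϕ) over the ten canonical templates, recomputed at every
calibration (coefficients depend on rate and step geometry; in-sample
residuals stay within ±0.35 grade, and predictions are clipped to
[0, 9]). No interaction terms are used — the linear form already
reproduces the template grades monotonically with anchored endpoints.
Because K_s scales with the relative pressure drop, the pipeline
regenerates the calibration at each subject's relative step amplitude
(model step amplitude in mmHg divided by that subject's operating
pressure), keeping descriptor scales commensurate.

## Transfer function analysis

Welch auto- and cross-spectra (Hann window, 512-sample segments, 50%
overlap, per-segment linear detrend, density scaling) give
`H(f) = S_pv/S_pp`, with the conj(P)·V convention so a pure output
delay of τ seconds has phase −2πfτ. Band means over VLF
[0.02, 0.07) Hz and LF [0.07, 0.2) Hz use half-open bin inclusion and
unwrap phase within the band before averaging. A band is accepted when
its mean squared coherence reaches `1 − α^{1/(L−1)}` (α = 0.05),
counting the L overlapped segments as independent — the common
practical convention; an effective-independent count can be
substituted via the `n_windows` field. The criterion is applied
per band. Spectra are delegated to `scipy.signal` and verified against
a direct per-segment DFT loop at 1e−10 relative tolerance.

## Dynamic ν-SVR models

Both structures use ν-SVR with an RBF kernel (penalty C, support-vector
fraction bound ν, kernel scope γ). Regressors include the
current-sample pressure p(t) plus n_p lags; NAR adds n_v output
recurrences. Training is one-step-ahead (measured CBFV in the
regressors); validation is free-run (model predictions fed back),
which is the property that exposes trivial last-sample trackers. The
NFIR free-run coincides exactly with one-step-ahead prediction — there
is no feedback path — and this identity is asserted in tests.

Model selection splits the recording into halves, trains on one and
scores free-run Pearson correlation on the other, then swaps the roles
and keeps the best correlation overall. Candidates are accepted only
if their step response (input held at the training mean for 60 s, then
a sustained −0.2 step in normalized units, 20 s observed) passes four
plausibility rules: bounded in [0, 2]×baseline; initial deflection
matching the step sign; settling (SD of the final 25% of post-step
samples < 5% of baseline); no ringing above 50% of the initial
deflection after first recovery. The four-rule codification is this
package's own explicit formulation of "physiologically credible".
When no candidate passes, the best-correlation model is returned
flagged non-plausible, and its indices are reported as missing.

Two hyper-parameter grids ship with the package. The default grid
spans C ∈ {1…10⁴}, ν ∈ {0.2…0.8}, γ ∈ {0.01…5}, n_p ∈ 1…8,
n_v ∈ 1…6, bracketing the magnitudes typical of selected models on
5-minute recordings. Cohort-scale runs and the reproduction script use
a documented **reduced grid** (n_p ∈ {2, 4}, n_v ∈ {1, 2}, C = 10,
ν = 0.5, γ ∈ {0.1, 1}): the synthetic pressure–flow relation is close
to linear at resting operating points, where large C multiplies libsvm
cost by orders of magnitude without changing the selected responses,
and the second-order dynamics at 2 Hz are captured within a few lags.
Both grids are plain dictionaries and fully overridable.

## ROC analysis

The impaired condition is always the positive class, called when an
index falls *below* the threshold (ties count as non-positive — a
convention that must be fixed for reproducibility). Index ROCs use the
integers 0–9 plus endpoint thresholds, matching the coarse reporting
scale of the indices; continuous TF coefficients use all observed
score midpoints, where trapezoidal AUC equals the tie-corrected
Mann–Whitney statistic (asserted on random fixtures). The paired
bootstrap comparison resamples baseline and impaired subjects
separately with replacement, applies the same resampled indices to
both methods (method pairing preserved), recomputes both AUCs per
replicate, and reports the studentized two-sided p-value
(observed difference over bootstrap SD, standard normal reference)
with a percentile 95% CI, 5000 replicates by default.

## Synthetic cohorts

Pressure is band-limited Gaussian variability (2nd-order Butterworth
band-pass, 0.015–0.25 Hz) plus a 0.1 Hz Mayer-wave sinusoid, recentred
exactly on the configured mean (default 94.5 mmHg, within-recording SD
5 mmHg — typical spontaneous variability at rest, distinct from the
much larger between-subject spread). CBFV is the second-order forward
model at the configured grade (operating point 57.4 cm/s) plus white
observation noise (default 5% of the operating point); beat markers at
~1 s with 5% jitter, snapped to the sample grid so files round-trip
exactly. Cohorts draw grades from truncated normals: baseline
5.9 ± 1.5, impaired 2.5 ± 1.2 (clipped to [0, 9]), with an optional
+8 cm/s CBFV operating-point shift for the impaired arm.

Using the same forward model for generation and for classic-ARI
fitting is deliberate circularity: it makes grade-recovery tests exact
and isolates failures to the estimation chain. What passing these
tests does **not** show: robustness to nonstationarity, measurement
artifacts, genuine physiological nonlinearity, CO₂ dynamics, or
beat-detection errors — none of which the generator emulates. A
mismatched first-order high-pass generator (`model="highpass"`) is
provided for qualitative robustness checks only.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses a 45-subject paired cohort (the study
size of interest), a 20-subject noise-free grade span, a 45-subject
null cohort, the reduced hyper-parameter grid, and 5000 bootstrap
replicates. All randomness derives from the single `--seed` argument.

## Known limitations

- The recovered index means on noisy cohorts sit a few tenths of a
  grade below the generating means (mild attenuation from noise and
  the reduced grid); rank order — what ROC analysis consumes — is
  preserved (Spearman ρ ≈ 1 noise-free).
- Free-run NAR prediction is sequential by nature; cohort-scale grid
  searches are minutes, not seconds.
- The coherence threshold treats overlapped windows as independent,
  which is anticonservative for heavily overlapped short records.
- The two-line fit requires ≥ 10 post-step samples and a settling
  response; monotone-diverging responses are flagged non-plausible
  rather than scored.
- The published per-subject supplementary tables are not
  redistributed; the two tests that score them fail with an
  explanatory message unless the files are supplied locally.
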