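# Methods

This note documents the models, conventions and parameter choices behind
`synergait`, and what the synthetic experiments do and do not demonstrate.

## Signal model of the synthetic walking generator

`synergait.simulate` produces one "subject": four-channel surface EMG
(TA, SOL, GL, RF) and bilateral vertical GRF at 2000 Hz.

**Gait timing.** Cycle durations are truncated-normal (mean 1.09375 s,
sd 0.03 s, clipped at ±3 sd). The mean is chosen so that 5% and 20% of a
cycle are exactly 54.69 ms and 218.75 ms — the run-length minimums used in
post-processing. Ipsilateral stance occupies the first 60% of each cycle
(duty factor 0.60); the contralateral schedule is the ipsilateral one
shifted by half a cycle, so in the ipsilateral frame the opposite final
contact (OFC) falls at ~10% and the opposite initial contact (OIC) at ~50%
of the cycle.

**Muscle activations.** The truth envelope is `W·H` with four synergies
whose activations are plateau (smoothed-boxcar) waveforms locked to the
gait events, mirroring textbook lower-limb EMG timing:

| synergy | interval (cycle fraction) | weights (TA, SOL, GL, RF) | amplitude |
|---|---|---|---|
| loading response | [0.00, 0.105) | 0.45, 0.05, 0.05, 1.00 | 2.2 |
| push-off | [0.105, 0.50) | 0.05, 1.00, 0.85, 0.05 | 1.0 |
| pre-swing (limb-advancement initiation) | [0.50, 0.60) | 0.05, 0.20, 0.45, 1.00 | 1.5 |
| swing dorsiflexion | [0.60, 0.97) | 1.00, 0.05, 0.05, 0.10 | 1.0 |

Push-off, pre-swing and swing carry a doubled-amplitude onset transient
(an extra stacked plateau over the first ~2–2.5% of the cycle after their
onset), emulating the recruitment overshoot of real activations — the
swing synergy's corresponds to the biphasic TA burst at toe-off. Plateau
edges rise/fall over 1% of a cycle (~11 ms), comparable to real EMG onset
times. The loading response — quadriceps-led (RF) with TA co-activation —
is the most prominent burst of the cycle, and the pre-swing RF burst is
short and strong with plantarflexor carryover. The four weight columns
are deliberately pairwise distinct in muscle space: a per-window synergy
feature can only mark a phase boundary if the muscle ratios change there,
and an early design with two TA-led patterns (loading and swing) left
stance onset and mid-swing indistinguishable. Each synergy's amplitude is
jittered per cycle by a lognormal gain (sd 0.08), the step-to-step
variability of steady treadmill walking.

**EMG.** Each channel is the truth envelope multiplying unit-variance
noise band-limited to 20–350 Hz (the same zero-lag Butterworth used in
preprocessing), plus a white noise floor at 0.02 relative amplitude.

**GRF.** During stance the vertical force is a two-peak (M-shaped) curve,
peaks ≈ 1.1 body weight at 25%/75% of stance with a mid-stance valley
≈ 0.5 body weight, zero during swing. Load/unload ramps span 0.2% of
stance, so the 20 N contact threshold crossing marks the true event time
to within about one sample — the generator's events and the GRF detector's
events agree by construction, as a force-plate protocol assumes.

**What the generator does not emulate:** motion artifacts, powerline
interference, electrode crosstalk, fatigue drift, within-phase waveform
variability beyond the lognormal gain, kinematic variability of overground
walking, and GRF waveform idiosyncrasies. Passing tests on this generator
show the pipeline is correct and that its comparative conclusions hold
under the stated signal model — not that the same accuracies would be
obtained on human recordings.

## Processing conventions

* **Envelope:** zero-lag (forward-backward) 4th-order Butterworth
  band-pass 20–350 Hz → full-wave rectification → zero-lag 4th-order
  low-pass 5 Hz, clipped at zero. The band-pass order is a package choice
  (matching the stated low-pass order); both stages are forward-backward.
* **GRF events:** threshold crossing at 20 N with a 50 ms debounce (both
  config-exposed): a contact state must persist 50 ms to count.
* **Labels:** half-open phase intervals ([IC, OFC), [OFC, OIC),
  [OIC, next IC); stance [IC, FC), swing [FC, next IC)); a sample at time
  t gets the phase whose interval contains t; samples outside complete
  cycles are unlabeled. Windows are causal: 200 ms (400 samples) sliding
  by 5 samples, labeled by the majority phase of the trailing 5-sample
  observation window; majority ties go to the class whose last occurrence
  is latest (the most recent state). Windows whose observation window
  touches unlabeled samples are dropped.
* **Feature banks:** TD (MAV, ZC, SSC, WL, Yule-Walker AR(4), RMS per
  channel; ZC/SSC dead-zone ε defaults to 0), WC (sym7 level-5 DWT,
  symmetric boundary extension — the boundary mode is part of the
  metadata since it sets the coefficient count), WF (energy, variance,
  sd, waveform length, entropy of normalized squared coefficients per
  subband), RE (raw samples, sample-major across muscles), MS (below).
  TD/WC/WF/RE are computed on the band-passed EMG; MS on the envelope.
* **MS features:** per window, min-max normalization jointly over the
  window (preserving between-muscle amplitude ratios; a per-channel flag
  exists), then NNMF by multiplicative updates (δ = 1e-12 stabilizer,
  tol 1e-6 relative residual change, max 500 iterations), best of
  `n_restarts` uniform-(0,1] initializations, weights max-normalized and
  flattened column-major. Restart draws for window i come from a
  generator seeded by (master seed, i), so features are independent of
  batch composition. For k > 1 the columns are ordered by dominant-muscle
  index (ties by activation energy) to resolve NMF's permutation
  ambiguity.
* **Classification:** time-blocked k-fold CV (contiguous test segments —
  shuffled CV would leak overlapping windows), the trailing 10% of each
  training portion as validation; features standardized on the training
  split; seeded random search (SVM: C log-uniform [1, 100], gamma
  log-uniform [0.03, 3]; KNN k 1–25; DT depth 2–30; NN one hidden layer
  16–256 units, lr log-uniform [1e-4, 1e-2]); the NN trains epoch-wise
  with early stopping after 10 non-improving epochs on validation
  accuracy. SMOTE (k=5 neighbors) balances minority phases in the
  training block only — applying it before the split would leak synthetic
  copies of test-adjacent windows.
* **Event identification:** predicted 400 Hz label runs shorter than
  54.69 ms (WA) / 218.75 ms (all other phases) are removed, merging into
  the preceding retained run (the first run merges forward), iterated to
  a fixed point; transitions are typed WA→SS = OFC, SS→LA = OIC,
  LA→WA = IC, ST→SW = FC, SW→ST = IC, timed at the first sample of the
  new phase. Matching is greedy nearest-first one-to-one within half a
  mean cycle; |Δt| ≤ tolerance is a TP, a matched pair beyond tolerance
  counts as FP and FN, unmatched predictions/truths as FP/FN. MAE is
  averaged over all matched pairs regardless of the TP tolerance, and
  reports are emitted at both ±2.5 ms (one window interval) and a relaxed
  ±50 ms — the strict tolerance is far below the timing error any
  windowed method can achieve, so the two are reported side by side.

## Problem sizes

The cohort study (`synergait.study.phase_classification_study`) defaults
to desk scale: 8 simulated subjects × 12 s, 10-fold CV, random-search
budget 3, 5 NNMF restarts per window. These sizes keep a full MS/TD ×
2-scheme × 8-subject comparison around ten minutes on one CPU; all of
them are parameters, and the full-length conditions (60 s per subject,
budget 20, 20 restarts) run unchanged through the same code. At k = 1 the
NNMF restart count is immaterial in practice: the rank-1 problem's global
optimum is the leading singular pair (Perron–Frobenius), and the
multiplicative updates reach it from essentially any initialization (the
test suite verifies best-of-20 equals the SVD bound to 1e-6).

## Numerical and degenerate-input choices

Constant channels min-max normalize to zero and get zero AR coefficients
(with a warning); all-zero windows give zero MS features (warning);
all-zero subbands have zero entropy and variance; all-zero synergy
columns are left unnormalized (warning). Event containers require
strictly increasing times per type. The stride downsampler (2000 →
400 Hz) deliberately skips anti-alias filtering: it aligns label grids,
not spectra.

## Known limitations

* The causal-window design bounds how fast any amplitude-ratio feature
  can react to a phase change: new-phase evidence accumulates linearly
  over the 200 ms window, so predicted transitions lag truth by however
  long the classifier needs to see decisive evidence (tens of ms for the
  softer boundaries). Event timing at the toe-off and opposite-contact
  boundaries is correspondingly noisier than at initial contact.
* With four muscles and one extracted synergy, some phase pairs are
  separated only by modest ratio differences; per-cycle amplitude jitter
  erodes those margins, and individual CV folds (≈1 cycle of test data at
  desk scale) can fail on a soft boundary, inflating pooled event MAE.
* The WC coefficient count depends on the boundary-extension convention;
  with symmetric extension a 400-sample window gives 463 coefficients per
  channel (1852 total), fixed by the declared mode and pinned in tests.
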