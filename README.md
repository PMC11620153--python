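# emgtap

Quantifying bradykinesia from forearm surface EMG during MDS-UPDRS III
tapping tests.

In Parkinson's disease, the motor examination scores bradykinesia by eye:
a neurologist watches "finger tapping" and "hand movements" tests and
assigns item scores 0–4. This package implements a signal-processing and
statistics pipeline that extracts objective correlates of those scores from
surface EMG (sEMG) recorded over the forearm flexor and extensor muscle
groups while patients perform the tests — before ("OFF") and after ("ON")
levodopa intake — and compares them with healthy controls.

The pipeline:

1. **Conditioning** — DC-offset removal, zero-phase 8th-order Butterworth
   band-pass (10–100 Hz), trimming of the first and last 2 s, full-wave
   rectification, and a linear envelope (zero-phase 2nd-order low-pass,
   6 Hz) of each channel of a 23-s recording sampled at 1260 Hz.
2. **Activation-peak metrics** — every voluntary movement produces one
   activation burst, hence one envelope peak. Peaks are local maxima whose
   *prominence* (height above the higher of the two base minima, i.e. the
   lowest contour line isolating the peak) reaches a per-signal threshold,
   `rel × (max − min)` of the envelope (default `rel = 0.1`). Three
   whole-recording features follow: the number of peaks *N*, the median
   peak amplitude (mV), and the mean inter-peak interval (s).
3. **Feature banks** — the band-passed signal is segmented into 1-s Hann
   windows with 0.5-s overlap; per window the Hudgins set {MAV, ZC, WL,
   SSC} and Du set {IAV, VAR, WL, ZC, SSC, WAMP} are computed
   ("standard"), plus MAV1, MAV2, approximate entropy and sample entropy
   (m = 2, r = 0.2 σ, Chebyshev) for the "extended" bank; window values are
   averaged per channel and the whole-recording peak count and mean
   interval are appended.
4. **Score regression** — a 100-tree random forest predicts the total
   MDS-UPDRS III score from the feature vector under leave-one-subject-out
   cross-validation (each fold holds out one patient's OFF *and* ON rows;
   standardization is fitted on training rows only). The pooled
   out-of-fold predictions are correlated (Pearson) with the clinician
   scores, separately per task and feature bank.
5. **Group statistics** — per muscle group: a 2×2 mixed-design ANOVA
   (between factor PD/healthy, within factor OFF/ON, healthy single
   measurements imputed into both conditions; df1 = 1, df2 = N − 2),
   paired and Welch t post-hoc contrasts, and Spearman correlations
   (exact permutation p for n ≤ 8) between peak features and clinical
   scores — all at the Bonferroni-adjusted alpha 0.05 / 4 = 0.0125 over
   the four muscle-group channels.
6. **Synthetic cohorts** — a forward generator produces EMG-like
   recordings (Gamma-renewal tap trains modulating 20–450 Hz band-limited
   noise) with known tap times and MDS-UPDRS-like scores antitone in the
   tap rate, so every stage can be validated against ground truth.

## Worked example

The numbered scripts under `analysis/` run the study end-to-end on a
synthetic cohort of 6 PD patients (OFF and ON) and 7 healthy controls:

```
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_and_peaks.py
python analysis/03_group_statistics.py
python analysis/04_score_prediction.py
python analysis/05_calibration_sweeps.py
```

`02` reports the detected activation peaks per 19-s analysed recording and
their agreement with the simulated tap times:

```
                                  mean  std
task           group   condition
finger_tapping healthy na         75.9  5.7
               pd      off        28.8  3.0
                       on         55.4  5.1

median |detected - true| tap-count error: 0.0% (interval: 1.0%)
```

OFF-state patients tap at about 1.5 Hz, ON at about 3 Hz, controls near
4 Hz; the peak count recovers the true tap count essentially exactly. `03`
then finds the levodopa-by-group interaction for the peak count in every
muscle group (e.g. `F(1,11) = 150.8, p = 9.2e-08`, all significant at
0.0125), all 24 post-hoc contrasts significant at the default effect
sizes, and strongly negative Spearman correlations between the OFF−ON
change in peak count and the change in total score (rho −0.87 to −1.00):
patients whose tapping speeds up most under levodopa improve most in their
clinical score. `04` compares the two feature banks:

```
pooled LOSO Pearson correlation with the total score:
   finger_tapping: standard +0.688  extended +0.931  (delta +0.243)
   hand_movements: standard +0.719  extended +0.933  (delta +0.214)
```

Adding the entropy and activation-peak features to the standard
time-domain bank raises the pooled correlation — the qualitative direction
reported for the extended model on real patients.

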