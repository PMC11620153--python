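# Methods

This note documents the models, parameter choices and numerical conventions
behind `emgtap`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Signal model and conditioning chain

A recording is a channel × time matrix in millivolts at a nominal
1260 Hz, 23 s per test. The conditioning chain is, in order: subtract the
mean (baseline DC offset); Butterworth band-pass 10–100 Hz of design order
8; cut the first and last 2 s (movement initiation/termination artifacts);
full-wave rectify; low-pass into a linear envelope.

Choices the source procedure leaves open, and how they are fixed here:

* **Phase handling.** The band-pass is applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase, because burst-peak *timing* feeds the
  inter-peak-interval feature and a causal 8th-order filter would delay
  peaks by tens of milliseconds. Zero-phase filtering doubles the
  effective magnitude order; `FilterSpec(zero_phase=False)` restores a
  single causal pass.
* **Envelope method.** A zero-phase 2nd-order Butterworth low-pass at
  6 Hz on the rectified signal — the common "linear envelope" convention.
  6 Hz preserves tap-repetition dynamics (≤ ~5 Hz) while removing the
  carrier; filter ringing below zero is clipped to 0 so the envelope stays
  a valid amplitude trace. Cutoff and order are parameters.
* **Trimming** removes `round(trim_s · fs)` samples per edge with
  half-open indexing, after filtering and before rectification, so a 23-s
  recording yields a 19-s (23 940-sample) analysed segment.

## Activation peaks and prominence

Local maxima are plateau-aware: a maximal run of equal values counts once,
at its midpoint (left-of-centre for even widths), when the samples
adjacent to the run are strictly lower on both sides; signal endpoints are
never peaks. The prominence of a peak is its height minus the higher of
its two bases, each base being the minimum between the peak and the
nearest strictly higher sample (or the signal edge) on that side — the
standard topographic definition.

The per-signal selection threshold is `rel_threshold × (max − min)` of the
envelope with default `rel_threshold = 0.1`. The source description of the
threshold ("the minimum prominence distance served as a threshold") is
ambiguous about the candidate set; the dynamic-range rule was chosen
because it has the properties that description implies — per-signal,
unit-free (selection is invariant to adding a constant and equivariant
under positive rescaling) — and it is flagged as an interpretation. A flat
envelope yields zero peaks and a logged warning rather than an error.

Peak selection and prominence are implemented in-package (they are the
core of the method) and are tested for exact agreement against a
brute-force contour-scan oracle and against `scipy.signal` on thousands of
random envelopes.

## Windowed feature banks

Windows are 1 s with 0.5 s step; a Hann taper is applied multiplicatively
before feature computation (the literal reading of segmenting "using the
Hanning window"; `taper="rect"` preserves the overlap-only reading).
Feature formulas are the standard literature definitions:

* MAV = Σ|xᵢ|/N, IAV = Σ|xᵢ|, WL = Σ|xᵢ₊₁ − xᵢ|, VAR = Σxᵢ²/(N−1);
* ZC counts sign changes with |xᵢ₊₁ − xᵢ| ≥ ε; SSC counts slope-sign
  changes with the larger adjacent difference ≥ ε; WAMP counts nonzero
  jumps |xᵢ₊₁ − xᵢ| ≥ ε. Thresholds default to 0.05 × the window standard
  deviation, making the counts invariant to amplitude rescaling; absolute
  thresholds are available. Requiring a *nonzero* jump for WAMP keeps the
  count at 0 on constant windows when the relative threshold degenerates
  to 0.
* MAV1 weights the central half of the window (i in [0.25N, 0.75N],
  1-based) with 1 and the tails with 0.5; MAV2 tapers linearly from the
  central band to the window ends (4i/N rising, 4(N−i)/N falling).
* ApEn(m, r) = φᵐ − φᵐ⁺¹ with self-matches included; SampEn(m, r) =
  −ln(A/B) over unordered template pairs with self-matches excluded.
  Defaults m = 2, r = 0.2 × window SD, Chebyshev distance — the field
  standards, since none are stated in the source. SampEn is undefined
  (NaN) when A or B is zero; undefined windows are excluded from the
  channel mean, and a channel whose every window is undefined falls back
  to 0 with a logged flag. The pairwise template counting is
  numba-compiled; tests pin it to a pure-Python O(N²) enumeration oracle.

Per channel, window features are averaged; the extended bank appends the
whole-recording peak count and mean inter-peak interval. Standardization
is z-scoring with statistics fitted on a designated row subset (inside
cross-validation: the training rows only — the leakage-free choice, as the
source is silent on where its standardization was fitted). Zero-SD columns
map to 0 with a warning, never NaN.

## Score regression

One row per (subject, condition, task); target = total MDS-UPDRS III score
(the upper-limb subtotal and single items are selectable, as the source
does not state which target its models used). Leave-one-subject-out
cross-validation: one fold per subject, test set = that subject's OFF and
ON rows. Per fold, standardization and a
`RandomForestRegressor(n_estimators=100, random_state=seed)` (defaults
otherwise; the source gives no hyperparameters) are fitted on the training
rows. The headline metric is the Pearson correlation between pooled
out-of-fold predictions and the true scores ("correlated with expert
estimates" is read as Pearson; Spearman is an option). Models are fitted
per task, mirroring the separately reported per-task correlations.

The published correlations on the six real patients (0.16 and −0.16 for
the standard bank, 0.17 and 0.63 for the extended) are not reproducible
without those recordings; what the package tests is the *direction* —
extended above standard — on cohorts where the score is genuinely antitone
in tapping speed.

## Group statistics

The 2×2 mixed ANOVA uses the classical univariate partition with subjects
nested in group: the between-subject error (subjects within groups,
df = N − 2) tests group; the condition-by-subject error (df = N − 2) tests
condition and interaction. With 6 + 7 subjects every source has df1 = 1,
df2 = 11. Group sums of squares use cell-size-weighted means, the
convention of standard repeated-measures software; the implementation
agrees with `pingouin.mixed_anova` to 1e-8 on unbalanced designs and with
a naive sums-of-squares oracle on random tables. Healthy subjects,
measured once, have their value imputed into both condition cells before
the ANOVA. Exactly degenerate designs (zero error SS with zero effect SS)
report F = 0 rather than 0/0.

Post-hoc contrasts: paired t (OFF vs ON within PD) and independent t
(each PD condition vs healthy), Welch by default since group sizes are
unequal and the original tool's variance assumption is unknown
(`variant="student"` is available). All tests are two-sided at the
Bonferroni-adjusted alpha `0.05 / 4 = 0.0125`, the four muscle-group
channels being the correction family — the only arithmetic consistent with
the printed threshold.

Spearman correlations use average ranks; for n ≤ 8 the two-sided p-value
is computed by exact enumeration of all permutations (at the study's n = 6
the t-approximation is unreliable), otherwise by the usual t
approximation.

## Synthetic cohort generator

The generator emulates the study conditions: 6 PD subjects recorded OFF
and ON and 7 healthy controls recorded once, two tasks, four forearm
channels, 23 s at 1260 Hz. Per recording:

* **Tap process.** A Gamma renewal train (mean interval 1/rate,
  coefficient of variation 0.1) models quasi-periodic voluntary tapping;
  CV 0 degenerates to exact periodicity. Group-condition mean rates:
  PD-OFF 1.5 Hz, PD-ON 3.0 Hz, healthy 4.0 Hz, with between-subject SD
  0.3 Hz drawn independently per condition — so patients differ in how
  much levodopa speeds their tapping, which is the variance the OFF−ON
  difference analyses measure.
* **EMG synthesis.** Each tap contributes a 120-ms Hann amplitude pulse;
  the summed pulse train modulates unit-variance noise band-limited to the
  sensor bandwidth 20–450 Hz, on top of 0.02 mV baseline noise. Burst
  amplitude is 0.5 mV scaled by a per-subject-channel lognormal factor
  (σ = 0.4): inter-subject sEMG amplitude variability (electrode
  placement, tissue) is a defining feature of real recordings, and without
  it amplitude features would be unrealistically informative across
  subjects. Optional extras: a sequence-effect amplitude decrement (the
  k-th of K bursts scaled by 1 − δ·k/(K−1)) and a 4–6 Hz tremor-band
  component; both default to 0.
* **Scores.** Each of the nine upper-limb motor items is
  `clip(round(4.5 − rate + N(0, 0.3)), 0, 4)` (round half up), an
  antitone map of the condition's true rate; totals are item sums. Any
  antitone link suffices for the correlation and regression direction
  tests; the affine-clip form keeps hand oracles trivial.

What the generator does **not** model: motor-unit physiology, electrode
lift or motion artifacts, inter-channel crosstalk or asymmetry between
sides, non-stationary medication kinetics, and tremor-dominant phenotypes.
Passing tests therefore demonstrate that the pipeline recovers known
structure from burst-modulated band-limited noise at realistic SNR — not
that it would achieve the same numbers on clinical recordings.

## Evaluation problem sizes

The calibration sweeps regenerate full-length recordings (23 s, 1260 Hz)
but reduce channel/task multiplicity, which carries no additional
information for the quantity under test: the ANOVA sweeps (200 cohorts at
default effect sizes, 200 in the matched ON≈healthy regime) use one
channel and one task; the null calibration (1000 replicates) simulates the
ANOVA's inputs directly; the model-comparison sweep (50 seeds) uses two
channels and one task. With these sizes a complete evaluation runs in a
few minutes on one core.

The matched-rate regime (healthy mean set to the PD-ON 3.0 Hz) exists
because the non-detection of the ON-vs-healthy contrast is a statement
about ON tapping *reaching* healthy speed; at the generator's default
4.0 Hz healthy rate that contrast is a ~3 SD effect and is detected
essentially always.

## Known limitations

* The prominence-threshold rule is one interpretation of an ambiguous
  description; the relative threshold is configurable but results depend
  on it at low SNR.
* Entropy features on 1-s windows at 1260 Hz are computed exactly
  (O(N²)); very long windows would need a different algorithm.
* The exact-permutation Spearman p is factorial in n and is capped at
  n ≤ 8 by design.
* The ANOVA is the classical univariate partition; with only two within
  levels sphericity is not an issue, but designs beyond 2×2 are out of
  scope.
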