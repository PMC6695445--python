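# Methods

This note documents the models, estimators and numerical choices behind
`leapmea`, and what the synthetic-data validation does and does not show
about real recordings.

## Signal model

An electrode trace is a voltage series in µV at a common sampling rate
(default 12.5 kHz, the rate of the multiwell acquisition platform this
pipeline targets; all synthesis and analysis are rate-parameterized).
Three electrode behaviours are modelled:

* **AP-scale (LEAP)** — the trace is the cardiac AP waveform scaled to an
  electrode-specific coupling amplitude (hundreds of µV to ~10 mV).
* **FP-scale** — the classic extracellular complex: sharp biphasic
  depolarization spike plus a small repolarization wave (T-wave analogue),
  typically well under 350 µV.
* **Electroporation-style** — an AP-scale signal whose amplitude decays
  exponentially (τ of tens of seconds) back toward an FP-scale residual,
  modelling transient pore-mediated coupling.

### AP template

The synthetic AP is phenomenological (no ionic model): a linear upstroke of
`rise_time_ms` from 0 to exactly 1, then one of three repolarization laws,
then zero for a diastolic interval.

| family | law (τ from repolarization onset) | APD_x from onset |
|---|---|---|
| `hill` | V(τ) = 1 / (1 + (τ/θ)^h) | θ·(x/(100−x))^(1/h) |
| `linear` | V falls linearly over `repol_ms` | (x/100)·repol_ms |
| `square` | flat plateau, one-sample drop | plateau_ms |

The closed forms make every downstream APD estimate testable to sub-sample
accuracy. The Hill tail is followed analytically to 96 % repolarization and
then closed out to exactly zero with a half-cosine ramp lasting 20 % of the
Hill support; APDs up to 90 % are unaffected. The triangulation ratio of a
Hill template is exactly 9^(−1/h); the linear family gives 5/9 ≈ 0.556 (the
"perfect triangle" anchor, 0.55 at the two-decimal precision it is usually
quoted at) and the square family exactly 1.

### Field potential as a derivative of the AP

The FP derives from the underlying AP. The depolarization spike is the
band-passed negative time-derivative of the AP train, which concentrates at
the upstroke. For the repolarization wave, the raw derivative is the wrong
shape: its extremum during a Hill decay sits at repolarized fraction
(h−1)/(2h), i.e. *before* 50 % repolarization for every finite h, whereas
measured FPDs fall between APD50 and APD90. Real T-waves reflect
repolarization *dispersion* across the syncytium, which grows as cells
begin to repolarize and collapses as the tissue reaches rest. We therefore
weight the derivative by r⁴(1−r), where r(t) is the repolarized fraction.
The weighted extremum has the closed form

    r* = (5h − 1) / (7h)   (hill family),

which lies in [4/7, 5/7) for h ≥ 1 — always strictly between APD50 and
APD90 — and at r* = 0.8 for the linear family. The (1−r) factor also
suppresses the template close-out ramp, which would otherwise leak into the
T-wave band. The T-wave is scaled to 20 % of the spike amplitude before the
whole FP is band-limited to the FP acquisition band and rescaled so the
spike peak-to-trough equals the electrode's coupling amplitude. The truth
table records the closed-form T-peak time; zero-phase band-limiting shifts
the measured extremum by a few percent, which the validation tolerances
accommodate.

### Beat schedules, restitution, EADs, noise

Spontaneous inter-beat intervals are truncated-normal with a 100 ms floor
(refractoriness); the floor biases the realized CoV slightly below the
nominal setting at very irregular rates (a ~39 % setting realizes ~37 %).
Paced mode uses an explicit stimulus train with capture assumed above the
floor. Rate dependence of APD uses a monotone restitution map
APD_ss(BP) = APD_max − k·exp(−BP/τ_r) approached geometrically over
`adaptation_beats` (default 25, matching the tens of beats over which
repolarization adapts after a rate change); the repolarization time base is
scaled per beat, the upstroke is not.

EADs are raised-cosine bumps added to the repolarization limb at a chosen
repolarized fraction. Because a bump on a decaying trend realizes less
topographic prominence than its height, the injector compensates the local
trend drop by fixed-point iteration and records the *realized* prominence,
measured with a hand-rolled left/right-walk prominence routine that is
independent of the scipy-based detector — keeping generation and detection
on separate code paths.

Noise is white Gaussian plus a sinusoidal baseline wander; both default to
zero and are config-exposed. The noise floor and drift spectrum of real
plates are not characterized here — synthetic noise levels are chosen per
experiment (0.5–2 % of signal amplitude in the validation suites).

## Analysis pipeline

**Band limiting.** Zero-phase (forward–backward) second-order Butterworth
high- and low-pass in cascade. When a trace is shorter than one period of
the low band edge (the 0.01 Hz AP-band edge has a ~16 s time constant), the
high-pass has nothing to remove and would only inject edge transients that
bow the baseline, so it is skipped; all morphology metrics are
offset-invariant.

**Beat detection.** The upstroke slope is a Savitzky–Golay first derivative
(~2 ms window; raw differencing at 12.5 kHz is noise-dominated). An
adaptive two-pass threshold takes 30 % of the 95th-percentile upstroke
slope, never below six robust (MAD-based) noise SDs of the *unclipped*
slope — the floor keeps the false-positive rate on beat-free traces
negligible over millions of samples. Detected starts are refined to the
centre of the near-maximal (≥ 80 %) slope region: on a linear upstroke the
slope plateau is flat and its argmax wanders under noise, while the plateau
midpoint stays at the middle of the rise. FP beats are detected the same
way on the absolute deviation from the median. Beat windows open 20 ms
before the start (so the take-off point is visible) and partial edge beats
are discarded.

**Classification.** The SD/amplitude rule (> 100 µV and > 350 µV) is
applied to the AP-band-conditioned trace; the amplitude is the median
per-beat full-window peak-to-peak. No beats at all ⇒ quiescent.

**Averaging.** Beats are normalized trough→0/peak→1 per beat, aligned at
beat start, averaged over the first five beats, and re-normalized. Metrics
measured on corners of the waveform are *not* taken from the average:
rise time is the median of per-beat estimates, because beat-alignment
jitter smears the upstroke corner of an averaged template upward by
several ms.

**APD.** Repolarization fraction r(t) = (V_peak − V)/(V_peak − V_trough);
APD_x is the first post-peak crossing of x/100, linearly interpolated
between samples, minus the beat start. Crossing-time precision under noise
is limited by the local repolarization slope: at a shallow Hill tail
(small h) a 0.2 % normalized noise SD translates to several ms of APD90
jitter; this is physics, not estimator error, and the end-to-end tolerances
(2 % or 1 ms) are set accordingly.

**Rise time.** Take-off is the last point before the maximum-slope sample
at which the smoothed slope (0.4 ms window) falls below 10 % of the
maximum slope (interpolated); the upstroke end is the first point after the
maximum-slope sample at which the slope returns to zero (noise-robust on
flat-topped APs). Near-instantaneous (≤ 2 sample) upstrokes are returned
directly. Band limiting smears sharp upstrokes slightly; at 12.5 kHz with a
2 kHz low edge this adds up to ~1 ms to very fast (≤ 2 ms) rises.

**EAD detection.** The beat is smoothed with a 5 ms moving average (which,
unlike a local polynomial, cannot overshoot at sharp corners; white noise
could otherwise fake prominences near the 20 µV floor, while genuine bumps
tens of ms wide pass through essentially unattenuated). The depolarization
peak is re-located on the smoothed signal, and local maxima strictly
between it and the 90 % repolarization time are kept when their topographic
prominence within the limb is ≥ 20 µV and > 2.5 % of the LEAP amplitude.
The 90 % endpoint separates EADs from delayed afterdepolarizations.

**FPD.** From the spike extremum, the repolarization feature is the largest
absolute deflection from the local baseline in [spike + 100 ms, spike +
0.9·BP] (polarity-agnostic; ties break earlier; the 100 ms guard skips the
spike recovery lobe and is config-exposed — short-APD sweeps lower it).
The feature must exceed four noise SDs, with noise estimated from the
first difference so genuine slow repolarization structure cannot inflate
the estimate; otherwise FPD is reported as not detected, the behaviour
seen on strongly triangulated real FPs. Fridericia: FPDc = FPD/(BP_s)^⅓.

**Well and plate level.** AP morphology comes from the well's
largest-median-amplitude LEAP electrode (ties to the lowest index); FP
endpoints are averaged across FP-class electrodes; a well is quiescent when
no electrode beats. Stability time-courses track whether each well's
originally chosen electrode still classifies as LEAP at later checkpoints.
Dose–response summaries report per-group mean ± SD (n−1) over non-quiescent
wells with quiescent counts. Pacing analysis groups stimuli into
constant-rate blocks (> 1 % interval change starts a block), counts a
stimulus as captured when a beat start lies within ±100 ms, and averages BP
and APD90 over the final third of each block. Group comparison is a
two-sided Mann–Whitney test (exact for small tie-free samples, midranks
otherwise) via scipy.

## Validation design and problem sizes

Template-level closed-form checks run at the native 12.5 kHz. Plate-scale
and long-recording checks are synthesized at 5 kHz and 2 kHz with band
edges clamped below Nyquist — morphology lives well below 1 kHz, and the
reduced rates keep the full validation suite at desk scale (the whole
pytest run completes in well under a minute). The 24-well end-to-end plate
uses Hill h = 4 (steep late repolarization, the physiological norm),
rises of 2–3.75 ms, amplitudes 600–1300 µV, beat periods 1.0–1.46 s and
noise at 0.5 % of amplitude; recovery tolerances are 2 % or 1 ms, whichever
is larger, and per-beat EAD flags must match the injected truth exactly.
The coupled FP/AP sweep covers h ∈ [1, 6] at APD90 targets of 280–700 ms
(the range the assay addresses); the rank-correlation check mirrors a
single-plate, single-cell-type scenario: 48 wells of one morphology family
with duration varying across wells.

## Known limitations

* The generator's waveforms are phenomenological; passing tests show the
  *pipeline* recovers known morphology under realistic amplitudes and
  noise, not that the templates reproduce any particular cell line.
* Waveform-level beat detection cannot resolve inter-beat intervals below
  the 250 ms refractory default, so the CoV of extremely irregular trains
  (≈ 40 %) is recovered from the beat schedule, not the waveform, and is
  biased ~2 points low by the refractory floor even there.
* FPD measured after band limiting sits a few percent earlier than the
  closed-form T-peak; FP repolarization waves slower than the FP band's
  1 Hz high-pass edge (APD90 beyond ~1 s) are strongly attenuated and may
  be reported as not detected — consistent with the practical difficulty
  of FP-based repolarization measurement that motivates AP-shaped signals.
* Rise times of very fast upstrokes carry a ~1 ms band-limiting bias at
  12.5 kHz.
* No conduction-velocity or propagation mapping across electrodes, and no
  reading of proprietary acquisition-system formats.
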