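# Methods

## The procedure being modelled

`p3tacs` implements an individualized, phase-locked transcranial
alternating current stimulation (tACS) protocol targeting the P300
event-related potential in a visual oddball task, together with the
full analysis chain around it. One experimental session has three
blocks: a *pre* EEG block, a *during* block in which tACS (or sham) is
delivered while the task continues, and a *post* EEG block. The P300
is treated as an event-related oscillation (ERO) in the delta/theta
band: a transient burst whose frequency and peak latency differ across
individuals. The protocol estimates both from the pre block, then times
every during-block stimulus so that the expected P300 peak coincides
with a peak of the stimulation sinusoid.

### Online parameter estimation

1. Preprocess the pre block: 0.5 Hz high-pass and 20 Hz low-pass
   (zero-phase Butterworth), epochs −3 to +4 s around stimulus onset,
   baseline removal over −50 to 0 ms, rejection of target trials with a
   blink (deflection > 100 µV with median pairwise inter-channel
   correlation > 0.8 in the 0–1 s post-onset window).
2. **P300 latency (P3Lat)**: time of the maximum of the retained-target
   average ERP at Pz inside the closed 300–600 ms window (ties resolve
   to the earliest sample; boundary maxima are flagged).
3. **Stimulation frequency**: per-trial complex Morlet transform
   (constant 3 cycles per wavelet, 1.5–20 Hz in 0.5 Hz steps, 24 ms
   time resolution), power averaged over retained target trials and
   expressed in dB against the mean −3–0 s baseline power per
   frequency (the ERSP). The stimulation frequency is the frequency of
   the ERSP maximum within ±150 ms of P3Lat, searched over the whole
   frequency axis.

### Phase-locked scheduling

The stimulation waveform is sin(2πft) starting at a rising
zero-crossing (where the stimulator emits a trigger); peaks fall at
T/4 + kT, T = 1000/f ms. After each trial the presentation waits for
the next zero-crossing trigger and then an additional

    wait = (T/4 − P3Lat) mod T,

so that stimulus onset + P3Lat lands on a stimulation peak (phase
π/2). The wait is reduced modulo T — the shortest non-negative wait —
which maximizes the during-block trial count; the block runs for a
fixed 20 min. Stimulation is 1 mA peak-to-peak with 10 s linear ramps;
sham ramps in and immediately out again.

### Offline analysis and outcomes

Offline preprocessing additionally low-passes at 8 Hz, re-references to
the scalp average and removes EOG-correlated independent components
(FastICA; |r| > 0.7 with the EOG channel), *protecting* any component
whose trial-averaged time course peaks inside 300–600 ms — an automated
version of the protect-the-P300 rule that a manual ICA review applies.
The offline time–frequency grid is finer (0.25 Hz / 14 ms, up to
10 Hz). Outcomes per subject and condition: P300 amplitude (window
maximum of the Pz ERP, µV) and latency; reaction-time mean and
variability (sample SD) over responded targets with RT in the closed
200–1000 ms validity window; omission and commission counts; and the
windowed ERSP maximum (±3 Hz × ±150 ms around the delivered stimulation
frequency and latency). Omission trials stay in the ERP averages but
leave the RT analysis.

The *phase miss* quantifies online estimation error: the circular
distance in [0, π] between the stimulation phase at P3Lat under the
online estimates (π/2 by construction) and under the offline
re-estimates, both evaluated with the wait actually delivered.

### Group statistics

Change scores are relative ((later − pre)/pre × 100) for amplitude, RT
and ERSP measures and absolute differences for error counts (whose
baseline can be zero). The primary comparison (H1) is a right-tailed
Wilcoxon/Mann–Whitney rank-sum test of the stimulation group's relative
P300-amplitude change pre-to-post against sham, uncorrected. Behavioral
measures (H2) are tested left-tailed pre-to-post and pre-to-during and
two-sided during-to-post, with Benjamini–Hochberg correction within
each measure's three comparisons. Commissions leave inference when
their per-condition maximum is ≤ 4. Both the rank-sum W and
U = W − n₁(n₁+1)/2 are reported: published results from different
packages print either, and at n = 9/9 a printed "U" above 81 can only
be a rank-sum. P-values are exact (full enumeration) for combined
samples ≤ 20 without ties, otherwise tie-corrected normal
approximations. Spearman correlations between change scores get exact
two-sided p-values (full permutation null) for tie-free n ≤ 9 and the
t-approximation otherwise.

## The synthetic cohort

No patient EEG is distributed with the protocol, so every stage is
exercised on synthetic sessions whose statistical structure matches the
task design.

* **Task**: 400 trials per EEG block, P(target) = 0.25, 1000 ms
  stimuli, ISI uniform on 1000–2000 ms (expected block length
  400 × 2.5 s = 16.7 min).
* **EEG**: 32-channel 10-10 montage plus one EOG channel at 1000 Hz.
  Background is pink noise (power ∝ 1/f, flattened below 0.1 Hz),
  12 µV RMS per channel — the spectrum EEG baselines actually have, and
  a deliberate stress test for the ERSP baseline normalization.
* **P300/ERO**: each target adds A·exp(−(t−L)²/2σ²)·cos(2πf₀(t−L)) at
  Pz with a cosine great-circle falloff over the scalp. Defaults:
  A = 10 µV (upper end of the published patient means, 7.7–9.5 µV),
  L = 440 ms (the pilot-study latency), f₀ = 3 Hz (the published mean
  stimulation frequency). The envelope SD defaults to one carrier
  period clipped to 150–500 ms, so the burst always spans ~2–3 cycles
  like a constant-cycle ERO.
* **Blinks**: a fixed ~400 ms biphasic template (two opposed
  half-Gaussians), identical waveform on every channel, 300 µV at the
  frontal pole with cosine falloff (floor 0.12, ≈36 µV at Pz; 1.2× on
  EOG), inserted on 10% of trials within 0–1 s post-onset.
* **Behavior**: targets answered with probability 1 − p_omission
  (default 0.05) at truncated-normal RTs (450 ± 100 ms, truncated to
  the response window); standards draw false alarms at p = 0.002.
  An optional switch couples RT to the ERO latency.

### Why these defaults — two interacting artifacts

The envelope width and blink topography are not free styling choices;
they sit at the intersection of two effects that the analysis chain is
genuinely sensitive to, and the defaults were calibrated once so the
generator occupies the regime the protocol assumes:

1. *Spectral tilt of the ERSP.* Expressing power in dB relative to a
   1/f baseline adds a +10·log₁₀(f) tilt across the map. For a burst
   that is spectrally *narrow* relative to the constant-cycle wavelet
   (σ_f = f/3), the wavelet's L2 normalization cancels the tilt and the
   ERSP argmax is unbiased; for a spectrally wide burst it does not,
   and the argmax drifts one grid cell upward. This requires an
   envelope of at least about one carrier period. Conversely, an
   envelope much *wider* than one period makes neighboring carrier
   peaks of the ERP nearly as tall as the true peak, so latency argmax
   errors of exactly ±T appear. One period is the window in which both
   estimators behave.
2. *Blinks in the ERSP baseline.* Blinks occur 0–1 s after stimulus
   onset, which places the previous trial's blink inside the −3–0 s
   baseline of the current epoch. Trial rejection cannot remove them
   (it only drops the trial whose post-stimulus window is
   contaminated), so their delta-band energy inflates low-frequency
   baseline power and pushes the ERSP argmax upward. With a
   realistically parietal-weak blink projection the effect is
   negligible; a blink drawn uniformly across the scalp (tens of µV at
   Pz) reproducibly costs one frequency cell.

Under the defaults, the full online chain recovers f₀ within ±0.5 Hz
and L within ±24 ms jointly in ≳95% of synthetic subjects with
f₀ ∈ [2, 7] Hz and L ∈ [350, 550] ms.

### What the generator does not emulate

Forward-modelled scalp potentials (the spatial profile is a smooth
cosine, not a head model), saccades and muscle artifact, the tACS
artifact in during-block EEG (never analyzed; the during condition is
behavior-only), non-stationary noise, and single-trial latency jitter
of the P300. Passing tests therefore certify the *pipeline logic* — the
estimators, the scheduler and the statistics — not robustness to every
pathology of clinical EEG.

## Numerical choices

* Zero-phase (forward–backward) Butterworth filters (HP order 2, LP
  order 4, squared response): causal filtering would delay the P300
  peak and corrupt the stimulation timing.
* Epoch windows are closed on both ends (−3000..4000 ms at 1 kHz =
  7001 samples); internal indexing is 0-based; all latencies are
  reported in ms relative to stimulus onset.
* Frequency grids are anchored at integer multiples of the resolution
  covering the requested range (offline: 1.00–10.00 Hz in 0.25 Hz
  steps), so quarter-Hz carriers are representable.
* ERSP cells whose wavelet support (±5 SD of the Gaussian envelope)
  crosses the epoch edge are invalid (NaN) and excluded from baseline
  means and maxima. Window maxima break ties toward the earliest time,
  then the lowest frequency; out-of-range windows are clipped and
  flagged.
* The during-block scheduler quantizes onsets to the sampling grid, so
  the realized phase at P3Lat deviates from π/2 by at most
  2πf × half a sample.
* "Maximum in time of maxima in frequency" is implemented as the global
  window maximum; the two readings coincide for a global maximum.
* Internal amplitudes are µV end to end; EDF+ files are written with
  the study amplifier's scaling (±3276.8 µV at 0.1 µV/bit), bounding
  round-trip error at 0.05 µV. The BrainVision writer stores IEEE
  float32. All writers emit fixed timestamps so outputs are
  byte-reproducible under a fixed seed.
* Every stochastic stage takes an explicit seed; the study driver
  spawns independent child seeds per subject and block from one master
  seed.

## Test problem sizes

The test suite exercises reduced problem sizes chosen to keep the
signal measurable: end-to-end study tests run 2 subjects per group at
40 trials per block without ICA; the parameter-recovery study runs 100
subjects at the full 400-trial block; the type-I-error simulation runs
10⁴ replicates of the H1 comparison on outcome tables at n = 9/9; the
statistic oracles enumerate every tie-free rank configuration up to a
combined sample of 10.

## Known limitations

* The printed ERSP magnitudes of group summaries are toolbox-dependent
  (the dB convention here is one of several); no attempt is made to
  match any particular absolute scale.
* The during-block trial count ignores presentation-software overhead
  (~200 ms/trial in real sessions), so simulated counts run slightly
  above published ones; the count's *dependence* on stimulation
  frequency is reproduced.
* Manual ICA component review is replaced by the EOG-correlation
  heuristic with the P300-protection rule; components with artifacts
  uncorrelated to EOG (cardiac, muscle) are out of scope.
* Exact Spearman p-values are computed only to n = 9 (9! permutations);
  beyond that the t-approximation is used, which is also what standard
  software reports.
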