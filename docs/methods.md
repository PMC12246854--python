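# Methods

`stresskit` implements a multimodal analysis of acute stress induction and
recovery: electrodermal activity (EDA) from wrist wearables, prefrontal
haemodynamics from functional near-infrared spectroscopy (fNIRS), and
salivary cortisol, recorded over a staged session (baseline, anticipation,
stress task, intermediate rest, sound intervention, two rests) in three
groups (soothing voice n = 12, robotic voice n = 11, silence n = 12).  This
note documents the models, the numerical choices, what the synthetic cohort
generator does and does not emulate, and the known limitations.

## EDA: artifact repair and tonic level

Wrist EDA (4 Hz, microsiemens) occasionally contains detachment artifacts:
second-scale windows where the electrodes lose skin contact and the signal
collapses toward 0 uS.  Detection walks the trace keeping the last valid
sample as an anchor; a sample is flagged when

1. its absolute difference to the anchor exceeds the jump threshold
   (default 0.01 uS), **and**
2. it lies outside the *acceptable range*.

The acceptable range is the union of a local band (centered 30-s rolling
median +/- 3 x rolling IQR) and a global envelope
`[q05 - 1*IQR, q98 + 3*IQR]` over the whole recording.  The two-band union is
deliberate: genuine skin-conductance responses (SCRs) can exceed a
quiet-period local band — whose IQR is noise-dominated — but they stay
within the participant's session-wide physiological range, whereas
detachment drops leave both.  The envelope is asymmetric — a tight pad
below the low quantile (detachments depress the signal) and a generous pad
above the high quantile (large upward excursions are usually genuine SCRs).
The global envelope assumes artifacts occupy
well under 5 % of the recording (occasional, seconds-long events); a device
that was detached for minutes at a time violates this assumption and should
be excluded upstream.  Both multipliers, the window and the quantile are
configurable (`eda.band_k`, `eda.global_k`).

Flagged segments are discarded and filled by linear interpolation between
the nearest valid neighbours (head/tail segments extend the nearest valid
value); a `relevel` mode that instead shifts a segment onto the last valid
level is available behind `eda.repair_mode`, since the field sometimes
treats level-shift artifacts that way.  Repair is idempotent and never
touches unflagged samples.

The repaired trace is low-pass filtered (4th-order Butterworth, 0.5 Hz
cutoff, zero-phase forward-backward), then min-max normalized to [0, 1]
per participant over the whole session.  Per-stage normalization was
rejected: it would erase exactly the between-stage level differences the
analysis measures.  A constant trace maps to all-zeros.  Stage summaries
are means of fully overlapping 120-s rolling-window means (step one
sample), so the stage mean is a triangular-weighted average of the stage
samples; the window must not exceed the shortest stage.  When two
wristbands are worn, stage summaries of devices with at least 70 % valid
samples are averaged; if neither passes, the better device is used alone.

## fNIRS: Beer-Lambert, channel quality, filtering

Optical-density changes at two wavelengths (defaults 760/850 nm — the
device's wavelengths are configurable, these are conventional values for
the class) are converted per channel by inverting the modified
Beer-Lambert law

    dOD(lambda) = [eps_OHb(lambda) dC_OHb + eps_HHb(lambda) dC_HHb]
                  * d * DPF(lambda),

with source-detector distance `d` (3 cm default), tabulated molar
extinction coefficients (standard compiled haemoglobin values:
760 nm: 586 / 1548.52, 850 nm: 1058 / 691.32 L mol^-1 cm^-1 for
OHb / HHb), and the general age- and wavelength-dependent differential
pathlength factor

    DPF(A, lambda) = 223.3 + 0.05624 A^0.8493 - 5.723e-7 lambda^3
                     + 0.001245 lambda^2 - 0.9025 lambda,

which is strictly positive over the validated grid and increasing in age.
Concentrations are in micromol/L.  No partial-pathlength or scattering
correction beyond the DPF is applied.  The synthetic generator uses the
identical forward map, which is what makes the round-trip identity test
(relative error ~1e-16, tolerance 1e-6) meaningful.

Channel quality is the scalp coupling index (SCI): both wavelength traces
are band-passed to the cardiac band (0.7-1.5 Hz, 4th-order zero-phase
Butterworth), scaled to unit variance, and the zero-lag cross-correlation
is taken.  SCI is symmetric in the wavelengths and invariant to positive
rescaling; a zero-variance filtered trace scores 0 by convention.  The
whole-recording zero-lag definition is used; a windowed variant seen in
parts of the literature is not claimed.  Channels below 0.75 are excluded
(keep at exactly 0.75).

Retained concentration traces are filtered with the hemodynamic band-pass
(0.02-0.18 Hz, 4th order, zero-phase), which removes cardiac, respiratory
and slow-drift components.

**Which signal feeds the stage means.**  A zero-phase band-pass whose low
edge is 0.02 Hz (period 50 s) removes essentially all of a sustained
activation block lasting minutes: we measured block retention of ~1 % at
600-s stages and ~8 % at 60-s stages, with the per-stage rolling mean of
the filtered block dominated by onset/offset filter transients whose sign
depends on the stage length.  Stage means of the fully band-passed signal
therefore do not measure sustained activation.  For this reason the stage
summaries default to the *low-pass-only* signal (0.18 Hz cutoff), which
removes the same high-frequency nuisance components while retaining
sustained blocks; the full band-pass remains implemented and tested and
can be routed into the summary path (`fnirs.summary_filter: bandpass`) to
reproduce the literal chain.  Slow instrumental drift is then not removed
from the summaries; the generator does not simulate fNIRS drift, and real
recordings with strong drift should use baseline-referenced contrasts.

Stage averages use the same rolling-window rule as EDA, per retained
channel and chromophore.

## Laterality Index Response

For configured (right, left) channel pairs, per participant and stage,

    LIR = (R - L) / (R + L),

on dOHb stage means; positive values mean right-dominant activity.  Stage
means can be negative, making the raw ratio unbounded, so the default
*rectified* mode first shifts each channel's stage means by that channel's
minimum across stages (activities become non-negative; the index is then
bounded in [-1, 1] and keeps antisymmetry under pair swap and invariance
under common positive scaling).  The raw verbatim ratio is available as
`lir.mode: raw`.  Whenever |R + L| falls below the degeneracy floor
(1e-9 micromol/L) the index is undefined and propagates as NaN — never as
a silent zero.  Pairs with a rejected member are skipped and logged.  The
default pair catalogue is the seven printed right/left pairs of the
montage, shipped in the packaged YAML.

## Cortisol trajectories

The five-point panel (baseline, stress, sound, rest1, rest2; nmol/L) is
anchored at -15, 0, +10, +20 and +30 minutes from stress-task end; the
sound sample's clock offset is stored per participant because it depends
on the track length.  Metrics:

- `stage_delta`: concentration difference between two stages.
- `baseline_return`: earliest post-stress stage whose concentration is
  within a tolerance fraction (default 5 %) of baseline; monotone in the
  tolerance; `None` when the trajectory never returns.
- `recovery_elevation`: per-participant mean of the sound/rest1/rest2
  concentrations minus baseline.  This is the group-level recovery
  contrast: it pools all three post-intervention samples instead of
  betting on a single time point, roughly 1.5x the power of a single-point
  contrast at these group sizes.
- `group_return_rank`: the median per-participant return rank of a group
  (no return sorts last) — a group-level "when did cortisol come back"
  summary that is robust to individual assay noise, which matters because
  the 5 % return tolerance is of the same order as a realistic assay CV.

## Statistical battery

Levene's test (median-centered) for variance homogeneity; two-sided paired
and independent t-tests with Cohen's d (paired: mean(diff)/sd(diff);
independent: pooled-sd standardized difference — a zero-variance contrast
raises rather than returning 0/0); and a mixed repeated-measures ANOVA
(between: group; within: stage) implemented from its sums-of-squares
partition

    SS_total = SS_group + SS_subjects_within_groups
             + SS_stage + SS_interaction + SS_error_within,

with F ratios against the subjects-within-groups (between effect) and
within-error (stage, interaction) mean squares.  The decomposition is
asserted additive to 1e-8 relative in the tests and cross-checked against
an independent implementation (pingouin) on an unbalanced 12/11/12 design.
Effect sizes are partial eta-squared by default (classical eta-squared
available).  Sphericity is not corrected by default — a Greenhouse-Geisser
flag applies the epsilon correction to the within-factor degrees of
freedom.  Multiple comparisons across channels are uncorrected at
alpha = 0.05 by default, with an optional Benjamini-Hochberg column.
In the two-level, one-group case the within-effect F equals the squared
paired t exactly.

`run_battery` executes a declarative plan of (measure, contrast, test)
triples; the default plan covers the cortisol 3x2 and 3x3 mixed ANOVAs, a
Levene check at the stress stage, the 3x5 EDA ANOVA, per-channel paired
t-tests (baseline vs stress) and per-channel between-group t-tests at the
sound stage for both chromophores, and the analogous per-pair LIR tests.

## Synthetic cohorts and ground truth

The generator emulates the study's statistical structure with known ground
truth; every default below is a modelling choice, not a claim about the
original data.

- **Design**: 12/11/12 participants, 40-min schedule (5-min stages except
  the 10-min stress task), ages ~N(23, 5) clipped to 18-35.
- **Cortisol**: lognormal baseline (median 10 nmol/L, sd 0.3 log units),
  additive stress rise (6 nmol/L, 0.15 log-unit spread), first-order
  exponential recovery with rate 0.16 /min for the soothing group and
  0.08 /min for both controls (the 2x contrast), and multiplicative
  lognormal measurement noise (sd 0.06 log units, an optimistic assay CV).
  With these values the soothing group's mean trajectory re-enters the 5 %
  baseline band at rest1 (+20 min) while the controls only approach it by
  rest2 (+30 min).
- **EDA**: tonic baseline ~N(2.0, 0.4) uS, smoothed per-stage arousal
  increments (stress +0.8 uS, anticipation +0.3, decaying afterwards),
  Poisson SCRs with bi-exponential shape (rise 0.7 s, decay 3 s, mean
  amplitude 0.2 uS, 6/min during stress vs 2/min at baseline), a slow
  sinusoidal drift, white noise (sd 0.01 uS), and 1 + Poisson(2)
  detachment artifacts per recording (1-4 s, dropping to 0.05 uS), kept
  at least 5 s away from stage boundaries so every stage retains valid
  anchors.  At least one detachment per recording is guaranteed so the
  per-participant repair guarantee is well defined.
- **fNIRS**: per-channel sustained dOHb blocks (stress: +1.0 micromol/L on
  right-hemisphere channels, +0.4 on left — the right-lateralized stress
  response; sound stage: +0.8 on a fixed four-channel set for the two
  control groups only, giving the soothing-vs-control contrast its channel
  specificity), dHHb = -0.3 x dOHb, a per-participant lognormal amplitude
  factor (sd 0.3 log units), Mayer waves (0.095 Hz, 0.2 micromol/L),
  respiration (0.25 Hz, 0.1 micromol/L), a shared cardiac pulse (~1.1 Hz
  with per-participant jitter, 0.01 OD units, scaled by coupling quality
  and by 0.8 at the second wavelength), and white OD noise (sd 2e-4).
  Decoupled channels carry independent noise only, so their SCI
  concentrates near zero while coupled channels score >0.99.  Optical
  densities are produced by the exact analysis forward model.
- **Ground truth**: clean EDA traces and artifact segments; true cortisol
  curve parameters; per-channel *true stage means* defined as the stage
  means of the clean concentration blocks passed through the same summary
  filter the analysis uses — the value an ideal noise-free analysis would
  produce.  A zero-noise configuration reproduces these exactly (to 1e-6).
- **Determinism**: everything derives from one `numpy` Generator seeded by
  the caller; CSV outputs are byte-identical across runs, EDF within the
  16-bit quantization of the format (~(max-min)/65536 per signal).

What the generator does **not** emulate: neurovascular coupling dynamics
(blocks are rectangular, not convolved with a haemodynamic response
function), pink-noise spectra, fNIRS drift, motion artifacts beyond full
decoupling, EDA temperature/pressure confounds, circadian cortisol
structure, or any semantic difference between the sound conditions.
Passing recovery tests therefore show the chain is correct and calibrated
under this model, not that the original study's effect sizes are
reproducible from real data — the raw recordings were never deposited, so
group-level verification is property-based by design.

## Simulation sizes and tolerances

Replicate-cohort studies use a reduced configuration (60-s stages, 10 Hz
fNIRS sampling, 30-s summary windows) chosen so that one cohort generates
and processes in about a second; effect parameters are unchanged.  The
calibration study uses 1000 null cohorts (rejection-rate band 0.03-0.07 at
alpha = 0.05); at 200 replicates the band itself would reject a perfectly
calibrated test ~18 % of the time, so the larger replicate count is the
honest choice.  Recovery studies use 1000 cohorts (cortisol) and 100
cohorts (full fNIRS lateralization chain).  Filter contracts are checked
both on measured tones (>=40 dB stopband, <=3 dB passband deviation) and
against the design frequency response (squared for the forward-backward
pass).  Beer-Lambert round trips must hold to 1e-6 relative; in practice
they hold to machine precision because inversion is an exact 2x2 solve.

## Known limitations

- The EDF writer is minimal (plain EDF, 1-s records, 16-bit): sufficient
  for optical-density exports, not a general EDF library.
- The global EDA artifact envelope assumes sparse artifacts (< 5 % of
  samples) and breaks for recordings that are mostly detached.
- The rectified LIR mode makes the index relative to each channel's
  quietest stage; absolute laterality levels are not comparable across
  studies that rectify differently (the raw mode is the fidelity
  reference).
- With the default low-pass summary path, very slow instrumental drift is
  not removed from stage means; with the band-pass path, sustained
  activation is.  This trade-off is inherent to the stage-mean design and
  is documented rather than hidden.
- The mixed ANOVA assumes complete within-subject data; participants with
  missing stages must be excluded upstream (the pipeline does this when a
  modality fails to load).
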