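# Methods

`trapsense` re-implements, on synthetic data with known ground truth, the
analysis chain of an automated mosquito-surveillance system: an optical
wingbeat sensor mounted on a suction trap records each insect transit; a
machine-learning model classifies target mosquitoes (*Aedes*/*Culex*, by
genus and sex); a Gaussian density gate separates target mosquitoes from
bycatch; and field performance is scored per collection cycle against manual
counts. The real recording dataset is unpublished, so every stage runs on a
simulator whose defaults reproduce the study conditions that *are* public
(dataset sizes, invalid-recording rate, catch totals and composition, trial
layout).

## Waveform model

A transit is modelled as a harmonic series under a raised-cosine (Hann)
transit envelope plus white Gaussian noise:

    x(t) = A(t) · Σ_{h=1..H} r^{h−1} sin(2π h f0 t + φ_h) + ε(t)

with an individual fundamental

    f0 = (f0_base + δ) · (1 + c_T (T − 28 °C)),   δ ~ N(0, f0_sd²).

The envelope models smooth entry/exit of the sensing zone; phases are
uniform; the harmonic sum is normalized to unit peak and scaled to 0.9 so
valid recordings never clip. Two invalid morphologies carry exact ground
truth for the cleaning stage:

* **double flight** — two transits whose envelopes overlap ~30% in time
  (two independent f0 draws);
* **wall hit** — the envelope truncated at one edge (transit interrupted
  mid-zone) with the waveform overdriven (×1.8) so a substantial fraction of
  samples clips at ±1.

### Default wingbeat parameters

The sensor's sampling rate, recording duration and signal units are not
public; the defaults below are configuration-level assumptions chosen once:
8 kHz sampling (covers 4 harmonics of the highest fundamental with margin),
100 ms transit, amplitude in [−1, 1].

| class        | f0_base (Hz) | f0_sd (Hz) | harmonics | decay r |
|--------------|--------------|------------|-----------|---------|
| *Culex* F    | 380          | 35         | 4         | 0.50    |
| *Aedes* F    | 480          | 40         | 4         | 0.55    |
| *Culex* M    | 580          | 45         | 4         | 0.60    |
| *Aedes* M    | 700          | 50         | 4         | 0.65    |
| non-target   | 170          | 60         | 3         | 0.85    |

Fundamentals follow the ordering reported for *Cx. pipiens* and
*Ae. albopictus* (females below males; *Culex* female lowest, *Aedes* male
highest), with spreads large enough that adjacent class distributions
overlap at roughly the 1.3–1.7 σ level — wingbeat frequency alone is a good
but imperfect discriminator, which is the known situation this line of work
exists to address. The temperature coefficient defaults to +0.8%/°C
(flight tone rises with ambient temperature); all values are free config
knobs. Non-targets (chironomids, phlebotomines, other small dipterans) are
a broad low-frequency class with flatter harmonic rolloff.

## Data cleaning

The study cleaned its laboratory dataset manually; this repository must run
unattended, so cleaning is automated with thresholded heuristics
(`features.CleaningConfig`): a recording is rejected as WALL_HIT when ≥ 2%
of samples clip or the smoothed RMS envelope at either edge reaches ≥ 50% of
its maximum; as DOUBLE_FLIGHT when the envelope shows ≥ 2 peaks at ≥ 35% of
the maximum with relative prominence ≥ 25%, separated by ≥ 20 ms; degenerate
inputs are TOO_SHORT (< 30 ms) or SILENT (peak < 0.05). Against simulator
ground truth at the default 7.5% invalid rate, sensitivity and specificity
both exceed 0.9 (in practice ≈ 1 for these morphologies).

## Features

Short-time Fourier magnitudes: Hann window of 256 samples, 50% overlap,
cropped to 0–2000 Hz (fundamentals plus first harmonics at 8 kHz). Because
transit duration varies, the classifier consumes a fixed-length summary: the
per-frequency-bin mean magnitude over frames (65 bins), concatenated with a
fundamental-frequency estimate. The f0 estimate is the peak of a 3-fold
harmonic product spectrum on the zero-padded (8192-point, ≈ 1 Hz grid) full-
recording FFT, searched in 80–1200 Hz; it is NaN for silent input. Raw
spectrograms, windowing and the flat-vector choice are assumptions — the
original pipeline's exact feature dimensions are not public.

## Classifier

Gradient-boosted decision trees (XGBoost, `multi:softprob`, hist). Protocol:
random undersampling to the minority-class count; a stratified test set
(n/4 per class) set aside first; stratified fourfold cross-validation —
folds stratified jointly by class and assay temperature, both of which
structure the laboratory data — over a small documented grid
(depth {3, 6} × learning rate {0.1, 0.3}, 150 rounds), scored by the mean
over folds of the mean per-class balanced accuracy; the best point is refit
on the full training set. Argmax ties resolve to the lowest class index for
determinism; all boosters run single-threaded with a fixed seed.

Per-class evaluation is one-vs-rest at the event level:
Se = TP/(TP+FN), Sp = TN/(TN+FP) with negatives pooled over the other three
classes, BA = (Se+Sp)/2, and the headline number is the unweighted mean of
the four per-class BAs. (Whether the original laboratory figure is macro-
recall or one-vs-rest (Se+Sp)/2 is not fully explicit; this package uses the
latter, matching the field-evaluation definition.)

## Target-detection gate

A single multivariate Gaussian fitted to laboratory target-mosquito
features: features are standardized and projected onto the leading 8
principal components (covariance stability at these sample sizes), then
scored by the exact log density −½[(x−μ)ᵀΣ⁻¹(x−μ) + log det 2πΣ] via a
Cholesky factor of the ridge-regularized covariance
(ridge = 10⁻⁶ × mean diagonal variance). A recording is TARGET iff its log
density is **at or above** the threshold (inclusive). The threshold is
chosen by scanning every observed log density plus a reject-all sentinel and
maximizing event-level balanced accuracy on a labeled calibration stream,
ties broken toward the stricter (higher) cut. The original system calibrated
against earlier unpublished field campaigns; here the calibration stream is
a synthetic labeled mix (500 target / 500 non-target events across 16–32 °C
by default).

## Count-based field evaluation

Per collection cycle, from aggregate counts only (no per-event matching):
TP = min(sensor, manual); FP = max(sensor − manual, 0);
FN = max(manual − sensor, 0); TN = manual negatives − FP (floored at zero
and flagged if FP exceeds the negatives). Se, Sp, BA = (Se+Sp)/2. For
target detection the negatives are manually counted non-target insects; for
genus × sex each class is scored one-vs-rest with the other three classes'
manual counts as negatives.

Conventions where the source material is silent or ambiguous:

* cycles with no positives contribute Sp only (and vice versa); the BA then
  equals the defined component and is flagged `partial`; cycles with
  neither are dropped from averages;
* per-trial averages weight cycles equally (not by catch size);
* quartiles use linear interpolation between order statistics ("type 7");
* the genus × sex overall BA is the per-class mean over cycles first, then
  the unweighted mean over the four classes;
* regression is reported in both orientations; the headline slope regresses
  the sensor count on the manual count, so slope < 1 reads "the sensor
  undercounts";
* excluded cycles (depredation, connectivity loss) are dropped before all
  statistics; a recording belongs to the cycle whose half-open
  [start, end) interval contains its timestamp.

A property worth knowing when interpreting these metrics: count-based
confusion cannot see paired errors. If a cycle loses k target events to
misses and gains k false alarms, the sensor total is unchanged and the cycle
scores BA = 100%. Symmetric event-level error rates therefore yield
count-based BAs *above* the event-level BA (the test suite asserts this
explicitly); only non-compensating error moves the count-based metrics, and
the exact expectations (e.g. a 5% miss rate alone → mean BA ≈ 97.5%) are
what the tests check.

## Field scenarios

The reference scenarios rebuild the reported two-trial layout: trial 1 with
32 collected 24-h cycles (July–October), 3 excluded; trial 2 with 21
collected 48-h cycles (June–September), 6 excluded — 29 + 15 = 44 analyzed.
Per-class captures are Poisson with intensities normalized so the expected
catch per trial equals the published totals (1570 and 1930 targets; 3283 and
2164 non-targets) with the published genus × sex mix, modulated by a mild
mid-summer seasonal multiplier. Timestamps follow per-genus diel profiles:
*Aedes* bimodal with peaks at 06:00 and 19:00, *Culex*
nocturnal/crepuscular, non-targets diffusely diurnal. Activity profiles are
recovered as average hourly sensor count per month (counts per hour divided
by the days of that month inside the trial).

## Problem sizes

The default laboratory build simulates the full 15,208-flight campaign with
7.5% invalid recordings and a 1000-flight test set; the acceptance script
runs it at this scale (≈ 1 min on one core). The test suite uses smaller
analogues chosen for statistical adequacy: the parameter-recovery check uses
180 flights per class × temperature cell (≥ 500 per class over all
temperatures), and unit/property tests use 40–60 per cell.

## What passing tests show — and what they do not

The simulator guarantees class structure by construction, so green tests
demonstrate that the *pipeline* is correct: cleaning recovers the designed
invalid fraction, the classifier reaches the designed separability, the gate
matches its brute-force and closed-form oracles, the count-based metrics
reproduce hand-computed and expected values, and a perfect detector yields
the exact identities (all BAs 100%, slope 1, R² 1). They do not demonstrate
field realism: real wingbeat spectra vary with load, age, humidity and
individual condition; real bycatch is heterogeneous and partly overlaps
target frequencies; real traps see bursts, wind noise and depredation. The
synthetic classes are more cleanly separable than nature, so absolute
synthetic accuracies (e.g. test BA ≈ 97–99%) sit above the published field
figures and should be read as upper bounds of pipeline behaviour under the
modelled conditions, not as replications of field accuracy. The published
per-cycle statistics can be reproduced exactly only from the per-cycle count
table distributed by the study authors on request; the loader accepts that
table's schema directly (`fieldeval.read_cycle_counts`).

## Numerical choices

One root seed; independent child streams are spawned per stage
(`numpy.random.SeedSequence`), so runs are bit-reproducible and stages are
statistically independent. Densities are computed in log space throughout.
The quantile convention, argmax tie-break, inclusive threshold comparison
and undefined-component handling are fixed as above to make outputs
deterministic across platforms. Degenerate inputs (empty waveforms, windows
longer than the signal, single-label calibration sets, constant predictors,
all-excluded cycle sets) raise `ValueError` with the offending quantity
named; the field pipeline converts evaluation-stage failures on degenerate
streams into a per-stage error report instead of crashing.
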