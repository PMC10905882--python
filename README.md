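# trapsense

Simulation and evaluation of an automated mosquito-surveillance system: an
optical wingbeat sensor at the mouth of a suction trap records each insect
that is drawn in, a gradient-boosting model classifies target mosquitoes
(*Aedes* and *Culex*, by genus and sex), a multivariate-Gaussian density
gate separates those targets from non-target bycatch, and performance is
scored per collection cycle against manual counts — the workflow of modern
smart-trap vector surveillance, built for entomologists and epidemiological
modellers who want to study or extend that analysis chain without access to
proprietary sensor recordings.

The recording dataset behind the original system is unpublished, so the
package ships a first-class synthetic-data module: harmonic wingbeat
waveforms under a transit envelope (class-ordered, partially overlapping
fundamental-frequency distributions; flight tone rising with temperature),
invalid-recording morphologies (double flights, wall hits) with exact
ground truth, and Poisson field-capture streams with diel and seasonal
structure whose expected catches match the published trial totals.

## The statistics at the core

Event-level classification is scored per class one-vs-rest with

    Se = TP / (TP + FN),  Sp = TN / (TN + FP),  BA = (Se + Sp) / 2,

averaged without weights over the four genus × sex classes. Field
performance uses **count-based** confusion per collection cycle — sensor
count s vs manual count m, with manual negatives n:

    TP = min(s, m),  FP = max(s − m, 0),  FN = max(m − s, 0),  TN = n − FP,

plus Pearson correlation and OLS regression of sensor on manual counts
(slope < 1 ⇒ the sensor undercounts), and diel activity profiles (average
hourly sensor count per month per genus). Target detection gates each
recording on the fitted Gaussian log density,
log p(x) = −½[(x−μ)ᵀΣ⁻¹(x−μ) + log det 2πΣ] ≥ θ, with θ calibrated to
maximize event-level BA on a labeled stream. See `docs/methods.md` for the
full model and every convention.

## Worked example

The numbered drivers under `analysis/` run the whole study in order. A
reduced laboratory build (4000 simulated flights instead of the full
15,208):

```sh
$ python analysis/01_published_tables.py
$ python analysis/02_lab_pipeline.py --seed 1 --flights 4000
recorded 4000 flights; 3696 valid after cleaning (7.6% rejected)
balanced dataset: 3160 flights; test set 1000
selected hyperparameters: {'max_depth': 6, 'learning_rate': 0.1} (CV BA 96.9%)
test mean BA: 97.1%
  AEDES_F: 95.4%
  AEDES_M: 98.3%
  CULEX_F: 98.7%
  CULEX_M: 96.1%
gate calibration BA: 97.9% (log-density threshold -22.36)
$ python analysis/03_field_trials.py --seed 2
trial 1: 4820 recordings, 29 cycles analyzed
  detection mean BA 98.5% (median 98.8%), r = 0.991
  genus/sex overall BA 93.8%
trial 2: 4125 recordings, 15 cycles analyzed
  detection mean BA 99.0% (median 99.1%), r = 0.995
  genus/sex overall BA 97.0%
combined (44 cycles): detection mean BA 98.7%, genus/sex 94.9%, slope 0.991, R² 0.991
$ python analysis/04_activity_dynamics.py
trial 1 Aedes: top hourly activity 19:00 (0.38/h), 06:00 (0.30/h), 07:00 (0.27/h)
trial 1 Culex: top hourly activity 23:00 (1.03/h), 02:00 (1.02/h), 00:00 (0.98/h)
...
```

Reading the output: 7.6% of recordings were rejected by the automated
cleaning (the designed invalid rate is 7.5%); the classifier's test BA of
97.1% is the mean of the four one-vs-rest per-class BAs on a held-out
stratified 1000-flight test set; in the simulated field trials the
count-based detection BA per cycle averages ~99% and the sensor-on-manual
regression slope of 0.991 means the sensor total tracks the manual total
almost one-to-one. The recovered *Aedes* activity peaks (06:00 and 19:00)
are the dawn/dusk bimodality designed into the simulator; *Culex* activity
is nocturnal. Synthetic accuracies sit above the published field figures
because the synthetic classes are more cleanly separable than real catches
— see `docs/methods.md` for what these numbers do and do not show.

## Layout

```
src/trapsense/      library: simulate, features, classify, detect,
                    fieldeval, pipeline, published (+ packaged tables)
analysis/           numbered narrative drivers (01–04)
scripts/            acceptance.py
tests/              pytest suite (unit, property, acceptance)
docs/methods.md     model, conventions, limitations
```
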