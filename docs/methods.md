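# Methods

## Protocol representation

A session is an ordered, contiguous list of illumination phases.  The
frozen default is five 2-s phases (10 s total): IR-both, VIS-right,
IR-both, VIS-left, IR-both.  Each visible phase defines a stimulus window
with three attached analysis intervals: the immediately preceding infrared
phase as baseline ("maximum diameter before irradiation"), the stimulus
interval itself, and the 2 s after light-off as recovery window (clipped to
the session end).  Time is seconds from session start; every interval maps
to samples half-open `[start, end)` so boundary samples are never counted
twice.  Timelines are configurable (durations, order), but a visible phase
must always be preceded by an infrared baseline.

A consequence of this timing worth keeping in mind when reading results:
the recovery window of the first stimulus **is** the baseline window of the
second ([4, 6) s).  Any incomplete recovery or overshoot after the first
stimulus therefore propagates into the second stimulus's baseline — a
limitation inherent to the 2-s interval design itself.

## Pupil dynamics model

No kinetic model of the pupil is prescribed by the measurement protocol, so
the generator uses a phenomenological model chosen for having closed-form
landmarks that tests can pin down:

* **Constriction.**  `c(t) = A · h(t − L)/h(t*)`,
  `h(s) = exp(−s/τ_fall) − exp(−s/τ_rise)`, `τ_fall > τ_rise`.  `h` peaks at
  `t* = (τ_fall τ_rise/(τ_fall − τ_rise)) ln(τ_fall/τ_rise)`; the
  normalisation makes the peak constriction exactly `A` mm at `t = L + t*`.
  Because `h` decays after its peak (pupil escape), the diameter minimum
  occurs strictly inside a sustained stimulus and the miosis time is a
  non-degenerate statistic.
* **Consensual coupling.**  The fellow eye receives the same waveform
  scaled by `consensual_gain` (default 1: direct and indirect responses are
  statistically identical in healthy subjects).
* **Recovery.**  During the latency after light-off the deficit holds at
  its offset value `c_off`, then decays as `c_off·exp(−t/τ_rec)`, minus a
  rebound term `R·ĝ(t)` where `ĝ` is a normalised difference of
  exponentials (0.5/0.15 s, peak ≈ 0.26 s) and `R = rebound_frac ×` resting
  diameter.  With `R > 0` the pupil transiently overshoots its resting
  diameter (post-stimulus sympathetic rebound).  Contributions of multiple
  stimulus windows superpose additively on the resting baseline.
* **Noise.**  Additive iid Gaussian per sample (default SD 0.05 mm).  No
  autocorrelation or hippus is modelled.

Ground-truth metrics are computed from the noiseless model evaluated on the
same sampling grid as the trace and scanned exactly like the metric
extractor, so on a noiseless trace the pipeline reproduces the ground truth
to machine precision, while the grid minimum sits within one sample period
of the analytic extremum `L + t*`.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| sample rate | 60 Hz | typical infrared video pupillometry frame rate; configurable |
| latency L | 0.2 s (SD 0.015) | onset latency of the light reflex |
| τ_fall, τ_rise | 1.4 s, 0.3 s (3 % jitter) | puts the minimum ≈ 0.79 s after onset, inside the 2-s stimulus, with visible pupil escape |
| τ_rec | 0.5 s (healthy) | fast-phase redilation; leaves the next baseline phase essentially clean |
| resting diameter | 6.5 − 0.035·age mm, subject SD 0.35 | senile miosis: linear age decline |
| anisocoria | 0.7 mm, right > left | fixed right-minus-left offset; single config knob |
| relative amplitude | 0.40 − 0.0012·age of resting diameter, SD 0.015 | constriction weakens with age, so miosis rates climb with age |
| noise SD | 0.05 mm | plausible per-frame measurement noise |

Age brackets: five brackets of five subjects, [20,30), [30,40), [40,50),
[50,60), [60,92) — bracket midpoints average 47.2 years and the last
bracket supplies exactly the five over-60 subjects the patient comparison
needs.

### Patient (left-lesion) effects

Patient effects are phenomenological multipliers calibrated to reproduce
the directional clinical findings, not a neurological model:

* `lesion_speed_factor = 0.6` scales both constriction time constants of
  the lesioned eye in **both** modes — its minima come ≈ 0.2 s earlier
  whichever eye is stimulated.
* `lesion_direct_factor = 0.7` scales the lesioned eye's amplitude under
  **direct** stimulation only — its direct miosis rate is elevated while
  its consensual response stays normal.
* `rebound_frac = 0.12` bilaterally, boosted ×2.5 after direct stimulation
  of the lesioned eye, with `τ_rec = 0.4 s`.

The rebound structure is forced by arithmetic, not taste.  With a pure
exponential return to baseline, `recovery_max ≤ baseline`, so a patient's
mydriasis rate can never drop below their miosis rate; an elevated
lesion-side miosis rate and a lowered lesion-side mydriasis rate therefore
jointly require overshoot above baseline.  Further, because window-2's
baseline is window-1's recovery window, a uniform large overshoot would
deflate window-2 miosis rates; the constraints ("lesion-side direct miosis
rate up", "mydriasis rates down in all four cells") pin the rebound to be
modest after consensual stimulation and strong after direct stimulation of
the lesioned eye.  One consequence the model cannot avoid: the patient
right pupil's indirect miosis rate and direct mydriasis rate share both
numerator and denominator windows, so they shift together — the pipeline
shows a lower-than-healthy right-indirect miosis rate even though no
lesion effect targets that cell.

Within-group metric SDs are small (≈ 0.015–0.02) by calibration: the
patient comparisons use n = 5 per group, and directional findings can only
be significant at that size if between-group effects dominate
between-subject spread.

## Segmentation and distance compensation

Frames are segmented by thresholding, taking the largest dark connected
component (8-connectivity, ties broken toward the topmost-leftmost
centroid) and filling holes left by specular highlights before counting
pixels.  The default threshold is a 3-class multi-Otsu with the lowest cut:
the scene has three intensity populations (pupil, iris, sclera), and a
plain 2-class Otsu maximises between-class variance by splitting iris from
sclera, merging the pupil into the iris.  The equivalent diameter is
`2·sqrt(area/π)`; a caliper diameter would agree for the circular pupils
rendered here.  Millimetre conversion uses the pinhole model,
`d_mm = d_px · pitch · distance / focal`, with the camera distance taken
from the rangefinder metadata.  Defaults (focal 12 mm, pitch 5 µm) make an
80-px pupil at 60 mm equal 2.0 mm.  The renderer draws discs with analytic
1-px anti-aliased edges, and its ≥ 50 % coverage mask is the area oracle;
validation across 40–100 mm and 10–60 px recovers diameters within 0.5 %
(tolerance 2 %), including frames with highlights covering 4 % of the
pupil.

## Metrics

Minima and maxima are taken over usable (`ok`) samples only; blink and
missing samples are excluded, and a window with under 25 % usable samples
fails with an error naming the eye and stimulus.  Miosis time is referenced
to stimulus onset and tie-broken to the earliest minimising sample.  No
smoothing is applied before extrema by default, which keeps the extractor
exactly equal to an exhaustive sample scan; a moving median for noisy real
recordings would trade that exactness for robustness and is deliberately
not enabled.

Noise propagates into the rates through extreme values: the baseline
maximum over ~120 iid-noise samples is biased up by ≈ 2.5 SD and the window
minimum down by ≈ 2 SD, so the mean absolute rate error is bounded by about
4·noise_SD/baseline (0.05 at the defaults) rather than the naive
2·noise_SD/baseline.

## Statistics

Two-group comparisons follow the gated rule: Shapiro–Wilk on each sample,
Student's t (equal variances) if both pass at α = 0.05, otherwise two-sided
Mann–Whitney U; constant samples (Shapiro undefined) fall back to
Mann–Whitney and are flagged.  All tests are two-sided; no multiplicity
correction is applied, and reports carry the number of tests performed.
The right-vs-left comparison of spontaneous diameters is paired (same
subjects), gated on the normality of the differences.  Direct-vs-indirect
equivalence is reported two ways: per eye, as the panels are conventionally
displayed, and pooled across eyes.  The per-eye contrasts compare the first
stimulus window against the second and so inherit the small carry-over bias
described above; the pooled contrast assigns one early-window and one
late-window cell to each group and is therefore balanced with respect to
stimulus order — it is the contrast used for the equivalence check.

Study 3 selects the over-60 healthy subset (exactly 5 with the default
brackets) and compares every metric × condition cell, plus spontaneous
diameters, against the patients.  Three headline flags require both
significance and direction: elevated lesion-side direct miosis rate,
shortened lesion-side miosis times (both modes), and lower mydriasis rates
in all four cells.  The miosis-time flag has limited power at n = 5 because
per-subject timing jitter under measurement noise is ≈ 0.1 s against a
≈ 0.2 s effect; the direction itself is stable.  With lesion factors set
to 1 and matched parameters all flags are type-I events and occur in under
5 % of seeds.

## What the generator does and does not emulate

It emulates: the five-phase session, age-dependent baselines with
right-dominant anisocoria, consensual coupling, pupil escape, incomplete
2-s recovery, lesion-side constriction deficits, patient rebound mydriasis,
iid measurement noise, blink dropouts, and the camera geometry of the
imaging chain.  It does not emulate: hippus and autocorrelated noise,
pharmacological effects, ambient-light adaptation, gaze-dependent pupil
ellipticity, eyelid occlusion, or between-session carry-over.  Passing
tests therefore demonstrate that the pipeline's arithmetic, decision rules
and imaging chain are correct under controlled conditions with known truth;
they do not certify performance on clinical video.

## Problem sizes

Default analyses use the full design sizes (25 healthy, 5 patients, 60 Hz,
10-s sessions).  The equivalence and type-I calibration checks run 100 and
60 seeds respectively; the imaging validation sweeps 60 rendered
conditions.
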