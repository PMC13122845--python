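# Methods

## Background and scope

Craniospinal compliance — the volume a cranio-spinal system accommodates per
unit pressure rise — can be probed on two very different scales. Over one
cardiac cycle, the arterial inflow transiently adds a few millilitres of
blood to the cranium and the ICP pulse records the resulting pressure
excursion; over the ten-odd minutes of a constant-rate lumbar infusion, tens
of millilitres of saline drive mean ICP from baseline to a steady plateau.
This package computes both estimates per subject and compares them at cohort
level:

- `C_physio = dV_ART / dP_CC`, the arterial-related physiological compliance
  (mL/mmHg), from 32-frame cardiac-gated flow curves of the two internal
  carotid arteries and the basilar artery plus a baseline lumbar ICP
  recording;
- `C_INF = dV_INF / dP_INF`, the infusion-derived compliance-related
  parameter, together with the CSF outflow resistance
  `Rout = dP_INF / rate` (mmHg/mL/min).

Image acquisition and vessel segmentation are out of scope: the package
consumes flow curves (mL/min, 32 samples per reconstructed cycle), not
images.

## Arterial volume change

The three vessel curves are summed pointwise into the total arterial inflow
`Q_ART` (after an optional per-vessel clamp of negative samples, off by
default: upstream flow software normally extracts inflow as positive values
at segmentation level, which we cannot reproduce from curves). `Q_ART` is
converted to mL/s once at load and integrated by cumulative trapezoid with
`dt = T/32`, closing the cycle periodically with the first sample at `t = T`.
With this quadrature the full-cycle integral equals `mean(Q)·T` exactly, so
for strictly positive inflow and no mean subtraction the amplitude
`dV_ART = max(V) − min(V)` coincides with the stroke-volume integral. The
alternative convention — subtracting the mean flow before integrating, which
isolates the pulsatile excursion — is exposed as `subtract_mean_flow` and
reported alongside; the default is no subtraction. At 32 samples the
trapezoid amplitude of band-limited waveforms (≤ 4 harmonics with
physiological 1/k decay) stays within 2% of a dense-quadrature oracle.

## Baseline ICP pulse amplitude

`dP_CC` is the peak-to-peak amplitude of an ensemble-averaged single-cycle
pulse from a 30 s baseline window ending 10 s before infusion start (shorter
baselines fall back to the full annotated window with a warning; below 10 s
the analysis refuses). The chain:

1. **Cardiac frequency**: largest FFT magnitude in 0.8–2.5 Hz (48–150 BPM).
   A flat or noise-only segment has no peak above the floor and is rejected.
2. **Band filter**: FFT bins outside `[0.66·f_c, min(15 Hz, 10·f_c)]` are
   zeroed (hard edges by default; a raised-cosine taper of configurable
   width is available) and the signal reconstructed by inverse FFT. The DC
   bin is kept by default so the averaged pulse sits at physiological mean
   ICP; the amplitude is DC-invariant either way. `0.66·f_c` cleanly
   separates respiration (≤ 0.5 Hz) from the slowest plausible cardiac
   fundamental; the 15 Hz cap retains roughly ten harmonics of the pulse
   shape. The filter is idempotent by construction.
3. **Beat segmentation**: peaks with minimum spacing `0.6/f_c` and
   prominence `0.25·SD(segment)` — thresholds chosen so that a tidal (P2)
   sub-peak exceeding the percussion peak is not double-counted. Pulses are
   the half-open spans between consecutive peaks; beats whose length
   deviates more than 25% from the median are discarded (guards the average
   against missed or spurious peaks); fewer than three retained beats is an
   error.
4. **Averaging**: each pulse is linearly resampled to 32 points on a
   normalized cycle (matching the 32-frame flow reconstruction, so both
   sides of `C_physio` live on the same grid), aligned at its starting peak,
   continued periodically at phase 1, and averaged pointwise. Peak alignment
   was chosen over upstroke-onset alignment; for amplitude estimation the
   difference is immaterial on jitter levels we model.

Averaging n beats reduces additive white noise by `1/sqrt(n)` (times a
constant interpolation factor); residual noise still inflates the
peak-to-peak estimate slightly because max and min are selected over noisy
points. With the default noise calibration (SD ≈ 0.2 mmHg against a 3 mmHg
pulse) the net bias of the whole chain is below 1%, and it stays below 2%
even at noise SD up to 20% of the pulse amplitude.

## Infusion analysis

Plateau onset is detected on the slow trend (10 s centred moving average,
which cancels cardiac and respiratory oscillations) in consecutive
non-overlapping 60 s windows after infusion start. A window qualifies when
its least-squares slope is ≤ 0.2 mmHg/min **and** its mean lies within
1 mmHg of the largest windowed mean later in the recording (the level guard
prevents a pause on the rising limb from being taken for the plateau). The
plateau runs from the first qualifying window's start to the recording end.
Non-overlapping windows make the detection granularity explicit (the stride
is configurable); on a first-order exponential rise with amplitude 20 mmHg
and `tau = 120 s` the onset lands at ≈ 480 s, consistent with the
closed-form crossing of the slope criterion near `3.9·tau`.

Baseline and plateau mean ICP are taken on the **raw** trace (annotated
baseline window / detected plateau interval) because mean ICP must include
the slow components the pulse filter removes. `dV_INF = rate · dt_INF`
(rate in mL/min, `dt_INF` in minutes), `C_INF = dV_INF/dP_INF`,
`Rout = dP_INF/rate`; the identity `C_INF · Rout = dt_INF` (minutes) holds
to machine precision and is asserted in the tests. A plateau mean at or
below baseline signals an annotation or detection failure and raises.

Cohort means of `C_physio` and `C_INF` are always means of per-subject
ratios, never ratios of cohort means — with published-scale values the two
differ materially (17/20 = 0.85 vs a subject-wise mean near 1.0).

## Cohort statistics

Paired outcomes are compared two-sidedly with a normality gate:
Shapiro–Wilk on the paired differences at alpha 0.05 chooses between the
paired t-test and the Wilcoxon signed-rank test (zeros dropped; normal
approximation with continuity correction beyond n = 25; all-zero
differences give p = 1; constant nonzero differences go to Wilcoxon since
normality is undefined). The family adjusted together by the step-down Holm
procedure is the set of condition contrasts run in one cohort invocation —
measurement duration (minutes vs seconds, on their native reporting
scales), volume change, pressure change, compliance — mirroring how the
outcome comparisons belong to one figure-level family; the heart-rate
contrast is reported separately. Associations use tie-corrected
(average-rank) Spearman correlations with pairwise-complete observations;
a constant variable yields a flagged entry rather than propagating NaN.
Summaries report mean, SD (n−1), Q1/Q3 with linear-interpolation quantiles,
and CV% = 100·SD/mean.

## Synthetic cohort generator

Patient recordings cannot be redistributed, so cohorts are synthesised with
per-subject ground truth drawn from truncated normals calibrated to the
published cohort (n = 108): MRI heart rate 74 ± 14 BPM, arterial mean flow
426 ± 102 mL/min, pulse amplitude 3.0 ± 1.5 mmHg (floor 0.5 mmHg to keep
ratio metrics finite), baseline ICP 11 ± 4 mmHg, infusion rise 20 ± 9 mmHg,
respiration 0.25 ± 0.05 Hz at 1.5 ± 0.5 mmHg, measurement noise
0.2 ± 0.05 mmHg, sampling 100 Hz. Heart-rate bounds are set at 50–120 BPM —
a realistic range for an elderly cohort that also keeps every cardiac
fundamental inside the 0.8–2.5 Hz detection band. The infusion-test heart
rate is coupled to the MRI heart rate through a Gaussian copula with
Spearman rho 0.84 and a slightly lower mean (73 ± 13); with this 1 BPM
offset the paired heart-rate contrast is *not* reliably significant at
n = 108, a deliberate compromise in favour of matching the published
0.83 s mean cycle duration (`E[60/HR] > 60/E[HR]` by Jensen's inequality,
so the mean period exceeds the period of the mean heart rate).

Flow curves are `share_v · q_mean · w(t)` with
`w(t) = 1 + 0.8·(g(t) − mean g)`, `g` a Gaussian systolic bump at `0.15 T`
with width `0.08 T`; the 32-sample mean of the summed curves equals
`q_mean` exactly. The ICP trace is trend + pulse + respiration + white
noise. The pulse is a smooth periodic template with the three classical
sub-peaks (P1, P2 = 1.1·P1, P3) and a rounded end-diastolic trough, built
from circularly wrapped Gaussian bumps so essentially all energy lies below
the tenth harmonic — the analysis band filter then leaves the shape intact
(noise-free full-chain recovery within 1%). Beats jitter by 3% SD. The
infusion trend is a single first-order exponential `icp_b +
dP·(1 − e^(−t/tau))`: the analysis only detects a plateau, so the simplest
trend possessing one suffices and has closed-form oracles. The time
constant is `tau ~ TruncNormal(210 s, 60 s, [60, 390])`: by the
detection-time closed form `t* = tau·ln(5·dP·(1 − e^(−60/tau)))` this
places the detected infusion duration near the published 11–12 min and
hence the infused volume near 17 mL at 1.5 mL/min — the infused volume is
deliberately calibrated *through* detection, since `dV_INF` is itself
pipeline output. Recordings run 300 s baseline, `6·tau` of infusion and
300 s of continued plateau. Pulse amplitude is held constant across
baseline and infusion by default (the pulse is measured pre-infusion only);
an amplitude-tracks-pressure flag exists for realism experiments.

All randomness descends from one master `SeedSequence`; identical
configuration and seed give byte-identical cohorts.

### What the generator does not emulate

Real ICP exhibits B-waves and vasogenic slow waves, posture and coughing
artefacts, infusion-needle transients, and pulse-shape changes with rising
mean ICP; arterial curves carry segmentation noise and aliasing residue.
The independent draws also make `C_physio` and `C_INF` uncorrelated at
truth level, whereas the published cohort reports a moderate positive
correlation (R ≈ 0.46) — the generator has no shared "stiffness" latent
factor. Passing tests therefore demonstrate correctness of the measurement
chain and of the statistics under the modelled signal structure, not
robustness to every clinical artefact.

## Problem sizes and tolerances

Cohort-level checks run the complete chain on n = 108 subjects; calibration
recovery averages three seeds and requires each cohort mean within three
standard errors (`3·SD/sqrt(108)`) of its anchor, with the cycle duration
held to ±0.05 s. The headline inference (infusion compliance lower than
physiological compliance at Holm-corrected p < 0.001) is required in at
least 99 of 100 seeds. Pulse-chain bias is estimated over 200 baselines
with amplitudes 1–6 mmHg, respiration up to twice and noise up to one
fifth of the amplitude. Numerical identities (quadrature closure,
`C_INF·Rout = dt_INF`) are asserted at machine precision; analytic
recoveries at 1–5% reflecting discretisation and detection granularity.
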