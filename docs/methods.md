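# Methods

This note documents the models, defaults and numerical choices behind
`posturolab`, and what the synthetic validation does and does not show.

## Signals

A trial holds two plate records (vertical force in newtons, CoP in mm,
common sampling rate read from the file header — 120 Hz in the reference
protocol). The combined CoP is the per-sample force-weighted mean of the
plate CoPs; it degenerates gracefully to the loaded plate during
single-support, which is what makes step episodes analysable without
special-casing. Simultaneous zero force on both plates is treated as a
recording fault (a standing protocol has no flight phase) and raises a
signal-gap error rather than producing NaNs downstream.

Scalar displacement is the Euclidean distance from a reference point. The
reference is a *choice*, recorded in outputs: the window's mean CoP for
quiet-stance analysis, and the 5 s pre-perturbation mean for perturbation
segments — both make the displacement zero-mean before anything
interesting happens. Velocity is |dD/dt| by symmetric central differences
(one-sided at the ends) with no pre-smoothing at this layer; smoothing
belongs to the envelope. Because D is a scalar distance, a CoP circling
the reference reads ~0 velocity; the 2-D path speed is available as
`path_velocity` for users who want the alternative convention.

## Static sway

The 95% ellipse is the covariance-based prediction ellipse: area
`pi * chi2_{0.95,2} * sqrt(det S)` with `chi2_{0.95,2} = 5.9915`, S the
sample covariance of (AP, ML). This is the standard posturographic
construction; the chi-squared constant is carried in the result metadata
so an alternative 95% construction could be swapped without touching
consumers. Degenerate scatter returns area 0 with a warning rather than
an error, because a perfectly still trace is a legitimate (if suspicious)
measurement. Both ellipse area and mean velocity use the same middle-20-s
window, half-open `[5 s, 25 s)` of a 30 s trial; attaching the window to
only one of the two outcomes would create asymmetric artifacts.

## Perturbation responses

Each perturbation is analysed on a fixed `[-5 s, +4.5 s]` segment.
"Return to steady state" is operationalised as:

* envelope: piecewise-linear interpolation through the local maxima of
  the velocity after a zero-phase 4th-order Butterworth low-pass at 10 Hz
  (endpoints anchor the interpolation);
* band: mean + 2 SD of the envelope over the 5 s pre-window, computed on
  the pre-window *in isolation* — computing it on the full-segment
  envelope lets interpolation toward the large response peak leak into
  the "resting" statistics and roughly doubles the band;
* recovery: the first post-onset instant at which the segment envelope
  stays inside the band for 0.5 s continuously. The dwell prevents
  triggering between oscillation lobes.

Band multiplier, dwell, low-pass cutoff and window lengths are all
exposed in `AnalysisConfig`. Responses that never re-enter the band are
reported at 4.5 s and flagged censored; censored responses, truncated
windows and off-plate step episodes are flagged discarded and excluded
from statistics but counted in the discard rate. The maximal displacement
is taken over the post-onset window only, and the mean recovery velocity
over `[onset, recovery instant]` (onset, not first envelope peak, starts
the average). The final pre-window velocity sample is excluded from
resting statistics because its central difference spans the onset.

The envelope's temporal resolution equals its anchor spacing (local-peak
spacing plus filter width), typically a few tens of milliseconds for
real CoP velocity signals; recovery times inherit that granularity.

## Step detection

"Zero pressure" is force at or below 5 N (plates never read exactly
zero); an unload interval qualifies as a step when it lasts ≥ 50 ms
(interval duration = below-threshold samples / fs, so 6 samples at 120 Hz
is exactly the boundary) *and* the plate's CoP after reloading differs
from before lift-off by ≥ 20 mm. The offset clause operationalises
"changed base of support"; the original protocol confirmed steps on
video, which a signals-only pipeline cannot do. Unload intervals
separated by < 30 ms are merged to absorb touchdown chatter. Landing
CoPs are measured as means over up-to-100 ms loaded windows flanking the
interval. 0 / 1 / ≥2 steps map to in-place / single-step / multiple-step
strategies; step total displacement sums per-step offset magnitudes with
the same distance equation as the CoP displacement.

## Dual-task costs

`DTC = 100 (single - dual) / single`, applied metric-wise per participant
per eyes condition; a metric inflated under dual task yields a negative
cost, matching the sign convention of the balance literature. The
cognitive costs apply the same formula to correct-counting rates
(counts/min) for (reference, sway), (reference, perturbation) and
(sway, perturbation); the third is algebraically determined by the first
two, an identity the tests assert. Perturbation-context counting pools
total counts over total timed duration, since that period varies between
participants. Costs are undefined (typed error) for a zero baseline.

## Group statistics

Outliers are removed in a single pass per metric per group: keep v iff
`|v - median| <= 1.5 * IQR`, quartiles by linear interpolation; removal
counts are reported per cell. The rule is deliberately not iterated.
Group comparison is the two-sided Mann-Whitney U: exact null when the
combined sample is ≤ 16 without ties, tie-corrected normal approximation
otherwise, with the method recorded in the result. The 2×2 multiple-step
contrast reports the uncorrected chi-squared statistic alongside the
Yates-corrected variant and the Fisher exact p, because the three can
disagree materially at step-episode sample sizes and the field is not
consistent about which it prints. No multiple-testing correction is
applied to the headline p-values; a Benjamini-Hochberg column is emitted
alongside for transparency. Repeated per-perturbation values are averaged
per participant before comparison.

## Synthetic cohort generator

The generator's defaults *are* the study conditions it emulates: 30 s
sway trials in EO/EC × DT/NoDT; eight perturbations per dynamic trial
(translations and tilts in four directions) with 9–15 s uniform gaps and
5 s pre-perturbation standing; 120 Hz plates under a 700 N body split
50/50 with slow anti-phase load modulation, 0.5 N sensor noise and
±100 mm stance offsets.

**Sway model.** Each axis is a stationary Ornstein-Uhlenbeck process
(mean reversion k, drive sigma; stationary variance `sigma^2/2k`),
simulated exactly at a 2 Hz knot rate and reconstructed at the plate rate
by polyphase (near-sinc) upsampling, plus white per-sample jitter. Sinc
reconstruction preserves the sampled process's variance (so the
closed-form variance holds at the plate rate) while confining the smooth
component's power below 1 Hz; this separation is what lets ellipse area
(variance) and mean velocity (bandwidth + jitter) be tuned
near-independently — the degrees of freedom the rigidity phenotype needs.
Defaults: control k = 2.0 /s, sigma = 5.86 mm/√s, jitter 0.07 mm
(eyes-open area ≈ 148 mm² at ≈ 9 mm/s); clinical-like k = 2.857 /s, same
sigma, jitter 0.16 mm (area ratio ≈ 0.7, velocity ratio ≈ 1.4).
Eyes-closed, dual-task and pre-perturbation anticipation factors
(variance and jitter multipliers per group) reproduce the corresponding
condition ratios of the reference cohort's printed tables. Participant
heterogeneity is lognormal with 10% CV on k, sigma, jitter and the
recovery time-constant.

**Perturbation kernel.** A double-exponential displacement
`A (e^{-t/tau2} - e^{-t/tau1})`, normalised so its peak equals the
configured amplitude (140 mm translations, 0.7× tilts; rise tau1 =
0.08 s), oriented along the perturbation direction. Recovery
time-constants tau2 = 0.80 s (control) vs 0.60 s (clinical-like) yield
detected recoveries of ≈ 1.7 s vs ≈ 1.3 s. The ground-truth recovery
instant is when the *noise-free* kernel speed has decayed into the
segment's resting envelope level (its pre-window mean) — past that point
the response is indistinguishable from resting activity, and the noisy
total envelope rides roughly one resting level above the kernel, so the
detector's band crossing lands there; the pipeline recovers these truths
with a median signed error under 0.15 s at default noise. Because the
kernel is peak-displacement-normalised, its speed scale falls as tau2
grows, and detected recovery flattens as a function of tau2 above
≈ 1.3 s — monotonicity holds in the physiological range only.

**Steps.** With per-group probability (0.39 / 0.36) a perturbation evokes
a step response, multiple (2–3 steps, alternating feet) with probability
0.10 / 0.60. Each step unloads one plate for 120–250 ms while the other
carries full weight, then lands the plate's CoP 40–90 mm away (offset
defined as post-reload minus pre-unload plate CoP, easing back to the
marked stance over ~2 s). Injected step counts are recovered exactly by
the detector on noise-free plates and at ≥ 99% with default sensor noise.

**Counting.** Poisson tallies at per-participant rates drawn from
17.5 ± 3.6 (control) and 11.9 ± 3.6 (clinical-like) counts/min, with
per-context multipliers.

All randomness flows from one master seed through spawned substreams, so
equal seeds give bit-identical cohorts.

## Replicate validation

`validation.replicate_contrasts` simulates study-sized cohorts (12 vs 11
participants; eyes-open and eyes-closed sway plus one eight-perturbation
trial each — the contrast-bearing subset, sized to keep 100 replicates
within a few minutes on one CPU), runs the full pipeline, applies the
same single-pass IQR outlier rule as the report layer, and tests each
contrast: ellipse area in the eyes-closed condition (the condition in
which the reference cohort's area separation was unambiguous; a 0.7 area
ratio estimated from one 20-s eyes-open window is underpowered at this
sample size — in the reference cohort as here), mean velocity eyes-open,
recovery time from the single-task trial summarised per participant by
the *median* over events (event-level recovery is right-skewed), and the
pooled single-vs-multiple step 2×2 by chi-squared. At defaults, all four
contrasts are detected at p < .05 with the configured direction in
≥ 90% of 100 replicates.

Two interactions found during validation are worth knowing: dual-task
velocity inflation raises the control group's resting band and thereby
*shortens* its detected recoveries, so pooling DT and NoDT perturbations
dilutes the recovery contrast; and anticipation inflation makes pre-
perturbation 5-s windows several-fold larger in area than quiet-stance
windows, as in the reference protocol.

## What passing tests do and do not show

The generator emulates stationary band-limited sway, deterministic
perturbation kernels with additive sway, force-criterion-clean steps and
Poisson counting. Real recordings contain non-stationarity (fatigue,
drift), direction-dependent and participant-specific response shapes,
partial unloads and shear during steps, vendor filtering, and missing or
clipped samples beyond the single failure modes modelled here. Passing
the synthetic validation therefore demonstrates correctness of the
*computations* and adequate detector behaviour under the modelled noise —
not clinical validity on any particular rig's data.

## Known limitations

* The recovery detector's steady-state notion (mean + 2 SD envelope band,
  0.5 s dwell) is one reasonable operationalisation; all parameters are
  config-exposed precisely because the construct is not standardised.
* Recovery-vs-tau2 monotonicity flattens above ~1.3 s (peak-normalised
  kernel), and recovery times inherit the envelope's anchor-spacing
  granularity.
* Step detection is force-only; steps fully off the instrumented area are
  flagged discarded, not reconstructed.
* The 95% ellipse assumes approximately elliptical scatter; heavy-tailed
  or multi-modal CoP distributions will be summarised, not flagged.
* Counting correctness (serial-7 errors) is a generator attribute; the
  analysis consumes correct-count tallies only.
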