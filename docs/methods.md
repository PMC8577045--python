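# Methods

This note documents the models and procedures implemented in `drgsens`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Statistics

Two-group mean comparisons use the pooled-variance unpaired Student t-test:
t = (m₁ − m₂)/√(s_p²(1/n₁ + 1/n₂)) with s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)
and df = n₁ + n₂ − 2; a Welch variant is available behind a flag.  Two
identical constant groups return t = 0, p = 1.  Proportion comparisons use
the uncorrected Pearson χ² on 2×2 tables, χ² = (ad−bc)²N/(r₁r₂c₁c₂), df = 1;
Yates' continuity correction is available behind a flag but off by default,
because the uncorrected statistic is the one consistent with the printed
p-values these analyses conventionally report.  No multiple-testing
correction is applied anywhere.

P-value display truncates (floors) at the requested decimal place —
p = 0.0484 prints as "0.04" — which is the only convention consistent with
reporting that style of table; the untruncated value is always retained.
Per-animal percentages (spontaneous activity, multiple firing; N = 3
animals per side) are compared with t-tests across animals, while pooled
per-neuron counts (agonist responders, IHC positives) are compared with χ²
— mixing the two units deliberately mirrors standard practice in this
literature and is not a recommendation.

## Current-clamp analysis

Spike detection is a Schmitt trigger on the membrane potential: an event
fires on an upward crossing of the overshoot level (default −10 mV) after
the trace has been below a re-arm level (overshoot − 5 mV), with a 2-ms
minimum inter-peak interval.  The AP threshold crossing is the last upward
crossing of dV/dt = 10 V/s before the peak.  These defaults are standard
nociceptor criteria; all three are parameters.  The trigger's hysteresis
makes it robust to noise chatter on the falling phase, and on synthetic
data it agrees exactly with a brute-force crossing-count oracle.

Features per spike: amplitude = peak − RMP (threshold-to-peak available);
HPD = interpolated width at RMP + amplitude/2; AHP amplitude = RMP − trough;
AHP duration = time from the post-spike downward RMP crossing until the
potential recovers to within 80% of the AHP depth (the metric's exact
definition is not standardised; the 80% recovery point is this package's
choice, exposed as a constant).  Spikes truncated at a trace edge yield
NaN for the affected features rather than a biased value.

Rheobase is the lowest level of the current-step protocol (20 evenly spaced
steps from 100 to 1000 pA inclusive, increment 900/19 ≈ 47.37 pA, 80 ms per
step — the grid is configurable) whose step window contains a spike; the
first spike of that sweep is the one measured.  "Multiple firing" is true
if any step evokes ≥2 spikes, evaluated over all steps rather than only at
rheobase.  Spontaneous activity is ≥1 detected spike in a zero-injection
recording; the window defaults to 30 s (the study duration is not
standardised, so it is configurable).  Agonist scoring subtracts the spike
count of the 10-s wash immediately preceding the 10-s application and
divides by the application time; "above baseline" is a strict inequality,
so ties are non-responders.

## Voltage-clamp analysis

Baseline subtraction removes the mean of the final 100 ms of the −120 mV
pre-pulse from the whole sweep, which eliminates any constant offset
current exactly.  Current density is the test-window minimum (inward) and
maximum (outward) divided by capacitance.  The Boltzmann fit minimises
unweighted least squares of I(V) = Σ Imax/(1+exp((V½−V)/k)) with 1 or 2
components, initialised at Imax = extreme density, V½ = voltage nearest
half the extreme, k = 8 mV, with up to 5 jittered restarts; the
two-component fit additionally starts from the one-component solution with
a negligible second component, which guarantees its residual never exceeds
the one-component residual.  Non-convergence is reported as an explicit
failed fit, never silently.  Ohmic leak beyond the constant-offset baseline
(e.g., P/N subtraction) is not modeled.  Fits can be run per neuron
(default) or on group means.

## Ca²⁺-imaging analysis

All windows are event-local: F₀ is the mean of the 10-s wash preceding each
application, so slow drift between events cannot bias later events, and the
ΔF and Fmax entering the ratio use their own local baselines (the ratio is
otherwise undefined under drift).  The peak is searched over the
application plus its 90-s wash; responses with peak latency > 30 s from
application onset are excluded as drift ("late_peak"), and responses with
ΔF/Fmax < 0.001 as noise ("below_threshold"); both boundaries are inclusive
for responders (exactly 0.001 and exactly 30 s count).  ROIs whose KCl
excursion does not exceed 5 baseline-noise SDs are dropped up front
(emulating the manual drawing of only KCl-positive cells), and ROIs whose
KCl response is non-positive are excluded as "kcl_negative".  Exclusions
are accounted: retained + excluded always equals the input ROI count, and
every classified response carries its exclusion reason.  All calls are
invariant to rescaling a dish by a positive constant.

## IHC scoring

The positivity threshold is mean + 2·SD of the per-section minimum gray
values ("distribution of minima"), built per animal × stain batch by
default because staining intensity is batch-dependent (scope configurable
to global); sample (n−1) SD throughout; a neuron is positive on a strict
inequality.  An optional per-section min–max normalisation before pooling
the minima exists but is off by default — pooling raw values is the most
literal reading of the rule.  Note the rule presumes that each section's
least-stained neuron estimates that section's background and that negative
neurons cluster near it; with a broad iid negative population the
threshold would sit in the negative distribution's lower tail and the rule
would not separate anything (see the generator notes below).  Size
categories default to small ≤ 600 μm², medium ≤ 1000 μm², large above —
only the 1000 μm² boundary (the small–medium nociceptor pool) is anchored
in the literature; both cutoffs are labelled conventions and configurable.

## Synthetic-data generators

The generators exist to make every analysis operator testable with known
ground truth; they are calibrated to the study conditions, not to be
biophysical models.

**Current clamp** uses a template AP (piecewise-exponential rise 2 ms and
fall 8.5 ms, giving a 3.1-ms half-width, peak ≈ RMP + 101.6 mV, 14-mV AHP
with 10-ms recovery — values matching reported ovine DRG AP properties)
inserted into a flat RMP of −48.3 mV with Gaussian noise (default 0.5 mV).
Suprathreshold steps evoke a configurable number of evenly spaced spikes;
spontaneous firing is a renewal process whose inter-event interval is the
template duration (absolute refractory) plus an exponential, so the mean
count over T is T/(τ_refr + 1/rate), slightly below rate·T.  No
conductances, adaptation, or subthreshold dynamics are modeled; passing
tests show the *operators* are correct, not that real traces look like
this.

**Voltage clamp** generates a fast inward alpha-function transient and a
delayed sigmoidal (1−e^(−t/τ))⁴ outward component whose step-wise peak
amplitudes follow planted Boltzmann activation curves, plus a constant
offset current standing in for leak.  The constant-offset choice (rather
than ohmic leak) makes baseline subtraction exact by construction; an
ohmic leak would survive baseline subtraction and contaminate the fitted
activation curve, which is precisely why real experiments apply P/N leak
subtraction that this package does not model.

**Ca²⁺ imaging** builds each ROI as a shared background series plus a
baseline, optional linear drift, and unit-peak double-exponential
transients (τ_rise 2 s, τ_decay 10 s → peak ≈ 3 s after onset): every cell
responds to the terminal KCl application (amplitude 50 gray units);
planted responders additionally respond to their agonist at a relative
amplitude drawn from (0, 1].  Default noise is 0.005 gray units — small
relative to KCl — because the 0.001 ΔF/Fmax exclusion threshold (0.05 gray
units at these amplitudes) is only a usable rule when instrument noise
sits below it; noisier settings are available but then the 0.001 rule
itself admits noise peaks, which is a property of the rule, not of the
implementation.

**IHC** plants exact per-section positive counts.  Negative neurons sit at
their section's background level plus a small jitter (0.25 gray units),
and the section backgrounds are stratified draws — one per quantile bin of
the between-section distribution (default uniform 20–40), shuffled, plus
0.25 jitter — emulating a systematic staining/sectioning gradient across
serial sections.  Stratification matters: with iid section backgrounds and
only 6 sections, the sample SD of the minima occasionally underestimates
the spread (the extremal case is five clustered sections plus one high
outlier, where the sample maximum attains the Samuelson bound of
mean + 2.04·SD), letting an entire section's negatives cross the
mean + 2·SD threshold.  Positive neurons draw iid from a normal (120 ± 15)
far above the threshold.  Areas are log-normal (median 700 μm², σ 0.5),
consistent with predominantly small–medium DRG profiles.

All draws flow from one seeded `numpy` generator per call; identical
parameters and seed give bit-identical outputs.  Planted labels use exact
rounded counts (`round(fraction·n)`, shuffled), so recovered proportions
equal the planted ones up to classification error rather than binomial
sampling error.

## Pipeline and problem sizes

The default end-to-end run simulates the study-sized cohorts: 15/16
patched neurons across 3 animals per side (30-s spontaneous windows, 20
protocol sweeps, two agonist trials each), 6 voltage-clamp cells per side,
one dish per agonist and side at the reported ROI counts (141/109
capsaicin, 115/69 αβ-me-ATP), and 6 × 300-neuron sections per stain and
side for IHC — a deliberate scale-down from the thousands of pooled IHC
neurons, chosen to keep a default run at a few seconds; the printed-count
statistics always use the full printed counts as inputs.  Stage seeds are
spawned from the run seed, outputs are tidy CSVs with provenance columns
(animal, side, weeks post-injury — enabling per-week breakdowns by simple
grouping), and reruns with the same config are byte-identical.

## Known limitations

- Trace-level results of any specific real dataset are not reproduced —
  raw recordings are not public; the tests demonstrate operator
  correctness and planted-effect recovery only.
- Per-animal nesting of neurons is ignored by the pooled χ² comparisons
  (as is conventional here); no mixed-effects alternative is provided.
- The IHC "manual validation" step that typically follows automatic
  scoring is not reproducible and is not modeled; automatic calls only.
- Capacitance is an input, not estimated from the capacitive transient;
  series-resistance compensation is not modeled.
- The single-replicate uncertainty of the Boltzmann slope k at 10 test
  voltages is several percent even at 5% measurement noise; replicate
  averaging (or fitting group means) is recommended when k matters.
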