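# Methods

## Behavioral staging model

Staging uses the video trajectory only — never EEG or EMG — so that a
drug's direct EEG effects cannot masquerade as a change in behavioral
state.  The pipeline order is fixed: sharp-turn correction → jump
correction → smoothing → instant speed → movement/immobility
classification → despiking → sleep rule → sweep assignment.

*Sharp turns.* The signed turning angle between successive displacement
vectors is computed in (−180°, 180°]; strictly beyond ±135° the middle
point is replaced by the mean of itself and the next point, scanning
left to right on the working copy.  The comparison carries a 10⁻⁹-degree
absolute guard so a turn of exactly 135° built from rotation matrices is
never corrected through float round-off; this is far below the 1°
granularity at which the rule is ever exercised.

*Jumps.* From each accepted point the nearest (Euclidean) of the next
four points is taken as the next realistic location; bypassed points are
replaced by linear interpolation in time, preserving the frame count the
fps-based staging needs.  On clean but tightly curving paths the rule
occasionally skips a genuine point (the point two frames ahead can be
nearer); this affects well under 0.5% of frames and never changes a
speed classification in practice.

*Smoothing.* A 1-D discretized penalized least squares smoother in the
DCT basis, with the smoothing parameter chosen by generalized
cross-validation — the classic automatic smoother for equally spaced
data.  Because the DCT-II basis assumes reflective boundaries, a linear
ramp is not in the penalty null space; x and y are therefore detrended
by a least-squares line first and retrended after, so constant-velocity
paths pass through bit-exactly.

*Rules and boundaries.* All printed thresholds are strict: speed
*higher than* 0.5 cm/s ⇒ movement; immobility runs *longer than* 30 s
gain sleep labels from 30 s of run time onward; a state must *exceed*
60% of a 10-s sweep's frames to win it.  Sweeps tile the session from
t = 0 and a trailing partial sweep is dropped.  The despike rule demands
at least 10 contiguous immobility frames on each side of an isolated
movement frame.

## Detector

The detector band-passes 7–23 Hz with a 4th-order Butterworth filter
applied forward-backward (zero phase, so event boundaries are not
lagged; stop-band attenuation ≥ 40 dB an octave out), takes the
magnitude of the analytic signal, and thresholds at
`mean + k_sd · SD` of the envelope over the artifact-free samples of
the whole record.  `k_sd` defaults to 2.5, the midpoint of the 1.8–3.4
range a human operator settles on when tuning per record.  Runs above
threshold separated by less than 100 ms merge (shorter than one
spike-wave cycle, so a single sub-threshold dip cannot split one
discharge); candidate duration is measured after merging.

Because excluded sweeps may contain broadband artifacts orders of
magnitude above the EEG, the zero-phase filter rings past the 10-s sweep
edge; a 0.5-s guard margin around every excluded sweep is therefore also
excluded from the envelope statistics and from candidate formation
(`artifact_pad_s`).  Without it a single artifact sweep inflates the
envelope SD enough to blind the detector.

*Cycle counting.*  Cycles are counted as positive peaks of the
band-passed segment whose prominence exceeds half the segment's peak
envelope; a spike-wave train carries one full-scale spike per cycle, so
the count equals the number of cycles, and the waveform generator
verifies this round-trip exactly.  When called from the detector, half
the record's envelope threshold is additionally imposed as an absolute
prominence floor, so sub-threshold background oscillation inside a
candidate cannot inflate the count.  A purely scale-free prominence rule
(e.g. relative to the segment's median envelope) cannot keep noise
counts low — band-passed noise has roughly `f₀ × duration` comparable
peaks at any amplitude — which is why the absolute floor exists.

*Inclusion and review.* A candidate is kept iff duration > 400 ms OR
cycles > 3, both strict.  In automated mode every predicate-passing
candidate is accepted; a decisions file (`event_id,accept`) reproduces
the human rater round-trip, and a rater can only reject, never rescue a
predicate-failing candidate.

*State assignment and rates.* An event takes the behavioral state of
the sweep containing its onset (boundary-spanning events included);
events starting in excluded sweeps are dropped.  Rates divide accepted
counts and summed durations by artifact-free hours per state; a state
with zero artifact-free time reports missing values, not zeros, and
movement is excluded from statistics.

## Spectra

All spectra use Welch's averaged modified periodogram with Hamming
windows, 50% overlap and segment length one eighth of the 10-s analysis
window (1.25 s), reduced to 1-Hz bins (bin b covers [b−0.5, b+0.5) Hz,
centers 1..100).  The merged-SWD PSD concatenates accepted events in
time order and keeps the same 1.25-s segmentation regardless of the
merged length (clipped for shorter series), so the spectral shape is
invariant to how many events are merged; by default events from sleep,
waking immobility and mixed states are pooled (an immobility-only mode
is available).  Relative PSD divides each bin by the mouse's summed
1–30 Hz power and multiplies by 5 000, so every relative spectrum sums
to exactly 5 000 over 1–30 Hz.  Group contrasts run an
independent-samples t-test per 1-Hz bin with Benjamini–Hochberg
correction across the 30 bins at α = 0.05; for drug-versus-saline
contrasts the control rows pool both saline sessions.

## Group statistics

The omnibus test is a one-way within-subject ANOVA computed from
definitional sums of squares; the Greenhouse–Geisser ε comes from the
double-centered sample covariance of the treatment columns,
`ε = tr(S̃)² / ((k−1)·ΣS̃²)`, clipped into [1/(k−1), 1], and deflates
both degrees of freedom.  Rows with missing cells are dropped listwise
from the omnibus; paired t-tests against the first saline session use
only mice present in both columns and are BH-corrected across the drugs
of one measure × state family (the second saline session sits outside
that family; it is used only for the saline-stability gate).  All tests
are two-sided.  Zero-variance pairings are given the defined answers
t = 0, p = 1 (no difference) or p = 0 (constant nonzero shift) rather
than NaN.  Pairwise tests run only when the GG-corrected omnibus is
significant; under a simulated global null the gated procedure flags
anything in well under 5% of experiments (it is conservative, as
gatekeeping procedures are).

## Synthetic data: what it emulates, and what it does not

A session is a bout schedule (by default: one sixth exploration with
long walks, one half immobility–walk alternation, one third long
immobility, mimicking how a mouse typically settles over 3 h), from
which per-frame ground truth follows deterministically — movement frames
in movement bouts, immobility otherwise, sleep from 30 s into long
stillness.  Trajectories are a correlated random walk at 1.5–6 cm/s
inside the 9.25-cm-radius arena (wall avoidance steers ≤ 80°/frame so
that wall encounters never mimic a sharp-turn glitch) and sub-threshold
jitter (σ = 0.003 cm) when still.  Glitches: lateral single-frame spikes
calibrated at injection time to make the turn sharp at exactly one frame
(~143°), and single-frame jumps to one fixed spurious point outside the
arena.

Background EEG mixes, per state: a 1/f floor (0.05 mV), delta 1–4 Hz
(0.10 mV in sleep, 0.03–0.04 mV awake), intermittent 12–15 Hz spindles
(4/min, 0.4–1 s, 0.05 mV peak, sleep only), theta 6–9 Hz (0.03–0.04 mV;
1.5× in REM-like subsegments that replace ~15% of long sleep), and a
small broadband floor.  No reference per-state amplitudes exist for
such recordings, so these are free generator parameters: they were
chosen once, at design time, to look like a mouse cortical screw
recording *and* to respect the pipeline's stated operating conditions —
spindles stay below the detection threshold and the waking background
does not produce sustained 7–23 Hz excursions.  Rhythmic components are
synthesized with steep order-8 zero-phase filters for exactly that
reason: a gentle 4th-order delta band leaks enough power above 7 Hz to
create ambiguous ground truth.

SWD trains are a sinusoid at the fundamental (9 Hz default, constrained
to the 7–23 Hz band) carrying one Gaussian spike (FWHM = period/8) per
cycle at the slow-wave maximum, peak-normalized; the default peak
amplitude is 3× the standard deviation of the session's background
signal.  (Tying the amplitude to the *envelope* SD instead would place
events below the detector's own mean + 2.5 SD threshold — for narrowband
noise the envelope SD is only 0.655σ — so the signal-SD convention is
what makes a detectable-by-construction default.)  Events are a thinned
Poisson process per behavioral state (default 100/h in sleep, waking
immobility and mixed) with a 2-s refractory gap, never overlapping,
never inside artifact sweeps or movement frames.  Artifact sweeps (2% of
sweeps) are white-noise bursts scaled to 2.5× the 2×10⁴ mV²/Hz exclusion
rule, so the artifact ground truth is unambiguous.  A second,
attenuated-copy channel stands in for the unanalyzed hemisphere.

What the generator does **not** emulate: volume conduction and
inter-hemispheric coherence, the unilateral parieto-occipital SWD
subtype, amplitude drift and electrode degradation, variable video
frame intervals, irregular or fragmented spike-wave morphology, and
rater disagreement.  Passing tests therefore certify the *rules and
numerics* of the pipeline — boundaries, normalizations, calibration of
the statistics and detector behavior under a known signal model — not
detection performance on real recordings, where threshold choice and
rater review carry real weight.

## Problem sizes and numerical choices

The test suite exercises: 10–30-min sessions at the full 2 kHz/20 fps
rates for detection and staging; 100–200 independent seeds for rate
calibration on the generator's event layer (EEG synthesis is not needed
to audit Poisson placement); 1 000 replicate experiments at the
measure-matrix level for the type-I calibration and 100 for power, with
half an hour of state time per cell — the statistics consume per-mouse
rates, and detection fidelity is certified separately on full synthetic
EEG.  The pipeline smoke test runs 2 mice × 3 five-minute sessions end
to end, byte-identical across reruns of the same seed.

Degenerate inputs have defined behavior throughout: constant envelopes
detect nothing (with a warning), empty event sets give empty spectra,
zero state-hours give missing rates, zero-variance pairs give exact
p-values, and sub-3-frame trajectories pass through correction
unchanged.  Seeds flow from a single `numpy` Generator per session;
per-session seeds in the cohort pipeline are derived by hashing
(experiment seed, mouse, treatment), so cohorts are reproducible and
order-independent.

## Known limitations

* The detector's k_sd is global per record; the upstream workflow tunes
  it per animal by eye.  An F-score sweep against ground truth is easy
  to run on synthetic data but has no real-data analogue here.
* The jump rule's nearest-of-4 heuristic can bypass genuine points on
  tight curves (see above); the effect is cosmetic at staging scale.
* GG-corrected F at fractional degrees of freedom is reported even when
  ε clips at its lower bound, where the correction is known to be
  conservative.
* The mixed state pools five different transition types; no attempt is
  made to separate them.
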