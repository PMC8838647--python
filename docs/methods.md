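# Methods

## Scope and objects

The package scores infant sleep behaviorally: each 30-s epoch of a
recording (the pediatric scoring convention) receives one of five states
— quiet sleep (QS), active sleep (AS), quiet awake (QA), active awake
(AA), vocalization/crying (V). A `Hypnogram` is the epoch-indexed label
sequence; epochs are 0-based with half-open time intervals, a convention
chosen to avoid off-by-one ambiguity in files and tests. Three label
spaces coexist (behavioral, PSG, merged three-class) and share one
merged target space so confusion matrices across sources are
well-formed.

The observational primitives of the framework — "eyes open" and
"actually crying", judgments a human makes from video — are modeled as
1-Hz input channels (eyes tristate open/closed/unknown, cry boolean)
rather than as signal processing: they are inputs to the rule logic, not
outputs of it. Respiration, movement and the audio envelope are
waveforms with arbitrary units.

## Feature extraction

**Breath cycles.** The respiration waveform is demeaned, band-pass
filtered to 0.2–2.0 Hz (12–120 cycles/min, the infant range;
configurable) with a 4th-order zero-phase Butterworth filter, and
segmented peak-to-peak with a prominence floor of half the filtered RMS
and a 0.4-s minimum peak distance. Flat signals yield no cycles rather
than an error.

**Regularity.** Cycles whose onset falls in the epoch are extrapolated
to per-minute rates; the verdict is REGULAR when max−min < 20
cycles/min and IRREGULAR at or above. Exactly 20 is called IRREGULAR:
the criterion's defining statement leaves equality open, and the gap is
closed on the irregular side because active sleep is the more prevalent
infant sleep state. Fewer than `min_cycles = 5` usable cycles yield
UNDETERMINED, which hands the epoch to the movement fallback — the same
escalation a human annotator applies when respiration is unclear.

**Movement bursts.** A smoothed absolute-amplitude envelope is
thresholded at `baseline + 4·spread`, where baseline and spread are
estimated from the 10th/40th envelope quantiles. A low-quantile
baseline (rather than the median) keeps the estimate on the quiet floor
even when movement covers a large share of the window. Bursts closer
than 1 s merge. A burst is a *twitch* when shorter than 0.5 s and
smaller than 25% of the 95th-percentile gross-burst amplitude (when no
gross bursts exist, the duration criterion alone applies); otherwise
*gross*. These thresholds are package choices — the framework describes
twitches only qualitatively.

**Movement as noise and as signal.** Breath cycles overlapping a burst
are discarded before the regularity computation, preventing
artifact-driven irregular calls; the fraction of the epoch covered by
bursts is kept as `movement_noise_fraction`, since heavy movement noise
itself argues for an active state.

## Classification

A decided observation vector wins outright (the exact state-table
lookup above; crying ⇒ V regardless of the rest, and only ever from the
cry channel — never from audio alone, because crying and loud giggling
are acoustically similar). Eyes follow the per-second majority within
the epoch; an exact 50/50 tie inherits the previous epoch's judgment
(first epoch: the sleep side). Movement presence does not hard-exclude
the sleep rows — infants past the newborn period show gross movements
in AS and occasionally QS — so gross movement splits QA/AA and flags
unmatched vectors (e.g. eyes closed, regular respiration, gross
movement) as undecided rather than forcing a row.

Undecided epochs are scored by equal-weight movement heuristics
(twitches +1 sleep; no movement or mean inter-movement interval ≥ 30 s
+1 sleep; ≥ 4 bursts with intervals < 10 s −1; sustained gross burst
≥ 5 s −1). Sleep-leaning epochs split QS/AS on respiration, or on
`movement_noise_fraction ≥ 0.3` when respiration is unknown;
wake-leaning epochs split QA/AA on gross movement; neutral epochs carry
the previous state forward, operationalizing the rule that the current
state holds until a transition is complete. A neutral first epoch
defaults to AS, the hub state adjacent to every other under the
transition rules. The cascade is total and deterministic, and every
decision carries an audit tag (vector / movement-fallback /
carry-forward). The equal weighting of the heuristics, and all the
numeric thresholds above, are package defaults exposed in configuration;
the framework states these contrasts only qualitatively.
"Goal-directedness" of movement is deliberately not a feature — it is
unobservable from a pressure sensor — and is subsumed by the
frequency/duration heuristics.

## Context rules

`min_run_epochs = 6` encodes the 3-min rule exactly at 30-s epochs.
Smoothing absorbs sub-minimum runs shortest-first (ties: earliest),
relabelling to the *preceding* run's state — backward in time, matching
the transition-carry rule — except where that would create a forbidden
QS↔wake adjacency. Because relabelling to either neighbor creates the
same adjacency, the wake|short|QS configuration instead becomes an AS
buffer, which is padded to the minimum run length by taking epochs from
the longer neighbor; this guarantees the post-condition that no
sub-minimum non-V run survives outside the falling-asleep window.
Exempt from absorption: V runs of any length, and AA/QA/AS runs lying
wholly inside the sleep-onset window (everything before the first
sleep run of ≥ 3 min — one reading of "on falling asleep", left uncapped
since pre-sleep eye-opening periods can last ~10 min). Short QS runs
are never exempt, and mid-nap wake runs under 3 min are deliberately
absorbed (only V and falling-asleep are excepted). Smoothing is
idempotent, preserves epoch count, and introduces no state beyond the
originals plus AS.

Forbidden-transition checking is validation by default — the framework
treats QS↔wake adjacencies as annotator error to be re-annotated —
with automatic repair opt-in: the shorter offending run (ties: later)
becomes AS, iterated to a fixed point that always validates clean.

## Simulator

Semi-Markov by design: bout durations are explicit gamma draws
(CV 0.35, floored at 1 min so no bout vanishes in discretization), since
3-min rules and 50–60-min cycles are duration statements a memoryless
chain cannot honor. Defaults: AS 25 min, QS 30 min (AS+QS cycle 55 min,
the center of the 50–60 min range; AS within its stated 20–30 min), AA
4 min, QA 1 min, V 2 min, 55-min naps matching the average observed
naptime. The bout transition graph is wake ↔ AS ↔ QS with V reachable
only via AA, so sampled truths cannot violate the forbidden-transition
rule. Majority rule discretizes bouts to epochs (ties to the state at
the epoch start).

Respiration is rendered breath by breath (half-offset sine cycles
meeting at zero crossings, so the waveform is continuous at state
boundaries). Quiet states breathe at 35 ± 2 cycles/min; active states
alternate short runs of 2–4 breaths between an 18–24 and a 52–60
cycles/min band — a periodic-breathing-like pattern that guarantees the
detected rate range trips the 20 cycles/min criterion within every
epoch (single-breath alternation would not: peak-to-peak intervals
average adjacent breath durations and compress the detected range) —
plus apneic pauses of 3–8 s at 0.5/min. Movement bursts are Poisson per
state (QS 0.1 gross + 0.1 twitch /min, AS 1.0 + 1.5, AA 4 sustained
gross of 5–8 s, QA 0.2, V 3), coupled into the respiration channel at
gain 0.4 as movement noise. Eyes are open per second with probability
0.95 awake / ≤ 0.03 asleep, masked to unknown at 0.1; crying spans
exactly the V bouts; audio is elevated during V and during 20% of AS
epochs (sleep sounds), exercising the never-audio-only rule. One root
seed spawns independent per-channel streams, so enabling one channel
never perturbs another.

Synthetic PSG partners map QS→N3, wake→Wake, and draw each AS epoch
from REM/N1/N2 (0.5/0.25/0.25) — encoding the observation that
behaviorally active sleep co-occurs with light NREM, which is exactly
why the REM⁺ merging scheme agrees with behavioral annotation far
better than the standard NREM pooling.

**What the simulator does not emulate:** real sensor artifacts
(baseline drift, ballistocardiographic content, room noise), the cyclic
clustering of AS movements, drowsy/indeterminate states, preterm sleep
architecture, overnight multi-cycle sleep with feeds, and
between-infant variability in movement style. Passing tests therefore
demonstrate internal consistency of detector, classifier, rules and
statistics under the stated conditions — not field performance on
infant recordings, whose empirical agreement values cannot be
reproduced here.

## Agreement statistics

Cohen's κ from explicit p_o/p_e marginals; the degenerate both-raters
constant-and-equal case (p_e = 1, p_o = 1) returns 1. Per-state κ is
one-vs-rest binarized — the standard construction consistent with
reporting a separate κ for single states against all others; a state
absent from both hypnograms is an error (undefined agreement), matching
the exclusion of near-empty states from per-state analyses. Per-infant
comparisons use the Wilcoxon signed-rank test (comparisons are paired
per infant; the exact null for n ≤ 12, normal approximation above,
all-zero differences ⇒ p = 1 by convention) with Bonferroni-adjusted
p capped at 1 and significance at 0.05.

## Problem sizes and numerics

The verification suite and `scripts/acceptance.py` use 200 state
sequences (4-h draws, complete bouts only — a 55-min nap censors most
QS bouts, which would bias duration statistics) for architecture
statistics, 20 full naps for detector closure and end-to-end recovery,
and 1000 random matrices for the κ oracle; channels are rendered at
10 Hz, ample for a ≤ 2 Hz breathing band. Smoothing and repair iterate
with a generous safety cap but converge in a handful of passes. V is
implemented as an exclusive state (in the validation setting crying
occurred only awake); dual-labeling V alongside sleep states is a
documented extension, as are EDF ingestion and drowsy-state scoring.
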