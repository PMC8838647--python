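"""Simulate one infant nap and look at its ground-truth structure.

The simulator draws a semi-Markov bout sequence (sleep cycles of ~50-60
min alternating active and quiet sleep) and renders state-conditional
respiration, movement, eyes, audio and cry channels on top.
"""

from collections import Counter

from infantsleep import SimConfig, runs_of, simulate_nap, validate

cfg = SimConfig(seed=42)  # 55-min nap at the default study-like conditions
sim = simulate_nap(cfg)

print(f"nap of {len(sim.truth)} epochs ({cfg.duration_min:.0f} min)")
print("epoch counts per state:", dict(Counter(l.value for l in sim.truth.labels)))
print("bout sequence:")
for run in runs_of(sim.truth):
    print(f"  {run.state.value:>2} from epoch {run.start_epoch:3d}, "
          f"{run.length_epochs * 0.5:.1f} min")
print("transition-rule violations in the truth:", len(validate(sim.truth)))
print(f"apneas simulated: {len(sim.events['apneas'])}, "
      f"movement bursts: {len(sim.events['bursts'])}")
# Each state's bout lengths follow the configured means (AS ~25 min,
# QS ~30 min, wake bouts a few minutes), and the truth never violates
# the forbidden QS<->wake transitions by construction.
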