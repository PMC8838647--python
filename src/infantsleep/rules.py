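"""Context rules for behavioral hypnograms.

Infant sleep is cyclic; states do not flip epoch to epoch.  Three rules
encode that context:

* **Minimum duration** — only changes lasting longer than 3 min (six
  30-s epochs) are accepted as a new state, with two exceptions:
  vocalization episodes of any length, and — on falling asleep — short
  AA/QA/AS runs, since infants drift between wake and active sleep
  before the first sustained sleep bout.
* **Transition carry** — the current state is kept until a transition is
  complete; absorption of short runs therefore defaults backward in time
  (to the preceding run's state).
* **Forbidden transitions** — QS cannot follow AA or QA, and AA/QA
  cannot follow QS: healthy infants past 2-3 months neither fall directly
  into quiet sleep nor wake directly out of it.  Such adjacencies are
  flagged as annotation errors; automatic repair (relabelling the shorter
  offending run to AS, the buffer state) is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core import BehavioralState, Hypnogram, StateRun, expand_runs, runs_of

_B = BehavioralState
_WAKE_QG = frozenset({_B.AA, _B.QA})
_ONSET_EXEMPT = frozenset({_B.AA, _B.QA, _B.AS})


@dataclass
class SmoothingConfig:
    """``min_run_epochs=6`` encodes the 3-min rule at 30-s epochs."""

    min_run_epochs: int = 6
    repair: bool = False


@dataclass(frozen=True)
class RuleViolation:
    """A forbidden QS<->wake adjacency; ``boundary_epoch`` indexes the
    first epoch of the offending (later) run."""

    rule_id: str
    boundary_epoch: int
    from_state: BehavioralState
    to_state: BehavioralState


def _forbidden(a: BehavioralState, b: BehavioralState) -> bool:
    return (a in _WAKE_QG and b is _B.QS) or (a is _B.QS and b in _WAKE_QG)


def find_sleep_onset(
    h: Hypnogram, min_run_epochs: int = 6
) -> Optional[int]:
    """Start epoch of the first sustained (>= 3 min) sleep run.

    Everything before it is the falling-asleep window in which short
    AA/QA/AS runs are legitimate.  ``None`` when the recording never
    contains a sustained sleep run.
    """
    for r in runs_of(h):
        if r.state in {_B.AS, _B.QS} and r.length_epochs >= min_run_epochs:
            return r.start_epoch
    return None


def validate(h: Hypnogram) -> list[RuleViolation]:
    """List forbidden QS<->wake adjacencies in epoch order."""
    if h.label_space != "behavioral":
        raise ValueError("validate expects a behavioral hypnogram")
    out = []
    runs = runs_of(h)
    for a, b in zip(runs, runs[1:]):
        if _forbidden(a.state, b.state):
            out.append(
                RuleViolation("R3", b.start_epoch, a.state, b.state)
            )
    return out


def smooth(h: Hypnogram, cfg: SmoothingConfig | None = None) -> Hypnogram:
    """Absorb sub-minimum runs, shortest first, to a fixed point.

    A short run is relabelled to the preceding run's state (backward in
    time, matching the transition-carry rule) unless that would create a
    forbidden QS<->wake adjacency — which happens exactly when the run
    separates a wake run from a QS run.  In that case the run becomes AS,
    the transition buffer, and is padded to the minimum run length by
    taking epochs from the longer neighbor so that no sub-minimum run
    survives.  V runs are exempt at any length, as are AA/QA/AS runs
    lying wholly inside the falling-asleep window.

    Idempotent; never changes the epoch count; never introduces a state
    outside the original states plus AS.
    """
    cfg = cfg or SmoothingConfig()
    if h.label_space != "behavioral":
        raise ValueError("smooth expects a behavioral hypnogram")
    labels = list(h.labels)
    min_len = cfg.min_run_epochs
    max_iter = 10 * len(labels) + 100
    for _ in range(max_iter):
        hyp = h.replace_labels(labels)
        runs = runs_of(hyp)
        onset = find_sleep_onset(hyp, min_len)
        window_end = onset if onset is not None else 0
        # candidate short runs, shortest first then earliest
        cands = []
        for k, r in enumerate(runs):
            if r.length_epochs >= min_len or r.state is _B.V:
                continue
            if r.state in _ONSET_EXEMPT and r.end_epoch <= window_end:
                continue
            if len(runs) == 1:
                continue  # a single-run hypnogram cannot be absorbed
            cands.append((r.length_epochs, r.start_epoch, k))
        if not cands:
            break
        changed = False
        for _, _, k in sorted(cands):
            r = runs[k]
            prev = runs[k - 1] if k > 0 else None
            nxt = runs[k + 1] if k + 1 < len(runs) else None
            if prev is None:
                new = nxt.state
            elif nxt is None:
                new = prev.state
            elif not _forbidden(prev.state, nxt.state):
                new = prev.state
            else:
                new = _B.AS
            if new is not r.state:
                labels[r.start_epoch : r.end_epoch] = [new] * r.length_epochs
                changed = True
                break
            # r is already the AS buffer between wake and QS: pad it to the
            # minimum length by taking epochs from the longer neighbor
            need = min_len - r.length_epochs
            lo, hi = r.start_epoch, r.end_epoch
            left_avail = prev.length_epochs - 1 if prev else 0
            right_avail = nxt.length_epochs - 1 if nxt else 0
            while need > 0 and (left_avail > 0 or right_avail > 0):
                if left_avail >= right_avail:
                    lo -= 1
                    labels[lo] = r.state
                    left_avail -= 1
                else:
                    labels[hi] = r.state
                    hi += 1
                    right_avail -= 1
                need -= 1
                changed = True
            if changed:
                break
        if not changed:
            break
    return h.replace_labels(labels)


def repair(h: Hypnogram) -> Hypnogram:
    """Resolve forbidden adjacencies by relabelling the shorter of the
    two offending runs to AS (ties: the later run).  Iterates to a fixed
    point; the result always validates clean.  Idempotent and the
    identity on legal hypnograms."""
    if h.label_space != "behavioral":
        raise ValueError("repair expects a behavioral hypnogram")
    labels = list(h.labels)
    for _ in range(10 * len(labels) + 100):
        hyp = h.replace_labels(labels)
        violations = validate(hyp)
        if not violations:
            break
        v = violations[0]
        runs = runs_of(hyp)
        later = next(r for r in runs if r.start_epoch == v.boundary_epoch)
        idx = runs.index(later)
        earlier = runs[idx - 1]
        target = earlier if earlier.length_epochs < later.length_epochs else later
        labels[target.start_epoch : target.end_epoch] = (
            [_B.AS] * target.length_epochs
        )
    return h.replace_labels(labels)
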