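"""Per-epoch behavioral state classification.

Each epoch is summarised as a four-property observation vector in the
Prechtl tradition — eyes open, respiration regular, gross movements,
vocalization — and looked up against the five state rows:

========================  ====  ====  =====  ===
state                     eyes  resp  gross  voc
========================  ====  ====  =====  ===
quiet sleep (QS)           -     +     -      -
active sleep (AS)          -     -     -      -
quiet awake (QA)           +     +     -      -
active awake (AA)          +     -     +      -
vocalization (V)           0     -     +      +
========================  ====  ====  =====  ===

(``0`` = may be absent or present.)  Crying decides V outright; it must
come from the cry channel (the video judgment), never from the audio
envelope alone, since crying and loud giggling are acoustically similar.

Infants over a couple of months old do show gross movements during sleep,
so movement presence cannot hard-exclude the sleep rows; eyes and
respiration are the discriminating properties, and gross movement splits
QA from AA.  When eyes or respiration are unknown the lookup is
undecided, and a movement-heuristic fallback takes over: twitches and
long inter-movement intervals lean sleep; frequent or sustained movement
leans wake.  A neutral fallback carries the previous epoch's state
forward (the current state is kept until a transition is complete).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .core import BehavioralState, Hypnogram
from .signals import (
    ChannelSet,
    EpochFeatures,
    RegularityCall,
    SignalConfig,
    extract_features,
)


class Presence(enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Lean(enum.Enum):
    SLEEP = "sleep-leaning"
    WAKE = "wake-leaning"
    NEUTRAL = "neutral"


@dataclass
class ClassifyConfig:
    """Thresholds of the decision cascade.

    ``cry_min_fraction`` — minimum crying fraction of an epoch to call
    vocalization.  ``sleep_interval_s`` / ``wake_burst_count`` /
    ``wake_interval_s`` / ``sustained_s`` parameterize the qualitative
    wake-sleep movement contrasts (sleep: fewer movements, longer
    intervals; wake: more and more continuous movement).
    ``active_noise_fraction`` — movement-noise coverage above which an
    ambiguous sleep epoch is called active rather than quiet.
    """

    cry_min_fraction: float = 0.2
    sleep_interval_s: float = 30.0
    wake_burst_count: int = 4
    wake_interval_s: float = 10.0
    sustained_s: float = 5.0
    active_noise_fraction: float = 0.3


@dataclass(frozen=True)
class ObservationVector:
    eyes_open: Presence
    respiration_regular: Presence
    gross_movements: bool
    vocalization: bool


@dataclass(frozen=True)
class EpochDecision:
    """Audit record: the state, how it was reached, and the evidence."""

    state: BehavioralState
    rationale: str  # "vector" | "movement-fallback" | "carry-forward"
    vector: ObservationVector


def observation_vector(
    f: EpochFeatures,
    config: ClassifyConfig | None = None,
    prev_eyes: Optional[Presence] = None,
) -> ObservationVector:
    """Reduce epoch features to the four observation properties.

    Eyes follow the per-second majority within the epoch; an exact tie
    inherits the previous epoch's judgment (sleep side, i.e. closed, when
    there is none).  An undetermined regularity verdict maps to unknown.
    """
    config = config or ClassifyConfig()
    if f.eyes_open_fraction is None:
        eyes = Presence.UNKNOWN
    elif f.eyes_open_fraction > 0.5:
        eyes = Presence.YES
    elif f.eyes_open_fraction < 0.5:
        eyes = Presence.NO
    else:
        eyes = prev_eyes if prev_eyes is not None else Presence.NO
    verdict = f.resp_regularity.verdict
    if verdict == RegularityCall.REGULAR:
        resp = Presence.YES
    elif verdict == RegularityCall.IRREGULAR:
        resp = Presence.NO
    else:
        resp = Presence.UNKNOWN
    return ObservationVector(
        eyes_open=eyes,
        respiration_regular=resp,
        gross_movements=f.gross_count >= 1,
        vocalization=f.cry_fraction >= config.cry_min_fraction,
    )


def classify_vector(v: ObservationVector) -> Optional[BehavioralState]:
    """Exact state-table lookup; ``None`` means undecided.

    Vocalization decides V regardless of the other properties.  A vector
    with unknown eyes or respiration, or one matching no row (e.g. eyes
    closed with regular respiration *and* gross movements), is undecided
    and falls through to the movement heuristics.
    """
    if v.vocalization:
        return BehavioralState.V
    if Presence.UNKNOWN in (v.eyes_open, v.respiration_regular):
        return None
    if v.eyes_open is Presence.NO:
        if v.respiration_regular is Presence.YES:
            return None if v.gross_movements else BehavioralState.QS
        return BehavioralState.AS
    # eyes open
    if v.respiration_regular is Presence.YES:
        return None if v.gross_movements else BehavioralState.QA
    return BehavioralState.AA


def movement_fallback(
    f: EpochFeatures, config: ClassifyConfig | None = None
) -> Lean:
    """Score the wake/sleep movement heuristics for an undecided epoch.

    Sleep evidence (+1 each): twitches present; no movements at all or
    long mean inter-movement interval.  Wake evidence (-1 each): many
    bursts with short intervals; sustained gross movement.
    """
    config = config or ClassifyConfig()
    score = 0
    if f.twitch_count >= 1:
        score += 1
    if f.burst_count == 0 or (
        f.mean_inter_burst_s is not None
        and f.mean_inter_burst_s >= config.sleep_interval_s
    ):
        score += 1
    if (
        f.burst_count >= config.wake_burst_count
        and f.mean_inter_burst_s is not None
        and f.mean_inter_burst_s < config.wake_interval_s
    ):
        score -= 1
    if f.gross_count >= 1 and f.max_burst_duration_s >= config.sustained_s:
        score -= 1
    if score > 0:
        return Lean.SLEEP
    if score < 0:
        return Lean.WAKE
    return Lean.NEUTRAL


def resolve_epoch(
    v: ObservationVector,
    f: EpochFeatures,
    fallback: Lean,
    prev_state: Optional[BehavioralState],
    config: ClassifyConfig | None = None,
) -> EpochDecision:
    """Total decision cascade: vector lookup, movement fallback, carry.

    A decided vector wins.  Sleep-leaning epochs split QS/AS on
    respiration, or on movement-noise coverage when respiration is
    unknown; wake-leaning epochs split QA/AA on gross movement.  Neutral
    epochs carry the previous state forward (AS when there is none: the
    hub state adjacent to every other under the transition rules).
    """
    config = config or ClassifyConfig()
    state = classify_vector(v)
    if state is not None:
        return EpochDecision(state, "vector", v)
    if fallback is Lean.SLEEP:
        if v.respiration_regular is Presence.NO:
            state = BehavioralState.AS
        elif (
            v.respiration_regular is Presence.UNKNOWN
            and f.movement_noise_fraction >= config.active_noise_fraction
        ):
            state = BehavioralState.AS
        else:
            state = BehavioralState.QS
        return EpochDecision(state, "movement-fallback", v)
    if fallback is Lean.WAKE:
        state = BehavioralState.AA if v.gross_movements else BehavioralState.QA
        return EpochDecision(state, "movement-fallback", v)
    if prev_state is not None:
        return EpochDecision(prev_state, "carry-forward", v)
    return EpochDecision(BehavioralState.AS, "carry-forward", v)


def classify_recording(
    channels: ChannelSet,
    signal_config: SignalConfig | None = None,
    classify_config: ClassifyConfig | None = None,
    epoch_length_s: float = 30.0,
) -> tuple[Hypnogram, list[EpochDecision]]:
    """Classify every 30-s epoch of a recording.

    Returns the behavioral hypnogram together with the per-epoch audit
    trail (decision rationale and observation vector).  Deterministic:
    identical channels and configuration give identical output.
    """
    feats = extract_features(channels, signal_config, epoch_length_s)
    decisions: list[EpochDecision] = []
    prev_state: Optional[BehavioralState] = None
    prev_eyes: Optional[Presence] = None
    for f in feats:
        v = observation_vector(f, classify_config, prev_eyes)
        lean = movement_fallback(f, classify_config)
        d = resolve_epoch(v, f, lean, prev_state, classify_config)
        decisions.append(d)
        prev_state = d.state
        if v.eyes_open is not Presence.UNKNOWN:
            prev_eyes = v.eyes_open
    h = Hypnogram(
        tuple(d.state for d in decisions),
        epoch_length_s=epoch_length_s,
        label_space="behavioral",
    )
    return h, decisions
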