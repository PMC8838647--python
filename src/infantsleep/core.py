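"""Domain types for behavioral infant sleep annotation.

The central object is the :class:`Hypnogram`: a time-ordered sequence of
state labels, one per fixed-length scoring epoch (30 s by default, the
pediatric scoring convention).  Three label spaces are supported:

* **behavioral** — the five Prechtl-style behavioral states: quiet sleep
  (QS), active sleep (AS), quiet awake (QA), active awake (AA) and
  vocalization/crying (V);
* **psg** — polysomnography stages Wake, REM, N1, N2, N3;
* **three-class** — the merged Wake / active-sleep / quiet-sleep space in
  which behavioral and PSG hypnograms become directly comparable.

Two merging schemes map PSG stages onto the three-class space: scheme A
pools REM with N1 and N2 ("REM+") against N3 alone ("NREM-"); scheme B is
the standard pooling of N1+N2+N3 into NREM against REM.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union


class BehavioralState(enum.Enum):
    """Five behavioral states; QS/AS are sleep, QA/AA/V count as wake."""

    QS = "QS"
    AS = "AS"
    QA = "QA"
    AA = "AA"
    V = "V"


class PsgState(enum.Enum):
    """Polysomnography stages scored by an expert."""

    WAKE = "WAKE"
    REM = "REM"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"


class ThreeClassState(enum.Enum):
    """Merged label space: wake vs active sleep vs quiet sleep."""

    WAKE3 = "WAKE3"
    ACTIVE3 = "ACTIVE3"
    QUIET3 = "QUIET3"


State = Union[BehavioralState, PsgState, ThreeClassState]

#: label_space identifier -> enum class
LABEL_SPACES = {
    "behavioral": BehavioralState,
    "psg": PsgState,
    "three-class": ThreeClassState,
}

SLEEP_STATES = frozenset({BehavioralState.QS, BehavioralState.AS})
WAKE_STATES = frozenset(
    {BehavioralState.QA, BehavioralState.AA, BehavioralState.V}
)

#: behavioral -> three-class (QA/AA/V all count as awake)
BSA_TO_THREE = {
    BehavioralState.QA: ThreeClassState.WAKE3,
    BehavioralState.AA: ThreeClassState.WAKE3,
    BehavioralState.V: ThreeClassState.WAKE3,
    BehavioralState.AS: ThreeClassState.ACTIVE3,
    BehavioralState.QS: ThreeClassState.QUIET3,
}

#: scheme A: REM+ = REM+N1+N2 vs NREM- = N3
PSG_SCHEME_A = {
    PsgState.WAKE: ThreeClassState.WAKE3,
    PsgState.REM: ThreeClassState.ACTIVE3,
    PsgState.N1: ThreeClassState.ACTIVE3,
    PsgState.N2: ThreeClassState.ACTIVE3,
    PsgState.N3: ThreeClassState.QUIET3,
}

#: scheme B: standard NREM = N1+N2+N3 vs REM
PSG_SCHEME_B = {
    PsgState.WAKE: ThreeClassState.WAKE3,
    PsgState.REM: ThreeClassState.ACTIVE3,
    PsgState.N1: ThreeClassState.QUIET3,
    PsgState.N2: ThreeClassState.QUIET3,
    PsgState.N3: ThreeClassState.QUIET3,
}

PSG_SCHEMES = {
    "A_remplus": PSG_SCHEME_A,
    "A": PSG_SCHEME_A,
    "B_standard": PSG_SCHEME_B,
    "B": PSG_SCHEME_B,
}

DEFAULT_EPOCH_LENGTH_S = 30.0


@dataclass(frozen=True)
class Hypnogram:
    """Epoch-indexed sequence of state labels.

    Epoch ``i`` covers the half-open interval
    ``[start_time_s + i*epoch_length_s, start_time_s + (i+1)*epoch_length_s)``;
    indices are 0-based.
    """

    labels: tuple
    epoch_length_s: float = DEFAULT_EPOCH_LENGTH_S
    start_time_s: float = 0.0
    label_space: str = "behavioral"

    def __post_init__(self):
        if self.label_space not in LABEL_SPACES:
            raise ValueError(f"unknown label_space {self.label_space!r}")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        cls = LABEL_SPACES[self.label_space]
        labels = tuple(
            lab if isinstance(lab, cls) else cls(lab) for lab in self.labels
        )
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def epoch_interval(self, i: int) -> tuple[float, float]:
        """Half-open time interval covered by epoch ``i``."""
        if not 0 <= i < len(self.labels):
            raise IndexError(f"epoch {i} out of range")
        t0 = self.start_time_s + i * self.epoch_length_s
        return (t0, t0 + self.epoch_length_s)

    def replace_labels(self, labels: Iterable, label_space: str | None = None) -> "Hypnogram":
        return Hypnogram(
            labels=tuple(labels),
            epoch_length_s=self.epoch_length_s,
            start_time_s=self.start_time_s,
            label_space=label_space or self.label_space,
        )


@dataclass(frozen=True)
class StateRun:
    """Maximal run of identical epoch labels within a hypnogram."""

    state: State
    start_epoch: int
    length_epochs: int

    @property
    def end_epoch(self) -> int:
        """One past the last epoch of the run."""
        return self.start_epoch + self.length_epochs


def runs_of(hypnogram: Hypnogram) -> list[StateRun]:
    """Decompose a hypnogram into maximal runs of identical labels.

    Concatenating the runs reproduces the label sequence exactly; adjacent
    runs always differ in state.
    """
    labels = hypnogram.labels
    if not labels:
        raise ValueError("hypnogram has no epochs")
    runs: list[StateRun] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append(StateRun(labels[start], start, i - start))
            start = i
    return runs


def expand_runs(
    runs: Sequence[StateRun],
    epoch_length_s: float = DEFAULT_EPOCH_LENGTH_S,
    start_time_s: float = 0.0,
    label_space: str = "behavioral",
) -> Hypnogram:
    """Inverse of :func:`runs_of`: rebuild a hypnogram from runs."""
    labels: list = []
    for r in runs:
        labels.extend([r.state] * r.length_epochs)
    return Hypnogram(tuple(labels), epoch_length_s, start_time_s, label_space)


def merge_bsa_to_three(h: Hypnogram) -> Hypnogram:
    """Merge behavioral states to wake / active-sleep / quiet-sleep.

    QA, AA and V epochs all become awake; AS maps to active sleep and QS to
    quiet sleep.  (In the validation setting, crying only occurred in awake
    infants, so V is treated as a wake state.)
    """
    if h.label_space != "behavioral":
        raise ValueError(f"expected behavioral hypnogram, got {h.label_space!r}")
    return h.replace_labels(
        (BSA_TO_THREE[lab] for lab in h.labels), label_space="three-class"
    )


def merge_psg(h: Hypnogram, scheme: str) -> Hypnogram:
    """Merge PSG stages to the three-class space.

    ``scheme='A_remplus'`` pools REM+N1+N2 into active sleep (REM+) and
    keeps N3 as quiet sleep (NREM-); ``scheme='B_standard'`` keeps REM as
    active sleep and pools N1+N2+N3 into quiet sleep (NREM).  ``'A'`` and
    ``'B'`` are accepted as shorthand.
    """
    if h.label_space != "psg":
        raise ValueError(f"expected psg hypnogram, got {h.label_space!r}")
    if scheme not in PSG_SCHEMES:
        raise ValueError(
            f"unknown PSG merging scheme {scheme!r}; expected one of "
            f"{sorted(set(PSG_SCHEMES))}"
        )
    table = PSG_SCHEMES[scheme]
    return h.replace_labels(
        (table[lab] for lab in h.labels), label_space="three-class"
    )
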