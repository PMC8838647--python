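"""Semi-Markov simulator of ground-truth infant naps.

Generates behavioral state sequences with realistic bout-duration
structure — infant sleep cycles last about 50-60 min, with AS bouts of
roughly 20-30 min alternating with QS — and renders state-conditional
channels on top:

* **respiration**: regular oscillation (~35 cycles/min with small
  per-breath jitter) in the quiet states; in the active states the
  per-breath rate alternates between a low and a high band so that the
  minute-extrapolated rate range trips the 20 cycles/min criterion, with
  occasional apneic pauses of a few seconds;
* **movement**: Poisson bursts per state (rare in QS; frequent twitches
  and gross movements in AS; sustained gross movement in AA), superposed
  on a near-zero baseline and optionally coupled into the respiration
  channel as movement noise;
* **eyes / audio / cry**: eyes open with high probability per second in
  the wake states and closed in sleep, masked to unknown at a
  configurable rate (eyes are sometimes invisible on video); crying
  exactly during V bouts; the audio envelope is elevated during V and
  during a fraction of AS epochs (sleep sounds), which exercises the rule
  that vocalization is never called from audio alone.

Bout durations are drawn explicitly (semi-Markov) rather than per-epoch:
the 3-min minimum-duration rule and 50-60 min cycles are duration
statements that a memoryless chain cannot honor.  The bout-level
transition graph excludes direct QS<->wake moves, so every sampled truth
hypnogram is valid under the forbidden-transition rule by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import BehavioralState, Hypnogram
from .signals import ChannelSet, RegularityCall

_B = BehavioralState
REGULAR_STATES = frozenset({_B.QS, _B.QA})


def _default_bout_means():
    # minutes; AS 25 and QS 30 give 55-min AS+QS cycles, the center of the
    # 50-60 min infant sleep-cycle range
    return {"AS": 25.0, "QS": 30.0, "AA": 4.0, "QA": 1.0, "V": 2.0}


def _default_transitions():
    # wake states <-> AS <-> QS; V reachable only from/to AA
    return {
        "AA": {"AS": 0.70, "QA": 0.15, "V": 0.15},
        "QA": {"AS": 0.80, "AA": 0.20},
        "AS": {"QS": 0.75, "AA": 0.20, "QA": 0.05},
        "QS": {"AS": 1.00},
        "V": {"AA": 1.00},
    }


def _default_gross_per_min():
    return {"QS": 0.1, "AS": 1.0, "AA": 4.0, "QA": 0.2, "V": 3.0}


def _default_twitch_per_min():
    return {"QS": 0.1, "AS": 1.5, "AA": 0.0, "QA": 0.2, "V": 0.0}


def _default_eyes_open_prob():
    return {"AA": 0.95, "QA": 0.95, "V": 0.7, "AS": 0.03, "QS": 0.01}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study-like conditions.

    Durations are minutes, rates cycles- or events-per-minute.  The
    respiration bands are chosen to land clearly on either side of the
    20 cycles/min regularity criterion: quiet states breathe at
    ``regular_rate_cpm`` +- ``regular_jitter_cpm``; active states
    alternate breaths between ``irregular_low_cpm`` and
    ``irregular_high_cpm`` (a periodic-breathing-like pattern) and may
    pause for ``apnea_duration_s`` seconds.
    """

    duration_min: float = 55.0  # typical naptime in the validation setting
    seed: int = 0
    epoch_length_s: float = 30.0

    bout_mean_min: dict = field(default_factory=_default_bout_means)
    bout_cv: float = 0.35
    bout_min_min: float = 1.0
    initial_weights: dict = field(
        default_factory=lambda: {"AA": 0.8, "QA": 0.2}
    )
    transition_weights: dict = field(default_factory=_default_transitions)

    sample_rate_hz: float = 10.0
    regular_rate_cpm: float = 35.0
    regular_jitter_cpm: float = 2.0
    irregular_low_cpm: tuple = (18.0, 24.0)
    irregular_high_cpm: tuple = (52.0, 60.0)
    apnea_per_min: float = 0.5
    apnea_duration_s: tuple = (3.0, 8.0)
    resp_amplitude: float = 1.0
    resp_amplitude_mod: float = 0.15
    resp_noise_sd: float = 0.02

    gross_per_min: dict = field(default_factory=_default_gross_per_min)
    twitch_per_min: dict = field(default_factory=_default_twitch_per_min)
    gross_duration_s: tuple = (1.0, 4.0)
    aa_gross_duration_s: tuple = (5.0, 8.0)  # sustained wake movement
    twitch_duration_s: tuple = (0.1, 0.4)
    gross_amplitude: tuple = (2.0, 5.0)
    twitch_amplitude: tuple = (0.2, 0.5)
    move_noise_sd: float = 0.02
    resp_move_coupling: float = 0.4

    eyes_open_prob: dict = field(default_factory=_default_eyes_open_prob)
    eyes_unknown_prob: float = 0.1
    audio_noise: float = 0.01
    audio_v_level: float = 1.0
    audio_sleep_sound_prob: float = 0.2  # per AS epoch
    audio_sleep_level: float = 0.5

    def validated(self) -> "SimConfig":
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        for s, t in self.transition_weights.items():
            for dst in t:
                a, b = _B(s), _B(dst)
                if (a is _B.QS and b in {_B.AA, _B.QA, _B.V}) or (
                    b is _B.QS and a in {_B.AA, _B.QA, _B.V}
                ):
                    raise ValueError(
                        f"transition {s}->{dst} violates the QS<->wake ban"
                    )
        for d in (self.bout_mean_min, self.gross_per_min, self.twitch_per_min):
            if any(v < 0 for v in d.values()):
                raise ValueError("rates and durations must be nonnegative")
        if not 0 <= self.eyes_unknown_prob <= 1:
            raise ValueError("eyes_unknown_prob must be in [0, 1]")
        return self


@dataclass(frozen=True)
class Bout:
    state: BehavioralState
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class SimOutput:
    channels: ChannelSet
    truth: Hypnogram
    truth_regularity: list  # per epoch: REGULAR | IRREGULAR
    events: dict  # "bouts", "bursts", "apneas", "cries"


def _weighted_choice(rng: np.random.Generator, weights: dict) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def sample_bouts(
    cfg: SimConfig, rng: np.random.Generator, duration_min: Optional[float] = None
) -> list[Bout]:
    """Draw a bout sequence covering the nap duration.

    Bout durations follow a gamma distribution with the configured mean
    and coefficient of variation, floored at ``bout_min_min`` (so no bout
    can vanish entirely in the 30-s discretization).  The final bout is
    censored at the nap end.
    """
    cfg.validated()
    dur_s = (duration_min if duration_min is not None else cfg.duration_min) * 60.0
    shape = 1.0 / cfg.bout_cv**2
    t = 0.0
    state = _weighted_choice(rng, cfg.initial_weights)
    bouts: list[Bout] = []
    while t < dur_s:
        mean_s = cfg.bout_mean_min[state] * 60.0
        d = rng.gamma(shape, mean_s / shape)
        d = max(d, cfg.bout_min_min * 60.0)
        d = min(d, dur_s - t)
        bouts.append(Bout(_B(state), t, d))
        t += d
        state = _weighted_choice(rng, cfg.transition_weights[state])
    return bouts


def _discretize(bouts: list[Bout], dur_s: float, epoch_length_s: float) -> Hypnogram:
    """Majority state per 30-s epoch."""
    n_epochs = int(dur_s // epoch_length_s)
    labels = []
    for i in range(n_epochs):
        t0, t1 = i * epoch_length_s, (i + 1) * epoch_length_s
        occ: dict = {}
        first_state = None
        for b in bouts:
            ov = min(b.end_s, t1) - max(b.start_s, t0)
            if ov > 0:
                occ[b.state] = occ.get(b.state, 0.0) + ov
                if first_state is None:
                    first_state = b.state
        top = max(occ.values())
        tied = [s for s, v in occ.items() if v == top]
        # ties break to the state occupying the epoch start
        labels.append(first_state if first_state in tied else tied[0])
    return Hypnogram(tuple(labels), epoch_length_s=epoch_length_s, label_space="behavioral")


def sample_state_sequence(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    duration_min: Optional[float] = None,
) -> Hypnogram:
    """Semi-Markov state sequence, discretized to 30-s epochs."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    dur_s = (duration_min if duration_min is not None else cfg.duration_min) * 60.0
    bouts = sample_bouts(cfg, rng, duration_min)
    return _discretize(bouts, dur_s, cfg.epoch_length_s)


def _state_at(bouts: list[Bout], t: float) -> BehavioralState:
    for b in bouts:
        if b.start_s <= t < b.end_s:
            return b.state
    return bouts[-1].state


def synth_respiration(
    bouts: list[Bout],
    dur_s: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list]:
    """Render the respiration waveform breath by breath.

    Each breath is a half-offset sine cycle whose duration follows the
    state at its onset; cycles meet at zero crossings so the waveform is
    continuous across state boundaries.  Returns the waveform and the
    list of apnea events ``(onset_s, duration_s)``.
    """
    fs = cfg.sample_rate_hz
    n = int(dur_s * fs)
    wave = np.zeros(n)
    apneas = []
    t = 0.0
    high_band = bool(rng.integers(2))
    run_left = 0
    while t < dur_s:
        state = _state_at(bouts, t)
        if state in REGULAR_STATES:
            rate = cfg.regular_rate_cpm + rng.uniform(
                -cfg.regular_jitter_cpm, cfg.regular_jitter_cpm
            )
            amp = cfg.resp_amplitude
        else:
            # irregular breathing alternates between a slow and a fast band
            # in short runs of breaths (periodic-breathing-like), so every
            # epoch exhibits the full rate range
            if run_left == 0:
                high_band = not high_band
                run_left = int(rng.integers(2, 5))
            run_left -= 1
            band = cfg.irregular_high_cpm if high_band else cfg.irregular_low_cpm
            rate = rng.uniform(*band)
            amp = cfg.resp_amplitude
            if rng.random() < cfg.apnea_per_min * (60.0 / rate) / 60.0:
                # replace this breath with an apneic pause
                d = rng.uniform(*cfg.apnea_duration_s)
                apneas.append((round(t, 3), round(d, 3)))
                t += d
                continue
        d = 60.0 / rate
        i0, i1 = int(t * fs), min(n, int((t + d) * fs))
        if i1 > i0:
            tt = np.arange(i0, i1) / fs
            mod = 1.0 + cfg.resp_amplitude_mod * np.sin(2 * np.pi * tt / 60.0)
            wave[i0:i1] = amp * mod * np.sin(2 * np.pi * (tt - t) / d)
        t += d
    wave += rng.normal(0.0, cfg.resp_noise_sd, n)
    return wave, apneas


def truth_regularity_of(truth: Hypnogram) -> list[str]:
    """Ground-truth regularity per epoch: regular in QS/QA, irregular in
    the active states."""
    return [
        RegularityCall.REGULAR if lab in REGULAR_STATES else RegularityCall.IRREGULAR
        for lab in truth.labels
    ]


def synth_movement(
    bouts: list[Bout],
    dur_s: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list]:
    """Poisson movement bursts per state on a near-zero baseline.

    Returns the waveform and the event list
    ``(onset_s, duration_s, amplitude, kind)``.  AA gross bursts use the
    longer sustained-duration range, so wake movement is continuous.
    """
    fs = cfg.sample_rate_hz
    n = int(dur_s * fs)
    wave = rng.normal(0.0, cfg.move_noise_sd, n)
    events = []
    for b in bouts:
        mins = b.duration_s / 60.0
        state = b.state.value
        for kind, per_min in (("gross", cfg.gross_per_min[state]),
                              ("twitch", cfg.twitch_per_min[state])):
            k = rng.poisson(per_min * mins)
            for _ in range(k):
                onset = b.start_s + rng.uniform(0.0, b.duration_s)
                if kind == "gross":
                    dr = (cfg.aa_gross_duration_s if b.state is _B.AA
                          else cfg.gross_duration_s)
                    d = rng.uniform(*dr)
                    amp = rng.uniform(*cfg.gross_amplitude)
                else:
                    d = rng.uniform(*cfg.twitch_duration_s)
                    amp = rng.uniform(*cfg.twitch_amplitude)
                i0, i1 = int(onset * fs), min(n, int((onset + d) * fs))
                if i1 > i0:
                    shape = np.sin(np.linspace(0, np.pi, i1 - i0)) ** 2
                    wave[i0:i1] += amp * shape
                events.append((round(onset, 3), round(d, 3), round(amp, 3), kind))
    events.sort()
    return wave, events


def synth_eyes_audio_cry(
    bouts: list[Bout],
    truth: Hypnogram,
    dur_s: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Per-second eyes/cry channels and the audio envelope.

    Crying is exactly the V bouts.  Audio is elevated during V and during
    a random fraction of AS epochs (whimpers and moans are sleep sounds,
    not vocalization): the classifier must not call V from audio alone.
    """
    fs = cfg.sample_rate_hz
    n_sec = int(dur_s)
    eyes = np.empty(n_sec, dtype=np.int8)
    cry = np.zeros(n_sec, dtype=np.int8)
    for s in range(n_sec):
        state = _state_at(bouts, float(s))
        if rng.random() < cfg.eyes_unknown_prob:
            eyes[s] = -1
        else:
            eyes[s] = 1 if rng.random() < cfg.eyes_open_prob[state.value] else 0
        if state is _B.V:
            cry[s] = 1
    n = int(dur_s * fs)
    audio = np.abs(rng.normal(0.0, cfg.audio_noise, n))
    cries = []
    for b in bouts:
        if b.state is _B.V:
            i0, i1 = int(b.start_s * fs), min(n, int(b.end_s * fs))
            audio[i0:i1] += cfg.audio_v_level
            cries.append((round(b.start_s, 3), round(b.duration_s, 3)))
    for i, lab in enumerate(truth.labels):
        if lab is _B.AS and rng.random() < cfg.audio_sleep_sound_prob:
            i0 = int(i * truth.epoch_length_s * fs)
            i1 = min(n, int((i + 1) * truth.epoch_length_s * fs))
            audio[i0:i1] += cfg.audio_sleep_level
    return eyes, audio, cry, cries


def simulate_nap(cfg: SimConfig) -> SimOutput:
    """Compose the generators into one deterministic nap.

    A single integer seed drives one root seed sequence; each channel
    draws from its own derived stream, so the channels are independently
    reproducible.
    """
    cfg.validated()
    ss = np.random.SeedSequence(cfg.seed)
    rng_seq, rng_resp, rng_move, rng_eac = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    dur_s = cfg.duration_min * 60.0
    bouts = sample_bouts(cfg, rng_seq)
    truth = _discretize(bouts, dur_s, cfg.epoch_length_s)
    resp, apneas = synth_respiration(bouts, dur_s, cfg, rng_resp)
    move, bursts = synth_movement(bouts, dur_s, cfg, rng_move)
    eyes, audio, cry, cries = synth_eyes_audio_cry(
        bouts, truth, dur_s, cfg, rng_eac
    )
    resp = resp + cfg.resp_move_coupling * move  # movement noise leaks in
    channels = ChannelSet(
        respiration=resp,
        resp_sample_rate_hz=cfg.sample_rate_hz,
        movement=move,
        move_sample_rate_hz=cfg.sample_rate_hz,
        audio_env=audio,
        audio_sample_rate_hz=cfg.sample_rate_hz,
        eyes_open=eyes,
        cry=cry,
        duration_s=dur_s,
    )
    events = {
        "bouts": [(b.state.value, round(b.start_s, 3), round(b.duration_s, 3)) for b in bouts],
        "bursts": bursts,
        "apneas": apneas,
        "cries": cries,
    }
    return SimOutput(channels, truth, truth_regularity_of(truth), events)


def movement_free(cfg: SimConfig) -> SimConfig:
    """Copy of ``cfg`` with all movement (and coupling) disabled — used to
    close the loop between the simulator's regularity ground truth and the
    detector."""
    return dataclasses.replace(
        cfg,
        gross_per_min={k: 0.0 for k in cfg.gross_per_min},
        twitch_per_min={k: 0.0 for k in cfg.twitch_per_min},
        resp_move_coupling=0.0,
        move_noise_sd=0.0,
    )


def psg_from_truth(
    truth: Hypnogram,
    rng: np.random.Generator,
    rem_weights: dict | None = None,
) -> Hypnogram:
    """Synthetic PSG partner for a behavioral truth hypnogram.

    QS maps to N3; wake states to Wake; each AS epoch draws a stage from
    REM/N1/N2 (light NREM commonly co-occurs with behaviorally active
    sleep), so merging scheme A (REM+N1+N2 pooled) agrees perfectly while
    scheme B (N1+N2 pooled into NREM) does not.
    """
    from .core import PsgState

    rem_weights = rem_weights or {"REM": 0.5, "N1": 0.25, "N2": 0.25}
    labels = []
    for lab in truth.labels:
        if lab is _B.QS:
            labels.append(PsgState.N3)
        elif lab is _B.AS:
            labels.append(PsgState(_weighted_choice(rng, rem_weights)))
        else:
            labels.append(PsgState.WAKE)
    return Hypnogram(
        tuple(labels),
        epoch_length_s=truth.epoch_length_s,
        start_time_s=truth.start_time_s,
        label_space="psg",
    )
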