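"""Waveform-to-feature extraction for behavioral sleep annotation.

Turns the raw channels of an unobtrusive crib setup (respiration from an
under-mattress pressure sensor, a body-movement waveform, an audio
envelope, and per-second eyes-open / crying indicators) into per-epoch
scalar features.

The scientifically load-bearing piece is the respiration *regularity
criterion*: within an epoch, each breath cycle's duration is extrapolated
to a per-minute rate, and respiration is called regular when the rates of
the longest and shortest cycles differ by less than 20 cycles/min, and
irregular otherwise.  Regular respiration characterises the quiet states
(QS, QA); irregular respiration with apneic pauses characterises the
active states (AS, AA).

Movement is both a nuisance and a signal: bursts corrupt the respiration
waveform (breath cycles overlapping a detected burst are discarded before
the regularity computation), but the fraction of an epoch covered by
movement noise is itself an informative feature — heavy movement noise
makes the quiet states unlikely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

EYES_OPEN = 1
EYES_CLOSED = 0
EYES_UNKNOWN = -1


@dataclass
class SignalConfig:
    """Thresholds for feature extraction.

    Parameters
    ----------
    resp_band_hz:
        Band-pass corner frequencies for the respiration waveform.  The
        default 0.2-2.0 Hz (12-120 cycles/min) covers the infant breathing
        range.
    regular_range_cpm:
        Rate-range threshold of the regularity criterion.  A range below
        this value is regular; at or above it, irregular (ties on the
        irregular side).
    min_cycles:
        Minimum breath cycles in a window for a regularity verdict; fewer
        cycles yield UNDETERMINED and hand control to the movement
        fallback heuristics.
    burst_k:
        Movement-burst threshold in robust spreads above the baseline
        median of the smoothed movement envelope.
    twitch_max_duration_s / twitch_amp_fraction:
        A burst is a twitch when it is short (<= max duration) and small
        (peak amplitude <= this fraction of the 95th-percentile gross-burst
        amplitude); otherwise gross.
    """

    resp_band_hz: tuple = (0.2, 2.0)
    regular_range_cpm: float = 20.0
    min_cycles: int = 5
    peak_min_distance_s: float = 0.4
    peak_prominence_factor: float = 0.5
    burst_smooth_s: float = 0.2
    burst_k: float = 4.0
    merge_gap_s: float = 1.0
    min_burst_duration_s: float = 0.05
    twitch_max_duration_s: float = 0.5
    twitch_amp_fraction: float = 0.25


@dataclass(frozen=True)
class BreathCycle:
    """One breath, peak-to-peak; ``rate_cpm`` extrapolates it to a minute."""

    onset_s: float
    duration_s: float

    @property
    def rate_cpm(self) -> float:
        return 60.0 / self.duration_s


@dataclass(frozen=True)
class RegularityCall:
    """Outcome of the 20 cycles/min regularity criterion on one window."""

    verdict: str  # REGULAR | IRREGULAR | UNDETERMINED
    rate_range_cpm: Optional[float]
    n_cycles: int

    REGULAR = "REGULAR"
    IRREGULAR = "IRREGULAR"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class MovementBurst:
    onset_s: float
    duration_s: float
    peak_amplitude: float
    kind: str  # "twitch" | "gross"

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class ChannelSet:
    """Synchronized multichannel recording covering ``[0, duration_s)``.

    ``eyes_open`` and ``cry`` are sampled at 1 Hz; eyes uses the tristate
    coding 1=open, 0=closed, -1=unknown (e.g. covered by a blanket).
    """

    respiration: np.ndarray
    resp_sample_rate_hz: float
    movement: np.ndarray
    move_sample_rate_hz: float
    audio_env: np.ndarray
    audio_sample_rate_hz: float
    eyes_open: np.ndarray  # int8 per second
    cry: np.ndarray  # 0/1 per second
    duration_s: float

    def __post_init__(self):
        for name in ("respiration", "movement", "audio_env"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.eyes_open = np.asarray(self.eyes_open, dtype=np.int8)
        self.cry = np.asarray(self.cry, dtype=np.int8)
        for fs_name in ("resp_sample_rate_hz", "move_sample_rate_hz", "audio_sample_rate_hz"):
            if getattr(self, fs_name) <= 0:
                raise ValueError(f"{fs_name} must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if np.any(self.audio_env < 0):
            raise ValueError("audio envelope must be nonnegative")


@dataclass(frozen=True)
class EpochFeatures:
    """Per-epoch scalar summaries feeding the state classifier."""

    resp_regularity: RegularityCall
    burst_count: int
    twitch_count: int
    gross_count: int
    mean_inter_burst_s: Optional[float]
    max_burst_duration_s: float
    movement_noise_fraction: float
    eyes_open_fraction: Optional[float]  # None when eyes unknown all epoch
    cry_fraction: float
    audio_rms: float


def detect_breath_cycles(
    respiration: np.ndarray,
    sample_rate_hz: float,
    config: SignalConfig | None = None,
) -> list[BreathCycle]:
    """Detect breath cycles peak-to-peak after band-pass filtering.

    Returns an empty list (not an error) for flat or oscillation-free
    input.  Cycle durations are positive and time-ordered by construction.
    """
    config = config or SignalConfig()
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    x = np.asarray(respiration, dtype=float)
    nyq = sample_rate_hz / 2.0
    lo, hi = config.resp_band_hz
    hi = min(hi, 0.95 * nyq)
    if x.size < int(2 * sample_rate_hz / lo):
        # shorter than two cycles of the slowest detectable breath
        return []
    if np.ptp(x) == 0:
        return []
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sample_rate_hz, output="sos")
    xf = sps.sosfiltfilt(sos, x - np.mean(x))
    rms = float(np.sqrt(np.mean(xf**2)))
    if rms == 0.0:
        return []
    peaks, _ = sps.find_peaks(
        xf,
        distance=max(1, int(config.peak_min_distance_s * sample_rate_hz)),
        prominence=config.peak_prominence_factor * rms,
    )
    if peaks.size < 2:
        return []
    t = peaks / sample_rate_hz
    return [
        BreathCycle(onset_s=float(t[i]), duration_s=float(t[i + 1] - t[i]))
        for i in range(len(t) - 1)
    ]


def regularity(
    cycles: Sequence[BreathCycle],
    window: tuple[float, float],
    config: SignalConfig | None = None,
) -> RegularityCall:
    """Apply the 20 cycles/min regularity criterion to one time window.

    Cycles whose onset lies in ``window`` are extrapolated to per-minute
    rates; the verdict is REGULAR when ``max - min`` of those rates is
    below the threshold, IRREGULAR at or above it, and UNDETERMINED when
    fewer than ``min_cycles`` cycles are available.
    """
    config = config or SignalConfig()
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError(f"empty or inverted window {window!r}")
    rates = [c.rate_cpm for c in cycles if t0 <= c.onset_s < t1]
    n = len(rates)
    if n < config.min_cycles:
        return RegularityCall(RegularityCall.UNDETERMINED, None, n)
    rng = max(rates) - min(rates)
    verdict = (
        RegularityCall.REGULAR
        if rng < config.regular_range_cpm
        else RegularityCall.IRREGULAR
    )
    return RegularityCall(verdict, rng, n)


def detect_movement_bursts(
    movement: np.ndarray,
    sample_rate_hz: float,
    config: SignalConfig | None = None,
) -> list[MovementBurst]:
    """Segment the movement waveform into bursts and classify twitch/gross.

    A burst is a maximal interval where the smoothed absolute-amplitude
    envelope exceeds ``baseline + burst_k * robust_spread``, with baseline
    and spread estimated from low quantiles of the envelope; bursts separated
    by less than ``merge_gap_s`` are merged.  The twitch amplitude cutoff
    is derived from the recording itself (a fraction of the
    95th-percentile gross-burst amplitude); when no gross bursts exist the
    duration criterion alone applies.
    """
    config = config or SignalConfig()
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    x = np.abs(np.asarray(movement, dtype=float))
    if x.size == 0:
        return []
    win = max(1, int(config.burst_smooth_s * sample_rate_hz))
    kernel = np.ones(win) / win
    env = np.convolve(x, kernel, mode="same")
    # baseline and spread from low quantiles of the envelope, so the
    # estimate stays on the quiet floor even when movement covers a large
    # share of the window
    base = float(np.quantile(env, 0.10))
    spread = (float(np.quantile(env, 0.40)) - base) / 0.6745
    thr = base + config.burst_k * spread
    above = env > thr
    if not above.any():
        return []
    # maximal runs of the boolean mask
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    intervals = [(s / sample_rate_hz, e / sample_rate_hz) for s, e in zip(starts, ends)]
    # merge bursts separated by short gaps
    merged: list[list[float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < config.merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    raw = np.asarray(movement, dtype=float)
    bursts: list[tuple[float, float, float]] = []
    for s, e in merged:
        if e - s < config.min_burst_duration_s:
            continue
        i0, i1 = int(s * sample_rate_hz), max(int(s * sample_rate_hz) + 1, int(e * sample_rate_hz))
        peak = float(np.max(np.abs(raw[i0:i1])))
        bursts.append((s, e - s, peak))
    if not bursts:
        return []
    gross_peaks = [p for (_, d_, p) in bursts if d_ > config.twitch_max_duration_s]
    if gross_peaks:
        amp_cut = config.twitch_amp_fraction * float(np.percentile(gross_peaks, 95))
    else:
        amp_cut = math.inf
    out = []
    for s, d_, p in bursts:
        kind = "twitch" if (d_ <= config.twitch_max_duration_s and p <= amp_cut) else "gross"
        out.append(MovementBurst(s, d_, p, kind))
    return out


def movement_noise_fraction(
    bursts: Sequence[MovementBurst], window: tuple[float, float]
) -> float:
    """Fraction of ``window`` covered by the union of burst intervals."""
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError(f"empty or inverted window {window!r}")
    segs = sorted(
        (max(b.onset_s, t0), min(b.end_s, t1))
        for b in bursts
        if b.end_s > t0 and b.onset_s < t1
    )
    covered = 0.0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return min(1.0, covered / (t1 - t0))


def _cycles_outside_bursts(
    cycles: Sequence[BreathCycle], bursts: Sequence[MovementBurst]
) -> list[BreathCycle]:
    """Discard breath cycles that overlap any movement burst.

    Movement is noise in the respiration signal; cycles measured during a
    burst would otherwise produce artifact-driven irregular calls.
    """
    if not bursts:
        return list(cycles)
    ivs = [(b.onset_s, b.end_s) for b in bursts]
    out = []
    for c in cycles:
        c0, c1 = c.onset_s, c.onset_s + c.duration_s
        if not any(c1 > s and c0 < e for s, e in ivs):
            out.append(c)
    return out


def _eyes_cry_epoch(
    channels: ChannelSet, t0: float, t1: float
) -> tuple[Optional[float], float]:
    s0, s1 = int(t0), int(min(t1, channels.duration_s))
    eyes = channels.eyes_open[s0:s1]
    cry = channels.cry[s0:s1]
    known = eyes != EYES_UNKNOWN
    if known.any():
        eyes_frac = float(np.mean(eyes[known] == EYES_OPEN))
    else:
        eyes_frac = None
    cry_frac = float(np.mean(cry == 1)) if cry.size else 0.0
    return eyes_frac, cry_frac


def extract_features(
    channels: ChannelSet,
    config: SignalConfig | None = None,
    epoch_length_s: float = 30.0,
) -> list[EpochFeatures]:
    """Compute :class:`EpochFeatures` for every complete epoch.

    Waveform-level detection (breath cycles, movement bursts) runs once on
    the full recording; per-epoch features are then windowed summaries.
    """
    config = config or SignalConfig()
    n_epochs = int(channels.duration_s // epoch_length_s)
    if n_epochs < 1:
        raise ValueError(
            f"recording of {channels.duration_s} s is shorter than one "
            f"{epoch_length_s}-s epoch"
        )
    cycles = detect_breath_cycles(
        channels.respiration, channels.resp_sample_rate_hz, config
    )
    bursts = detect_movement_bursts(
        channels.movement, channels.move_sample_rate_hz, config
    )
    clean_cycles = _cycles_outside_bursts(cycles, bursts)
    onsets = np.array([b.onset_s for b in bursts])

    feats = []
    for i in range(n_epochs):
        t0 = i * epoch_length_s
        t1 = t0 + epoch_length_s
        reg = regularity(clean_cycles, (t0, t1), config)
        in_epoch = [b for b in bursts if t0 <= b.onset_s < t1]
        twitch = sum(1 for b in in_epoch if b.kind == "twitch")
        gross = len(in_epoch) - twitch
        max_dur = max((b.duration_s for b in in_epoch), default=0.0)
        # inter-burst intervals: gaps between consecutive onsets, including
        # the gap back to the last burst before the epoch (context matters
        # for the wake/sleep frequency heuristic)
        ep_onsets = [b.onset_s for b in in_epoch]
        prev = onsets[onsets < t0]
        seq = ([float(prev[-1])] if prev.size else []) + ep_onsets
        gaps = np.diff(seq)
        mean_ibi = float(np.mean(gaps)) if gaps.size else None
        noise = movement_noise_fraction(bursts, (t0, t1))
        eyes_frac, cry_frac = _eyes_cry_epoch(channels, t0, t1)
        a0 = int(t0 * channels.audio_sample_rate_hz)
        a1 = int(t1 * channels.audio_sample_rate_hz)
        aud = channels.audio_env[a0:a1]
        audio_rms = float(np.sqrt(np.mean(aud**2))) if aud.size else 0.0
        feats.append(
            EpochFeatures(
                resp_regularity=reg,
                burst_count=len(in_epoch),
                twitch_count=twitch,
                gross_count=gross,
                mean_inter_burst_s=mean_ibi,
                max_burst_duration_s=max_dur,
                movement_noise_fraction=noise,
                eyes_open_fraction=eyes_frac,
                cry_fraction=cry_frac,
                audio_rms=audio_rms,
            )
        )
    return feats


def epoch_features(
    channels: ChannelSet,
    epoch_index: int,
    epoch_length_s: float = 30.0,
    config: SignalConfig | None = None,
) -> EpochFeatures:
    """Features of a single epoch (convenience wrapper over
    :func:`extract_features`)."""
    feats = extract_features(channels, config, epoch_length_s)
    if not 0 <= epoch_index < len(feats):
        raise ValueError(
            f"epoch {epoch_index} outside recording ({len(feats)} epochs)"
        )
    return feats[epoch_index]
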