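"""CSV readers and writers.

Hypnogram CSV: header ``epoch,start_s,state``, one row per epoch, epochs
contiguous from 0, state tokens from exactly one label space.

Channel CSV: header ``t_s,resp,move,audio_env,eyes,cry``, rows at the
respiration sample rate; ``eyes`` is 0/1/NA (NA = invisible), ``cry`` is
0/1, both forward-held between their 1-Hz updates.  Waveform columns must
be dense (no NA).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, LABEL_SPACES
from .signals import ChannelSet, EpochFeatures

HYPNOGRAM_COLUMNS = ["epoch", "start_s", "state"]
CHANNEL_COLUMNS = ["t_s", "resp", "move", "audio_env", "eyes", "cry"]


def write_hypnogram(h: Hypnogram, path) -> None:
    df = pd.DataFrame(
        {
            "epoch": np.arange(len(h)),
            "start_s": h.start_time_s + np.arange(len(h)) * h.epoch_length_s,
            "state": [lab.value for lab in h.labels],
        }
    )
    df.to_csv(path, index=False)


def _infer_space(tokens: set[str]) -> str:
    for name, cls in LABEL_SPACES.items():
        if tokens <= {s.value for s in cls}:
            return name
    raise ValueError(f"state tokens {sorted(tokens)} match no label space")


def read_hypnogram(path, label_space: str | None = None) -> Hypnogram:
    df = pd.read_csv(path)
    if list(df.columns) != HYPNOGRAM_COLUMNS:
        raise ValueError(
            f"expected header {','.join(HYPNOGRAM_COLUMNS)}, got "
            f"{','.join(df.columns)}"
        )
    if len(df) == 0:
        raise ValueError("hypnogram file has no epochs")
    epochs = df["epoch"].to_numpy()
    if not np.array_equal(epochs, np.arange(len(df))):
        gap = int(np.flatnonzero(epochs != np.arange(len(df)))[0])
        raise ValueError(f"epoch indices not contiguous from 0 (row {gap})")
    tokens = df["state"].astype(str).tolist()
    space = label_space or _infer_space(set(tokens))
    valid = {s.value for s in LABEL_SPACES[space]}
    for i, tok in enumerate(tokens):
        if tok not in valid:
            raise ValueError(
                f"row {i}: unknown state token {tok!r} for label space "
                f"{space!r}"
            )
    starts = df["start_s"].to_numpy(dtype=float)
    epoch_len = float(starts[1] - starts[0]) if len(df) > 1 else 30.0
    return Hypnogram(
        tuple(tokens),
        epoch_length_s=epoch_len,
        start_time_s=float(starts[0]),
        label_space=space,
    )


def write_channels(cs: ChannelSet, path) -> None:
    fs = cs.resp_sample_rate_hz
    n = len(cs.respiration)
    t = np.arange(n) / fs
    sec = np.minimum(t.astype(int), len(cs.eyes_open) - 1)
    eyes = cs.eyes_open[sec].astype(object)
    eyes_col = np.where(eyes == -1, "NA", eyes)
    # movement/audio resampled onto the respiration clock by sample-and-hold
    mi = np.minimum((t * cs.move_sample_rate_hz).astype(int), len(cs.movement) - 1)
    ai = np.minimum((t * cs.audio_sample_rate_hz).astype(int), len(cs.audio_env) - 1)
    df = pd.DataFrame(
        {
            "t_s": np.round(t, 6),
            "resp": cs.respiration,
            "move": cs.movement[mi],
            "audio_env": cs.audio_env[ai],
            "eyes": eyes_col,
            "cry": cs.cry[sec],
        }
    )
    df.to_csv(path, index=False)


def read_channels(path) -> ChannelSet:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing = [c for c in CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"channel file missing column(s) {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    for col in ("resp", "move", "audio_env"):
        if df[col].isna().any():
            row = int(df[col].isna().idxmax())
            raise ValueError(f"waveform column {col!r} has NA at row {row}")
    fs = 1.0 / float(np.median(np.diff(t)))
    duration = float(t[-1] + 1.0 / fs)
    n_sec = int(duration)
    sec_idx = np.minimum((np.arange(n_sec) * fs).astype(int), len(t) - 1)
    eyes_raw = df["eyes"].to_numpy(dtype=float)[sec_idx]
    eyes = np.where(np.isnan(eyes_raw), -1, eyes_raw).astype(np.int8)
    cry = df["cry"].to_numpy(dtype=float)[sec_idx].astype(np.int8)
    return ChannelSet(
        respiration=df["resp"].to_numpy(dtype=float),
        resp_sample_rate_hz=fs,
        movement=df["move"].to_numpy(dtype=float),
        move_sample_rate_hz=fs,
        audio_env=df["audio_env"].to_numpy(dtype=float),
        audio_sample_rate_hz=fs,
        eyes_open=eyes,
        cry=cry,
        duration_s=duration,
    )


def features_frame(feats: list[EpochFeatures]) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(feats):
        rows.append(
            {
                "epoch": i,
                "resp_verdict": f.resp_regularity.verdict,
                "resp_rate_range_cpm": f.resp_regularity.rate_range_cpm,
                "resp_n_cycles": f.resp_regularity.n_cycles,
                "burst_count": f.burst_count,
                "twitch_count": f.twitch_count,
                "gross_count": f.gross_count,
                "mean_inter_burst_s": f.mean_inter_burst_s,
                "max_burst_duration_s": f.max_burst_duration_s,
                "movement_noise_fraction": f.movement_noise_fraction,
                "eyes_open_fraction": f.eyes_open_fraction,
                "cry_fraction": f.cry_fraction,
                "audio_rms": f.audio_rms,
            }
        )
    return pd.DataFrame(rows)


def write_features(feats: list[EpochFeatures], path) -> None:
    features_frame(feats).to_csv(path, index=False)


def write_audit(decisions, path) -> None:
    """Audit CSV: epoch,state,rationale,eyes,resp,gross,voc."""
    rows = [
        {
            "epoch": i,
            "state": d.state.value,
            "rationale": d.rationale,
            "eyes": d.vector.eyes_open.value,
            "resp": d.vector.respiration_regular.value,
            "gross": int(d.vector.gross_movements),
            "voc": int(d.vector.vocalization),
        }
        for i, d in enumerate(decisions)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
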