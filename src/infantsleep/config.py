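"""Pipeline configuration: one structured object, YAML round-trippable.

Every tunable threshold of the signal, classification, smoothing and
simulation stages lives here with a documented default;
:func:`write_reference_config` emits a commented reference file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .classify import ClassifyConfig
from .rules import SmoothingConfig
from .signals import SignalConfig
from .simulate import SimConfig


@dataclass
class PipelineConfig:
    epoch_length_s: float = 30.0
    seed: int = 0
    signals: SignalConfig = field(default_factory=SignalConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    simulate: SimConfig = field(default_factory=SimConfig)


_SECTIONS = {
    "signals": SignalConfig,
    "classify": ClassifyConfig,
    "smoothing": SmoothingConfig,
    "simulate": SimConfig,
}


def _plain(obj):
    """dataclass -> plain YAML-friendly types (tuples become lists)."""
    if dataclasses.is_dataclass(obj):
        return {f.name: _plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    return obj


def _rebuild(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        kwargs[f.name] = data[f.name]
    obj = cls(**kwargs)
    # restore tuple-typed fields that YAML turned into lists
    for f in fields(cls):
        v = getattr(obj, f.name)
        if isinstance(v, list):
            setattr(obj, f.name, tuple(v))
    return obj


def to_dict(cfg: PipelineConfig) -> dict:
    return _plain(cfg)


def from_dict(data: dict) -> PipelineConfig:
    kwargs = {}
    for key in ("epoch_length_s", "seed"):
        if key in data:
            kwargs[key] = data[key]
    for key, cls in _SECTIONS.items():
        if key in data:
            kwargs[key] = _rebuild(cls, data[key])
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=False))


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return from_dict(data)


_REFERENCE_HEADER = """\
# infantsleep pipeline configuration (all values shown are the defaults)
#
# epoch_length_s   scoring epoch length in seconds (pediatric convention: 30)
# seed             global random seed for the simulator
#
# signals:         feature extraction
#   resp_band_hz            respiration band-pass corners (Hz)
#   regular_range_cpm       regularity criterion: rate range threshold
#                           (cycles/min); >= threshold is irregular
#   min_cycles              min breath cycles per epoch for a verdict
#   burst_k                 movement threshold in robust spreads above median
#   merge_gap_s             bursts closer than this merge into one
#   twitch_max_duration_s   max duration of a twitch
#   twitch_amp_fraction     twitch amplitude cutoff as a fraction of the
#                           95th-percentile gross-burst amplitude
#
# classify:        decision cascade thresholds
#   cry_min_fraction        min crying fraction of an epoch for V
#   sleep_interval_s        inter-movement interval that leans sleep
#   wake_burst_count /      movement frequency that leans wake
#     wake_interval_s
#   sustained_s             gross-burst duration that leans wake
#   active_noise_fraction   movement-noise coverage calling active sleep
#
# smoothing:       context rules
#   min_run_epochs          minimum accepted run (6 epochs = 3 min)
#   repair                  auto-repair forbidden QS<->wake adjacencies
#
# simulate:        semi-Markov nap generator (durations in minutes,
#                  rates per minute); see module docs for each field
"""


def write_reference_config(path) -> None:
    """Write a commented reference configuration with all defaults."""
    body = yaml.safe_dump(to_dict(PipelineConfig()), sort_keys=False)
    Path(path).write_text(_REFERENCE_HEADER + body)
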