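"""End-to-end pipeline: simulate/load -> features -> classify -> smooth
-> validate -> compare against truth, with a JSON report."""

from __future__ import annotations

import logging
import math
from pathlib import Path

from . import io as isio
from .agreement import agreement_report
from .classify import classify_recording
from .config import PipelineConfig
from .core import merge_bsa_to_three
from .rules import repair as repair_h, smooth, validate
from .signals import extract_features
from .simulate import simulate_nap

log = logging.getLogger("infantsleep")


def _report_kappa(report) -> dict:
    return {
        "kappa_overall": report.kappa_overall,
        "observed_agreement": report.observed_agreement,
        "kappa_per_state": {
            lab.value: (None if math.isnan(k) else k)
            for lab, k in report.kappa_per_state.items()
        },
        "confusion": report.matrix.counts.tolist(),
        "labels": [lab.value for lab in report.matrix.labels],
        "n_epochs": report.matrix.n,
    }


def run_pipeline(
    cfg: PipelineConfig,
    outdir,
    channels_path=None,
    seed: int | None = None,
) -> dict:
    """Run the full pipeline and write artifacts under ``outdir``.

    Without ``channels_path`` a nap is simulated first (so the report can
    compare the smoothed classification against ground truth); with it,
    the recorded channels are classified instead.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg.simulate.seed = seed
    truth = None
    if channels_path is None:
        log.info("simulating nap: %.1f min, seed %d",
                 cfg.simulate.duration_min, cfg.simulate.seed)
        sim = simulate_nap(cfg.simulate)
        channels, truth = sim.channels, sim.truth
        isio.write_channels(channels, outdir / "channels.csv")
        isio.write_hypnogram(truth, outdir / "truth.csv")
        isio.write_report(sim.events, outdir / "events.json")
    else:
        channels = isio.read_channels(channels_path)
    feats = extract_features(channels, cfg.signals, cfg.epoch_length_s)
    log.info("extracted features for %d epochs", len(feats))
    isio.write_features(feats, outdir / "features.csv")
    raw, audit = classify_recording(
        channels, cfg.signals, cfg.classify, cfg.epoch_length_s
    )
    n_fallback = sum(1 for d in audit if d.rationale != "vector")
    log.info("classified %d epochs (%d via fallback/carry)", len(raw), n_fallback)
    isio.write_hypnogram(raw, outdir / "hypnogram_raw.csv")
    isio.write_audit(audit, outdir / "audit.csv")
    smoothed = smooth(raw, cfg.smoothing)
    changed = sum(1 for a, b in zip(raw.labels, smoothed.labels) if a != b)
    log.info("smoothing relabeled %d epochs", changed)
    if cfg.smoothing.repair:
        smoothed = repair_h(smoothed)
    isio.write_hypnogram(smoothed, outdir / "hypnogram.csv")
    violations = validate(smoothed)
    report: dict = {
        "n_epochs": len(smoothed),
        "epochs_changed_by_smoothing": changed,
        "fallback_epochs": n_fallback,
        "violations": [
            {
                "rule": v.rule_id,
                "epoch": v.boundary_epoch,
                "from": v.from_state.value,
                "to": v.to_state.value,
            }
            for v in violations
        ],
    }
    if truth is not None:
        rep3 = agreement_report(merge_bsa_to_three(smoothed), merge_bsa_to_three(truth))
        report["vs_truth_three_class"] = _report_kappa(rep3)
        log.info("three-class kappa vs truth: %.3f", rep3.kappa_overall)
    isio.write_report(report, outdir / "report.json")
    return report
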