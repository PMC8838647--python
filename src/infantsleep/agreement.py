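"""Agreement statistics between hypnograms.

Chance-corrected agreement uses Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

with observed agreement ``p_o = trace / n`` and chance agreement
``p_e = sum_k (row_k / n)(col_k / n)`` from the confusion-matrix
marginals.  Per-state agreement binarizes both hypnograms one-vs-rest and
reports the 2x2 kappa.  Across subjects, per-subject kappas under two
conditions are compared with the Wilcoxon signed-rank test (pairing is
per infant) with Bonferroni correction for multiple comparisons and a
0.05 significance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import (
    Hypnogram,
    LABEL_SPACES,
    ThreeClassState,
    merge_bsa_to_three,
    merge_psg,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    labels: tuple
    counts: np.ndarray  # square, nonnegative ints
    n: int


@dataclass(frozen=True)
class AgreementReport:
    kappa_overall: float
    kappa_per_state: dict
    observed_agreement: float
    matrix: ConfusionMatrix


@dataclass(frozen=True)
class SubjectKappas:
    values: tuple
    mean: float
    sd: float


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


def confusion(h1: Hypnogram, h2: Hypnogram) -> ConfusionMatrix:
    """Epoch-by-epoch confusion matrix over the full label space."""
    if h1.label_space != h2.label_space:
        raise ValueError(
            f"label spaces differ: {h1.label_space!r} vs {h2.label_space!r}"
        )
    if len(h1) != len(h2):
        raise ValueError(f"epoch counts differ: {len(h1)} vs {len(h2)}")
    if h1.epoch_length_s != h2.epoch_length_s:
        raise ValueError("epoch lengths differ")
    if len(h1) == 0:
        raise ValueError("empty hypnograms")
    labels = tuple(LABEL_SPACES[h1.label_space])
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, b in zip(h1.labels, h2.labels):
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(labels, counts, int(counts.sum()))


def cohens_kappa(m: ConfusionMatrix | np.ndarray) -> float:
    """Cohen's kappa from a square confusion matrix.

    When both raters are constant and identical (chance agreement 1 with
    perfect observed agreement) the statistic is taken as 1.
    """
    counts = m.counts if isinstance(m, ConfusionMatrix) else np.asarray(m, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / n
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    p_e = float(np.dot(row, col))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _binarize_counts(h1: Hypnogram, h2: Hypnogram, state) -> np.ndarray:
    c = np.zeros((2, 2), dtype=np.int64)
    for a, b in zip(h1.labels, h2.labels):
        c[0 if a == state else 1, 0 if b == state else 1] += 1
    return c


def per_state_kappa(h1: Hypnogram, h2: Hypnogram, state) -> float:
    """One-vs-rest kappa for a single state.

    Undefined (an error) when the state occurs in neither hypnogram —
    mirroring the exclusion of states with too few epochs from per-state
    analyses.
    """
    if h1.label_space != h2.label_space or len(h1) != len(h2):
        raise ValueError("hypnograms must share label space and length")
    cls = LABEL_SPACES[h1.label_space]
    state = state if isinstance(state, cls) else cls(state)
    if state not in h1.labels and state not in h2.labels:
        raise ValueError(
            f"state {state.value} absent from both hypnograms; per-state "
            "agreement is undefined"
        )
    return cohens_kappa(_binarize_counts(h1, h2, state))


def agreement_report(h1: Hypnogram, h2: Hypnogram) -> AgreementReport:
    """Overall and per-state agreement between two hypnograms."""
    m = confusion(h1, h2)
    per_state = {}
    for lab in m.labels:
        try:
            per_state[lab] = per_state_kappa(h1, h2, lab)
        except ValueError:
            per_state[lab] = math.nan
    return AgreementReport(
        kappa_overall=cohens_kappa(m),
        kappa_per_state=per_state,
        observed_agreement=float(np.trace(m.counts) / m.n),
        matrix=m,
    )


def per_subject_kappas(pairs: Sequence[tuple[Hypnogram, Hypnogram]]) -> SubjectKappas:
    """Kappa per subject pair with the mean +- sd summary."""
    if not pairs:
        raise ValueError("no subject pairs")
    vals = tuple(cohens_kappa(confusion(a, b)) for a, b in pairs)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return SubjectKappas(vals, mean, sd)


def paired_compare(
    kappas_a: Sequence[float],
    kappas_b: Sequence[float],
    n_comparisons: int = 1,
) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired per-subject kappas.

    The exact null distribution is used for n <= 12 paired differences,
    the normal approximation above.  Bonferroni: adjusted
    p = min(1, raw p * n_comparisons); significance at adjusted p < 0.05.
    All-zero differences are a no-difference result with p = 1.
    """
    a = np.asarray(kappas_a, dtype=float)
    b = np.asarray(kappas_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length paired lists of length >= 2")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    diffs = a - b
    if np.all(diffs == 0):
        return PairedTestResult(0.0, 1.0, 1.0, False)
    method = "exact" if a.size <= 12 else "approx"
    try:
        res = stats.wilcoxon(a, b, method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, method="approx")
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return PairedTestResult(
        float(res.statistic), float(res.pvalue), p_adj, p_adj < 0.05
    )


def compare_bsa_psg(bsa: Hypnogram, psg: Hypnogram) -> dict:
    """Compare a behavioral and a PSG hypnogram under both merging
    schemes.

    Both are merged to the three-class space — behavioral QA/AA/V to
    wake; PSG under scheme A (REM+ vs NREM-) and scheme B (REM vs
    NREM) — and an :class:`AgreementReport` is returned per scheme.
    """
    if len(bsa) != len(psg):
        raise ValueError(f"epoch counts differ: {len(bsa)} vs {len(psg)}")
    if len(bsa) == 0:
        raise ValueError("empty hypnograms")
    b3 = merge_bsa_to_three(bsa)
    return {
        "A_remplus": agreement_report(b3, merge_psg(psg, "A_remplus")),
        "B_standard": agreement_report(b3, merge_psg(psg, "B_standard")),
    }
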