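import itertools
import math

import numpy as np
import pytest

from infantsleep.agreement import (
    ConfusionMatrix,
    agreement_report,
    cohens_kappa,
    compare_bsa_psg,
    confusion,
    paired_compare,
    per_state_kappa,
    per_subject_kappas,
)
from infantsleep.core import BehavioralState, Hypnogram, PsgState

from conftest import beh

B = BehavioralState


def kappa_oracle(counts):
    """Brute-force p_o/p_e arithmetic, independent of the implementation."""
    counts = [[float(c) for c in row] for row in counts]
    n = sum(sum(row) for row in counts)
    p_o = sum(counts[i][i] for i in range(len(counts))) / n
    p_e = 0.0
    for k in range(len(counts)):
        row_k = sum(counts[k]) / n
        col_k = sum(counts[i][k] for i in range(len(counts))) / n
        p_e += row_k * col_k
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


class TestConfusion:
    def test_identical_is_diagonal(self):
        h = beh("AS", "QS", "AS", "AA")
        m = confusion(h, h)
        assert np.trace(m.counts) == m.n == 4

    def test_swapped_is_off_diagonal(self):
        m = confusion(beh("AS", "QS"), beh("QS", "AS"))
        assert np.trace(m.counts) == 0
        assert m.n == 2

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            confusion(beh(("AS", 10)), beh(("AS", 11)))

    def test_mismatched_spaces_rejected(self):
        psg = Hypnogram((PsgState.WAKE,), label_space="psg")
        with pytest.raises(ValueError):
            confusion(beh("AS"), psg)


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(np.array([[5, 0], [0, 5]])) == 1.0

    def test_chance_agreement_is_zero(self):
        assert cohens_kappa(np.array([[1, 1], [1, 1]])) == 0.0

    def test_hand_computed_value(self):
        # p_o = 35/50 = 0.7, p_e = 0.5 -> kappa = 0.4
        assert cohens_kappa(np.array([[20, 5], [10, 15]])) == pytest.approx(0.4)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(np.zeros((2, 2)))

    def test_constant_equal_raters(self):
        assert cohens_kappa(np.array([[7, 0], [0, 0]])) == 1.0

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(300):
            k = int(rng.integers(2, 7))
            m = rng.integers(0, 30, size=(k, k))
            if m.sum() == 0:
                continue
            assert cohens_kappa(m) == pytest.approx(kappa_oracle(m), abs=1e-12)

    def test_symmetric_and_permutation_invariant(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            m = rng.integers(0, 20, size=(k, k))
            if m.sum() == 0:
                continue
            assert cohens_kappa(m) == pytest.approx(cohens_kappa(m.T), abs=1e-12)
            perm = rng.permutation(k)
            assert cohens_kappa(m[np.ix_(perm, perm)]) == pytest.approx(
                cohens_kappa(m), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        # independent reference implementation on random label sequences
        sklearn = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            a = rng.integers(0, 3, size=100)
            b = rng.integers(0, 3, size=100)
            m = np.zeros((3, 3), dtype=int)
            for x, y in zip(a, b):
                m[x, y] += 1
            assert cohens_kappa(m) == pytest.approx(
                sklearn.cohen_kappa_score(a, b), abs=1e-12
            )


class TestPerStateKappa:
    def test_identical_hypnograms(self):
        h = beh("AS", "QS", "AS")
        assert per_state_kappa(h, h, B.QS) == 1.0

    def test_absent_state_rejected(self):
        h = beh("AS", "AS")
        with pytest.raises(ValueError):
            per_state_kappa(h, h, B.QA)

    def test_hand_built_binarization(self):
        # one-vs-rest table for QS: [[1,1],[0,2]] -> kappa 0.5
        h1 = beh("AS", "AS", "QS", "QS")
        h2 = beh("AS", "QS", "QS", "QS")
        expected = kappa_oracle([[1, 1], [0, 2]])
        assert per_state_kappa(h1, h2, B.QS) == pytest.approx(expected)

    def test_binary_symmetry(self):
        # in a two-state hypnogram, either state's kappa equals the overall
        h1 = beh("AS", "QS", "AS", "QS", "QS", "AS")
        h2 = beh("AS", "AS", "AS", "QS", "QS", "QS")
        overall = cohens_kappa(confusion(h1, h2))
        assert per_state_kappa(h1, h2, B.AS) == pytest.approx(overall)
        assert per_state_kappa(h1, h2, B.QS) == pytest.approx(overall)


class TestPerSubject:
    def test_identical_pairs(self):
        h = beh("AS", "QS")
        res = per_subject_kappas([(h, h)] * 3)
        assert res.values == (1.0, 1.0, 1.0)
        assert res.mean == 1.0 and res.sd == 0.0

    def test_elementwise_composition(self):
        pairs = [
            (beh("AS", "QS", "AS", "QS"), beh("AS", "QS", "QS", "QS")),
            (beh("AA", "AS"), beh("AA", "AS")),
        ]
        res = per_subject_kappas(pairs)
        for v, (a, b) in zip(res.values, pairs):
            assert v == pytest.approx(cohens_kappa(confusion(a, b)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            per_subject_kappas([])


def signed_rank_enumeration_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    mags = np.abs(d)
    order = np.argsort(mags, kind="stable")
    ranks = np.empty(len(d))
    # midranks for ties
    sorted_m = mags[order]
    i = 0
    while i < len(d):
        j = i
        while j + 1 < len(d) and sorted_m[j + 1] == sorted_m[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    observed = min(w_plus, total - w_plus)
    count = 0
    n_all = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= observed:
            count += 1
        n_all += 1
    return count / n_all


class TestPairedCompare:
    def test_identical_lists_not_significant(self):
        res = paired_compare([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert res.p_raw == 1.0 and not res.significant

    def test_bonferroni_caps_at_one(self):
        res1 = paired_compare([0.9, 0.8, 0.85, 0.95, 0.9],
                              [0.5, 0.4, 0.45, 0.55, 0.5], n_comparisons=1)
        res3 = paired_compare([0.9, 0.8, 0.85, 0.95, 0.9],
                              [0.5, 0.4, 0.45, 0.55, 0.5], n_comparisons=3)
        assert res3.p_adjusted == pytest.approx(min(1.0, res1.p_raw * 3))
        res_big = paired_compare([0.8, 0.7], [0.7, 0.8], n_comparisons=50)
        assert res_big.p_adjusted == 1.0

    def test_exact_p_matches_enumeration(self):
        a = [0.9, 0.8, 0.85, 0.95, 0.9]
        b = [0.5, 0.4, 0.45, 0.55, 0.5]
        res = paired_compare(a, b)
        expected = signed_rank_enumeration_p(np.array(a) - np.array(b))
        assert res.p_raw == pytest.approx(expected)
        assert res.statistic == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([0.1, 0.2], [0.1])


class TestCompareBsaPsg:
    def test_perfect_after_merge(self):
        bsa = beh("QA", "AS", "QS")
        psg = Hypnogram((PsgState.WAKE, PsgState.REM, PsgState.N3), label_space="psg")
        reports = compare_bsa_psg(bsa, psg)
        assert reports["A_remplus"].kappa_overall == 1.0

    def test_light_nrem_diverges_between_schemes(self):
        # behaviorally active sleep scored N1: agreement under REM+ pooling,
        # disagreement under standard NREM pooling
        bsa = beh("AS", "QS", "QA")
        psg = Hypnogram((PsgState.N1, PsgState.N3, PsgState.WAKE), label_space="psg")
        reports = compare_bsa_psg(bsa, psg)
        assert reports["A_remplus"].observed_agreement == 1.0
        assert reports["B_standard"].observed_agreement < 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_bsa_psg(
                Hypnogram((), label_space="behavioral"),
                Hypnogram((), label_space="psg"),
            )


class TestAgreementReport:
    def test_per_state_nan_for_absent_states(self):
        h = beh(("AS", 5), ("QS", 5))
        rep = agreement_report(h, h)
        assert rep.kappa_overall == 1.0
        assert math.isnan(rep.kappa_per_state[B.V])
        assert rep.kappa_per_state[B.AS] == 1.0
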