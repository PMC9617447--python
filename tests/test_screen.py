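"""Molecule classification, metrics, IFPs and threshold sweeps."""

from __future__ import annotations

import numpy as np
import pytest

from igocsvm.interactions import InteractionTriplet
from igocsvm.screen import (
    BinaryIFP,
    ConfusionCounts,
    MetricsReport,
    average_ifp,
    classify_molecule,
    compute_ifp,
    evaluate,
    ifp_tanimoto,
    optimal_threshold,
    round_table,
)

UNIVERSE = (("ASP113", 113), ("SER207", 207), ("ASN312", 312))


def triplet(itype="HBA", residue=("SER207", 207)):
    return InteractionTriplet.from_endpoints(itype, (0.0, 0.0, 0.0),
                                             (3.0, 0.0, 0.0), residue, 1)


class TestClassifyMolecule:
    def test_any_inlier_is_agonist(self):
        assert classify_molecule([False, False, True]) == "agonist"

    def test_all_outlier(self):
        assert classify_molecule([False, False]) == "non_agonist"

    def test_union_over_receptors(self):
        poses_a, poses_b = [True], [False, False]
        assert classify_molecule(poses_a + poses_b) == "agonist"

    def test_no_poses_warns(self):
        with pytest.warns(UserWarning):
            assert classify_molecule([]) == "non_agonist"


def _decision_set(n_agonists, n_antagonists, selected_agonists, selected_others):
    labels, decisions = {}, {}
    for i in range(n_agonists):
        mol = f"ag{i}"
        labels[mol] = "agonist"
        decisions[mol] = "agonist" if i < selected_agonists else "non_agonist"
    for i in range(n_antagonists):
        mol = f"an{i}"
        labels[mol] = "antagonist"
        decisions[mol] = "agonist" if i < selected_others else "non_agonist"
    return decisions, labels


class TestEvaluate:
    def test_screening_worked_example(self):
        # 19 agonists + 17 antagonists; 16 selected, 15 of them agonists
        decisions, labels = _decision_set(19, 17, 15, 1)
        counts, report = evaluate(decisions, labels)
        assert (counts.TP, counts.FP) == (15, 1)
        assert round_table(report.precision) == 0.94
        assert round_table(report.recall) == 0.79
        assert (report.n_selected, report.n_total) == (16, 36)

    def test_select_all_worked_example(self):
        decisions, labels = _decision_set(19, 17, 19, 17)
        _, report = evaluate(decisions, labels)
        assert report.recall == 1.0
        assert round_table(report.precision) == 0.53  # 19/36

    def test_nothing_selected_conventions(self):
        decisions, labels = _decision_set(5, 5, 0, 0)
        _, report = evaluate(decisions, labels)
        assert report.precision == 0.0
        assert report.recall == 0.0
        assert report.f1 == 0.0

    def test_inactive_counts_as_negative(self):
        decisions = {"a": "agonist", "b": "agonist"}
        labels = {"a": "agonist", "b": "inactive"}
        counts, _ = evaluate(decisions, labels)
        assert (counts.TP, counts.FP) == (1, 1)

    def test_unlabeled_errors_with_ids(self):
        with pytest.raises(KeyError, match="mystery"):
            evaluate({"mystery": "agonist"}, {})

    def test_permutation_invariant(self):
        decisions, labels = _decision_set(10, 8, 6, 2)
        items = list(decisions.items())
        reversed_decisions = dict(reversed(items))
        assert evaluate(decisions, labels) == evaluate(reversed_decisions, labels)

    def test_confusion_consistency_property(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n_ag, n_an = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            sa = int(rng.integers(0, n_ag + 1))
            so = int(rng.integers(0, n_an + 1))
            decisions, labels = _decision_set(n_ag, n_an, sa, so)
            counts, report = evaluate(decisions, labels)
            assert counts.TP + counts.FN == n_ag
            assert counts.FP + counts.TN == n_an
            if report.precision + report.recall > 0:
                assert report.f1 == pytest.approx(
                    2 * report.precision * report.recall
                    / (report.precision + report.recall))


class TestIfp:
    def test_single_bit(self):
        ifp = compute_ifp([triplet()], UNIVERSE)
        assert ifp.bits.sum() == 1
        assert ifp.bits[1, 0]  # SER207 x HBA

    def test_residue_outside_universe_errors(self):
        with pytest.raises(ValueError, match="outside"):
            compute_ifp([triplet(residue=("TRP999", 999))], UNIVERSE)

    def test_average_mask_boundary(self):
        present = compute_ifp([triplet()], UNIVERSE)
        absent = compute_ifp([], UNIVERSE)
        for n_present, shown in ((9, False), (10, True)):
            ifps = [present] * n_present + [absent] * (100 - n_present)
            freq, mask = average_ifp(ifps)
            assert freq[1, 0] == pytest.approx(n_present / 100)
            assert mask[1, 0] == shown

    def test_crystal_bit_always_shown(self):
        absent = compute_ifp([], UNIVERSE)
        crystal = compute_ifp([triplet("HBD", ("ASP113", 113))], UNIVERSE)
        _, mask = average_ifp([absent] * 50, crystal=crystal)
        assert mask[0, 1]

    def test_tanimoto_identical_and_disjoint(self):
        a = compute_ifp([triplet()], UNIVERSE)
        b = compute_ifp([triplet("HBD", ("ASP113", 113))], UNIVERSE)
        assert ifp_tanimoto(a, a) == 1.0
        assert ifp_tanimoto(a, b) == 0.0

    def test_tanimoto_hand_value(self):
        a = compute_ifp([triplet("HBA", ("ASP113", 113)),
                         triplet("HBD", ("SER207", 207)),
                         triplet("HYD", ("ASN312", 312))], UNIVERSE)
        b = compute_ifp([triplet("HBA", ("ASP113", 113)),
                         triplet("HBD", ("SER207", 207)),
                         triplet("ARO", ("ASN312", 312))], UNIVERSE)
        assert ifp_tanimoto(a, b) == pytest.approx(2.0 / 4.0)

    def test_both_empty_warns(self):
        empty = compute_ifp([], UNIVERSE)
        with pytest.warns(UserWarning):
            assert ifp_tanimoto(empty, empty) == 0.0

    def test_universe_mismatch_errors(self):
        a = compute_ifp([], UNIVERSE)
        b = compute_ifp([], UNIVERSE[:2])
        with pytest.raises(ValueError):
            ifp_tanimoto(a, b)


class TestOptimalThreshold:
    def test_perfect_separation_lowest_midpoint(self):
        scores = {"a1": 0.9, "a2": 0.8, "n1": 0.2, "n2": 0.1}
        labels = {"a1": "agonist", "a2": "agonist",
                  "n1": "antagonist", "n2": "antagonist"}
        t, report = optimal_threshold(scores, labels)
        assert report.f1 == 1.0
        assert t == pytest.approx(0.5)  # lowest midpoint inside the gap

    def test_noisy_planted_gap_recovered(self):
        rng = np.random.default_rng(2)
        scores, labels = {}, {}
        for i in range(30):
            scores[f"a{i}"] = 0.8 + rng.normal(0, 0.03)
            labels[f"a{i}"] = "agonist"
            scores[f"n{i}"] = 0.2 + rng.normal(0, 0.03)
            labels[f"n{i}"] = "inactive"
        t, report = optimal_threshold(scores, labels)
        assert 0.35 < t < 0.65
        assert report.f1 == 1.0

    def test_inverted_scores_select_all(self):
        scores = {"a1": 0.1, "a2": 0.2, "a3": 0.3,
                  "n1": 0.7, "n2": 0.8, "n3": 0.9}
        labels = {"a1": "agonist", "a2": "agonist", "a3": "agonist",
                  "n1": "antagonist", "n2": "antagonist", "n3": "antagonist"}
        t, report = optimal_threshold(scores, labels)
        assert t == pytest.approx(0.1)  # select-all baseline
        assert report.n_selected == 6
        assert report.recall == 1.0

    def test_degenerate_equal_scores_warns(self):
        scores = {"a": 0.5, "b": 0.5}
        labels = {"a": "agonist", "b": "antagonist"}
        with pytest.warns(UserWarning):
            t, _ = optimal_threshold(scores, labels)
        assert t == 0.5


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (0.945, 0.95), (0.944999, 0.94), (0.5278, 0.53), (0.789473, 0.79),
    ])
    def test_half_up(self, value, expected):
        assert round_table(value) == expected


class TestEnsembleMonotonicity:
    def test_union_recall_never_lower(self):
        rng = np.random.default_rng(21)
        labels = {f"m{i}": ("agonist" if i % 2 else "antagonist")
                  for i in range(20)}
        single = {m: rng.random() < 0.4 for m in labels}
        extra = {m: rng.random() < 0.3 for m in labels}
        dec_single = {m: "agonist" if single[m] else "non_agonist" for m in labels}
        dec_union = {m: "agonist" if (single[m] or extra[m]) else "non_agonist"
                     for m in labels}
        _, rep_single = evaluate(dec_single, labels)
        _, rep_union = evaluate(dec_union, labels)
        assert rep_union.recall >= rep_single.recall
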