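import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sspbench.metrics import (SSAnnotation, SSPair, compare_groups,
                              evaluate_set, map_8to3, pearson_correlation,
                              q_accuracy, read_pairs_tsv, sov, weighted_sov)
from sspbench.synth import gen_ss_pair

from conftest import sov_brute_force


def pair3(obs, pred, pid="p"):
    return SSPair(SSAnnotation(pid, obs, 3), SSAnnotation(pid, pred, 3))


def pair8(obs, pred, pid="p"):
    return SSPair(SSAnnotation(pid, obs, 8), SSAnnotation(pid, pred, 8))


class TestMap8to3:
    def test_all_eight_states(self):
        out = map_8to3(SSAnnotation("p", "HGIEBTSC", 8))
        assert out.states == "HHHEECCC"
        assert out.alphabet_size == 3

    def test_coil_fixed_point(self):
        assert map_8to3(SSAnnotation("p", "CCCC", 8)).states == "CCCC"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            SSAnnotation("p", "", 8)

    def test_three_state_input_rejected(self):
        with pytest.raises(ValueError):
            map_8to3(SSAnnotation("p", "HEC", 3))

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            SSAnnotation("p", "HXQ", 8)


class TestQAccuracy:
    def test_half_correct(self):
        agg, per = q_accuracy([pair3("HHHCCC", "CCCCCC")])
        assert agg == pytest.approx(0.5)
        assert per["p"] == pytest.approx(0.5)

    def test_identical_strings(self):
        agg, _ = q_accuracy([pair3("HEC" * 5, "HEC" * 5)])
        assert agg == 1.0

    def test_micro_vs_macro(self):
        # A: 80 of 100 correct, B: 0 of 10 correct
        a = pair3("H" * 100, "H" * 80 + "E" * 20, "a")
        b = pair3("H" * 10, "E" * 10, "b")
        micro, _ = q_accuracy([a, b], mode="micro")
        macro, _ = q_accuracy([a, b], mode="macro")
        assert micro == pytest.approx(80 / 110)
        assert macro == pytest.approx(0.4)

    def test_micro_recomputable_from_counts(self, rng):
        pairs = [gen_ss_pair(50 + 10 * i, 0.7, seed=i, protein_id=f"p{i}")
                 for i in range(5)]
        micro, _ = q_accuracy(pairs)
        correct = sum(sum(o == q for o, q in zip(p.observed.states,
                                                 p.predicted.states))
                      for p in pairs)
        total = sum(len(p) for p in pairs)
        assert micro == pytest.approx(correct / total, abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pair3("HH", "H")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            q_accuracy([])


class TestSov:
    def test_identical_strings_score_one(self):
        for s in ["HHHEEECCC", "H", "CECECE", "HHHH"]:
            assert sov(pair3(s, s))[0] == pytest.approx(1.0)

    def test_hand_derived_two_thirds_case(self):
        # H pair: (3+1)/6*6 = 4 over N=6; C pair: (2+1)/5*2 = 1.2 over N=2
        assert sov(pair3("HHHHHHCC", "HHHCCCCC"))[0] == pytest.approx(0.65)

    def test_hand_derived_missed_segment(self):
        # unmatched H adds 3 to N only; C pair: (3+1)/6*3 = 2; => 2/6
        assert sov(pair3("HHHCCC", "CCCCCC"))[0] == pytest.approx(1 / 3)

    def test_per_state_breakdown(self):
        _, per_state = sov(pair3("HHHHHHCC", "HHHCCCCC"))
        assert per_state["H"] == pytest.approx(4 / 6)
        assert per_state["C"] == pytest.approx(1.2 / 2)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.integers(1, 30), st.integers(0, 10_000))
    def test_agrees_with_brute_force_enumerator(self, length, seed):
        rng = np.random.default_rng(seed)
        obs = "".join(rng.choice(list("HEC"), size=length))
        pred = "".join(rng.choice(list("HEC"), size=length))
        value, _ = sov(pair3(obs, pred))
        assert value == pytest.approx(sov_brute_force(obs, pred), abs=1e-12)
        assert 0.0 <= value <= 1.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            pair3("HH", "HHH")


class TestWeightedSov:
    def test_single_protein_identity(self):
        assert weighted_sov([(120, 0.73)]) == pytest.approx(0.73)

    def test_equal_sizes_reduce_to_mean(self):
        assert weighted_sov([(50, 0.6), (50, 0.8)]) == pytest.approx(0.7)

    def test_weighted_case(self):
        assert weighted_sov([(100, 0.8), (50, 0.5)]) == pytest.approx(0.7)

    def test_errors(self):
        with pytest.raises(ValueError):
            weighted_sov([])
        with pytest.raises(ValueError):
            weighted_sov([(0, 0.5)])


class TestEvaluateSet:
    def test_perfect_predictions(self):
        pairs = [pair8("HHGGEEBTSC", "HHGGEEBTSC")]
        res = evaluate_set(pairs)
        assert res[8].aggregate_q == 1.0
        assert res[8].aggregate_sov == pytest.approx(1.0)
        assert res[3].aggregate_q == 1.0
        assert res[3].aggregate_sov == pytest.approx(1.0)

    def test_helix_subtype_error_collapses_under_mapping(self):
        pairs = [pair8("GGGGCCCC", "HHHHCCCC")]
        res = evaluate_set(pairs)
        assert res[8].aggregate_q < 1.0
        assert res[3].aggregate_q == 1.0

    def test_generator_contract_q_target(self):
        pairs = [gen_ss_pair(300, 0.8, alphabet=8, seed=s, protein_id=f"p{s}")
                 for s in range(4)]
        res = evaluate_set(pairs)
        assert res[8].aggregate_q == pytest.approx(0.8, abs=1 / 300)

    def test_coarsening_never_lowers_q(self):
        for seed in range(10):
            pairs = [gen_ss_pair(120, 0.6, alphabet=8, seed=seed)]
            res = evaluate_set(pairs)
            assert res[3].aggregate_q >= res[8].aggregate_q

    def test_three_state_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_set([pair3("HEC", "HEC")])


class TestPearson:
    def test_perfect_positive_linear(self):
        assert pearson_correlation([1, 2, 5], [3, 5, 11]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestCompareGroups:
    def test_identical_groups_give_p_one_on_student_branch(self):
        a = [0.1, 0.5, 0.9, 0.3, 0.7, 0.2, 0.8]
        res = compare_groups(a, list(a))
        assert res.branch == "student"
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_separated_normals_match_direct_t_formula(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(5.0, 1.0, 10)
        res = compare_groups(a, b)
        assert res.p_value < 1e-3
        # direct pooled-variance Student's t computation
        if res.branch == "student":
            n1, n2 = len(a), len(b)
            sp2 = (((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1))
                   / (n1 + n2 - 2))
            t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
            assert res.t_statistic == pytest.approx(t, abs=1e-12)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_unequal_variances_select_welch(self, rng):
        a = rng.normal(0.0, 0.05, 12)
        b = rng.normal(0.1, 5.0, 12)
        res = compare_groups(a, b)
        assert res.branch == "welch"
        assert res.f_test_p is not None and res.f_test_p <= 0.05

    def test_non_normal_group_falls_back_to_welch(self, rng):
        # strongly bimodal group fails Shapiro-Wilk
        a = np.concatenate([np.zeros(15) + rng.normal(0, 1e-3, 15),
                            np.ones(15) * 100 + rng.normal(0, 1e-3, 15)])
        b = rng.normal(50.0, 1.0, 30)
        res = compare_groups(a, b)
        assert min(res.shapiro_p) <= 0.05
        assert res.branch == "welch"
        assert res.f_test_p is None

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


def test_read_pairs_tsv_round_trip(tmp_path):
    p = tmp_path / "pairs.tsv"
    p.write_text("protein_id\tobserved\tpredicted\n"
                 "a\tHHEECC\tHHEECC\n"
                 "b\tHHHH\tEEEE\n")
    pairs = read_pairs_tsv(p, alphabet_size=3)
    assert [pr.protein_id for pr in pairs] == ["a", "b"]
    agg, _ = q_accuracy(pairs)
    assert agg == pytest.approx(6 / 10)
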