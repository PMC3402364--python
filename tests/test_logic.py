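"""Entropy, uncertainty coefficients, balancing, and the dU statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lapp.logic import (
    LOGIC_TYPES,
    DegenerateTargetError,
    ScenarioCounts,
    apply_logic,
    balance,
    compatibility_report,
    delta_u,
    entropy,
    scenario_counts,
    uncertainty_coefficient,
)

TOL = 1e-9


class TestEntropy:
    def test_uniform_binary_is_one_bit(self):
        assert entropy([0.5, 0.5]) == pytest.approx(1.0, abs=TOL)

    def test_degenerate_is_zero(self):
        assert entropy([1.0, 0.0]) == pytest.approx(0.0, abs=TOL)

    def test_quarter_three_quarter_closed_form(self):
        expected = -(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75))
        assert entropy([0.25, 0.75]) == pytest.approx(expected, abs=TOL)
        assert entropy([0.25, 0.75]) == pytest.approx(0.811278, abs=1e-6)

    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            entropy([-0.1, 1.1])
        with pytest.raises(ValueError):
            entropy([0.5, 0.6])


class TestUncertaintyCoefficient:
    def test_complete_dependency(self):
        joint = [[0.5, 0.0], [0.0, 0.5]]
        assert uncertainty_coefficient(joint) == pytest.approx(1.0, abs=TOL)

    def test_independence(self):
        px = np.array([0.3, 0.7])
        py = np.array([0.6, 0.4])
        assert uncertainty_coefficient(np.outer(px, py)) == pytest.approx(
            0.0, abs=TOL
        )

    def test_and_gate_under_uniform_inputs(self):
        # x = a AND b with (a, b) uniform on {0,1}^2, predictor y = a:
        # H(x) = H(1/4) = 0.811278, H(x, y) = 1.5, I = 0.311278
        joint = np.array([[0.5, 0.25], [0.0, 0.25]])
        expected = (0.8112781244591328 + 1.0 - 1.5) / 0.8112781244591328
        assert uncertainty_coefficient(joint) == pytest.approx(expected, abs=TOL)
        assert uncertainty_coefficient(joint) == pytest.approx(0.383689, abs=1e-6)

    def test_degenerate_target_raises(self):
        with pytest.raises(DegenerateTargetError):
            uncertainty_coefficient([[0.6, 0.4], [0.0, 0.0]])


class TestScenarioCounts:
    def test_enumeration_example(self):
        sc = scenario_counts((1, 1, 0, 0), (1, 0, 1, 0), (1, 0, 0, 0))
        assert sc.counts[1, 1, 1] == 1
        assert sc.counts[1, 0, 0] == 1
        assert sc.counts[0, 1, 0] == 1
        assert sc.counts[0, 0, 0] == 1
        assert sc.total == 4

    def test_all_zero_profiles(self):
        sc = scenario_counts([0] * 5, [0] * 5, [0] * 5)
        assert sc.counts[0, 0, 0] == 5
        assert sc.total == 5

    def test_matches_position_loop_oracle(self):
        rng = np.random.default_rng(11)
        a, b, c = rng.integers(0, 2, size=(3, 200))
        sc = scenario_counts(a, b, c)
        brute = np.zeros((2, 2, 2), dtype=int)
        for i, j, k in zip(a, b, c):
            brute[i, j, k] += 1
        assert (sc.counts == brute).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            scenario_counts([0, 1], [0, 1, 0], [1, 1])


class TestBalance:
    def test_cell_formula(self):
        counts = np.zeros((2, 2, 2), dtype=int)
        counts[0, 0] = [5, 5]
        counts[0, 1] = [5, 5]
        counts[1, 0] = [5, 5]
        counts[1, 1] = [10, 30]
        p = balance(ScenarioCounts(counts)).p
        assert p[1, 1, 0] == pytest.approx(0.0625, abs=TOL)  # 0.25 * 10/40
        assert p[1, 1, 1] == pytest.approx(0.1875, abs=TOL)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_cells_fixed_point(self):
        counts = np.full((2, 2, 2), 10)
        sc = ScenarioCounts(counts)
        p = balance(sc).p
        assert np.allclose(p, counts / counts.sum(), atol=TOL)

    def test_conditional_ratio_preserved(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(2, 2, 2))
        sc = ScenarioCounts(counts)
        p = balance(sc).p
        for i in range(2):
            for j in range(2):
                assert p[i, j, 0] / p[i, j, 1] == pytest.approx(
                    counts[i, j, 0] / counts[i, j, 1], rel=1e-9
                )
                assert p[i, j].sum() == pytest.approx(0.25, abs=TOL)

    def test_input_marginals_are_uniform(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 40, size=(2, 2, 2))
        p = balance(ScenarioCounts(counts)).p
        assert p.sum(axis=(1, 2)) == pytest.approx([0.5, 0.5], abs=TOL)
        assert p.sum(axis=(0, 2)) == pytest.approx([0.5, 0.5], abs=TOL)

    def test_empty_cells_share_mass_over_nonempty(self):
        counts = np.zeros((2, 2, 2), dtype=int)
        counts[0, 0] = [3, 1]
        counts[1, 1] = [2, 2]
        p = balance(ScenarioCounts(counts)).p
        assert p[0, 0].sum() == pytest.approx(0.5, abs=TOL)
        assert p[1, 1].sum() == pytest.approx(0.5, abs=TOL)
        assert p[0, 1].sum() == 0 and p[1, 0].sum() == 0

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            balance(ScenarioCounts(np.zeros((2, 2, 2), dtype=int)))

    @pytest.mark.parametrize("type_id", sorted(LOGIC_TYPES))
    def test_replication_oracle_equivalence(self, type_id):
        """Balanced dU equals raw dU on genomes replicated so that every ab
        cell reaches equal total weight (LCM construction)."""
        rng = np.random.default_rng(type_id)
        counts = rng.integers(1, 13, size=(2, 2, 2))
        sc = ScenarioCounts(counts)
        cell_totals = counts.sum(axis=2)
        lcm = np.lcm.reduce(cell_totals.ravel())
        a_rep, b_rep, c_rep = [], [], []
        for i in range(2):
            for j in range(2):
                factor = lcm // cell_totals[i, j]
                for k in range(2):
                    n = int(counts[i, j, k]) * int(factor)
                    a_rep += [i] * n
                    b_rep += [j] * n
                    c_rep += [k] * n
        replicated = scenario_counts(a_rep, b_rep, c_rep)
        t = LOGIC_TYPES[type_id]
        got = delta_u(sc, t, balanced=True)
        oracle = delta_u(replicated, t, balanced=False)
        assert got.delta_u == pytest.approx(oracle.delta_u, abs=TOL)
        assert got.u_cf == pytest.approx(oracle.u_cf, abs=TOL)
        assert got.agreement == pytest.approx(oracle.agreement, abs=TOL)


class TestApplyLogic:
    def test_and(self):
        assert apply_logic(LOGIC_TYPES[1], (1, 0, 1), (1, 1, 0)).tolist() == [1, 0, 0]

    def test_a_and_not_b_respects_order(self):
        assert apply_logic(LOGIC_TYPES[5], (1, 1, 0), (0, 1, 0)).tolist() == [1, 0, 0]
        assert apply_logic(LOGIC_TYPES[5], (0, 1, 0), (1, 1, 0)).tolist() == [0, 0, 0]

    @pytest.mark.parametrize("tid", sorted(LOGIC_TYPES))
    def test_complement_pairs_negate(self, tid):
        rng = np.random.default_rng(tid)
        a, b = rng.integers(0, 2, size=(2, 32))
        t = LOGIC_TYPES[tid]
        comp = LOGIC_TYPES[t.complement_of]
        assert (apply_logic(t, a, b) == 1 - apply_logic(comp, a, b)).all()

    def test_truth_tables(self):
        grid = [(i, j) for i in (0, 1) for j in (0, 1)]
        expected = {
            1: [i & j for i, j in grid],
            2: [1 - (i & j) for i, j in grid],
            3: [i | j for i, j in grid],
            4: [1 - (i | j) for i, j in grid],
            5: [i & (1 - j) for i, j in grid],
            6: [(1 - i) | j for i, j in grid],
            7: [i ^ j for i, j in grid],
            8: [1 - (i ^ j) for i, j in grid],
        }
        for tid, vals in expected.items():
            assert list(LOGIC_TYPES[tid].table) == vals


@st.composite
def count_tables(draw):
    flat = draw(
        st.lists(st.integers(min_value=1, max_value=60), min_size=8, max_size=8)
    )
    return ScenarioCounts(np.array(flat).reshape(2, 2, 2))


class TestDeltaU:
    def test_noiseless_and_gate_closed_form(self):
        # c = a AND b with uniform balanced ab cells: u_cf = 1,
        # u_ca = u_cb = 0.383689, dU = 0.616311
        counts = np.zeros((2, 2, 2), dtype=int)
        for i in range(2):
            for j in range(2):
                counts[i, j, i & j] = 25
        score = delta_u(ScenarioCounts(counts), LOGIC_TYPES[1], balanced=True)
        assert score.u_cf == pytest.approx(1.0, abs=TOL)
        assert score.u_ca == pytest.approx(0.383689, abs=1e-6)
        assert score.delta_u == pytest.approx(0.616311, abs=1e-6)
        assert score.agreement == pytest.approx(1.0, abs=TOL)

    def test_degenerate_output_raises(self):
        counts = np.zeros((2, 2, 2), dtype=int)
        counts[:, :, 1] = 20  # c always present
        with pytest.raises(DegenerateTargetError):
            delta_u(ScenarioCounts(counts), LOGIC_TYPES[1], balanced=True)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(count_tables(), st.sampled_from(sorted(LOGIC_TYPES)))
    def test_complement_pair_shares_u_cf(self, sc, tid):
        t = LOGIC_TYPES[tid]
        comp = LOGIC_TYPES[t.complement_of]
        for balanced in (True, False):
            s1 = delta_u(sc, t, balanced)
            s2 = delta_u(sc, comp, balanced)
            assert s1.u_cf == pytest.approx(s2.u_cf, abs=TOL)
            assert s1.delta_u == pytest.approx(s2.delta_u, abs=TOL)
            assert s1.agreement == pytest.approx(1 - s2.agreement, abs=TOL)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(count_tables(), st.sampled_from([1, 2, 3, 4, 7, 8]))
    def test_symmetric_types_invariant_under_input_swap(self, sc, tid):
        t = LOGIC_TYPES[tid]
        for balanced in (True, False):
            s1 = delta_u(sc, t, balanced)
            s2 = delta_u(sc.swap_inputs(), t, balanced)
            assert s1.delta_u == pytest.approx(s2.delta_u, abs=TOL)
            assert s1.u_ca == pytest.approx(s2.u_cb, abs=TOL)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(count_tables(), st.sampled_from(sorted(LOGIC_TYPES)))
    def test_delta_u_bounded_above_by_one(self, sc, tid):
        s = delta_u(sc, LOGIC_TYPES[tid], balanced=True)
        assert s.delta_u <= 1.0 + TOL
        assert 0.0 <= s.u_cf <= 1.0 and 0.0 <= s.u_ca <= 1.0

    def test_balanced_equals_raw_when_cells_already_equal(self):
        rng = np.random.default_rng(9)
        counts = np.zeros((2, 2, 2), dtype=int)
        for i in range(2):
            for j in range(2):
                k1 = int(rng.integers(5, 26))
                counts[i, j] = [30 - k1, k1]
        sc = ScenarioCounts(counts)
        for tid in LOGIC_TYPES:
            sb = delta_u(sc, LOGIC_TYPES[tid], balanced=True)
            sr = delta_u(sc, LOGIC_TYPES[tid], balanced=False)
            assert sb.delta_u == pytest.approx(sr.delta_u, abs=TOL)

    def test_perfect_fit_delta_equals_one_minus_best_single(self):
        counts = np.zeros((2, 2, 2), dtype=int)
        for i in range(2):
            for j in range(2):
                counts[i, j, i | j] = 11
        s = delta_u(ScenarioCounts(counts), LOGIC_TYPES[3], balanced=True)
        assert s.u_cf == pytest.approx(1.0, abs=TOL)
        assert s.delta_u == pytest.approx(1.0 - max(s.u_ca, s.u_cb), abs=TOL)


class TestCompatibilityReport:
    def test_or_gate_compatible_set(self):
        sc = ScenarioCounts(np.arange(1, 9).reshape(2, 2, 2))
        report = compatibility_report(sc, LOGIC_TYPES[3])
        compatible = set(report[report.compatible].scenario)
        assert compatible == {"000", "011", "101", "111"}

    def test_and_gate_compatible_set(self):
        sc = ScenarioCounts(np.ones((2, 2, 2), dtype=int))
        report = compatibility_report(sc, LOGIC_TYPES[1])
        compatible = set(report[report.compatible].scenario)
        assert compatible == {"000", "010", "100", "111"}

    @pytest.mark.parametrize("tid", sorted(LOGIC_TYPES))
    def test_counts_partition(self, tid):
        rng = np.random.default_rng(tid)
        sc = ScenarioCounts(rng.integers(0, 30, size=(2, 2, 2)))
        report = compatibility_report(sc, LOGIC_TYPES[tid])
        assert report.n_genomes.sum() == sc.total
        assert report.compatible.sum() == 4  # exactly half the scenarios
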