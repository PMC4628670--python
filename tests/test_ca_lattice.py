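"""The lattice automaton: initialisation, swap rules, convergence."""

import itertools

import numpy as np
import pytest

from cabin.ca_lattice import (
    Lattice,
    RuleSchedule,
    apply_rule,
    compute_R,
    init_lattice,
    is_fixpoint,
    run_iteration,
    run_to_convergence,
)
from cabin.kmer_features import pairwise_distance_provider

from conftest import random_spectra_provider


class TestInit:
    def test_single_cell(self):
        assert init_lattice(1, seed=3).order.tolist() == [0]

    def test_determinism(self):
        a = init_lattice(50, seed=9)
        b = init_lattice(50, seed=9)
        np.testing.assert_array_equal(a.order, b.order)

    def test_is_permutation(self):
        lat = init_lattice(1000, seed=4)
        assert sorted(lat.order.tolist()) == list(range(1000))

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            init_lattice(0, seed=1)


class TestComputeR:
    @pytest.mark.parametrize("n,expected", [(9, 3), (5000, 70), (4, 3), (600, 24)])
    def test_values(self, n, expected):
        assert compute_R(n) == expected

    def test_monotone_nondecreasing(self):
        values = [compute_R(n) for n in range(4, 400)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            compute_R(3)


def table_oracle(table: np.ndarray):
    """Distance oracle backed by an explicit symmetric table."""

    def d(i: int, j: int) -> float:
        return float(table[i, j])

    return d


class TestApplyRule:
    def test_compares_successor_with_range_cell(self):
        # phi_5 at cell 0 must compare d(x0, x1) against d(x0, x4):
        # make x4 closer to x0 than x1 is, so the rule swaps cells 1 and 4.
        n = 6
        table = np.full((n, n), 5.0)
        np.fill_diagonal(table, 0.0)
        table[0, 1] = table[1, 0] = 4.0
        table[0, 4] = table[4, 0] = 1.0
        lat = Lattice(np.arange(n))
        assert apply_rule(lat, 0, 5, table_oracle(table))
        assert lat.order.tolist() == [0, 4, 2, 3, 1, 5]

    def test_periodic_wraparound(self):
        # phi_5 at cell N-4 reaches cell (N-4)+4 = N wrapped to 0.
        n = 6
        table = np.full((n, n), 5.0)
        np.fill_diagonal(table, 0.0)
        i = n - 4
        table[i, i + 1] = table[i + 1, i] = 4.0
        table[i, 0] = table[0, i] = 1.0
        lat = Lattice(np.arange(n))
        assert apply_rule(lat, i, 5, table_oracle(table))
        assert lat.order[i + 1] == 0 and lat.order[0] == i + 1

    def test_equal_distances_never_swap(self):
        n = 8
        table = np.ones((n, n))
        np.fill_diagonal(table, 0.0)
        lat = Lattice(np.arange(n))
        before = lat.order.copy()
        for r in range(3, n):
            for i in range(n):
                assert not apply_rule(lat, i, r, table_oracle(table))
        np.testing.assert_array_equal(lat.order, before)

    def test_invalid_range_rejected(self):
        lat = Lattice(np.arange(6))
        oracle = table_oracle(np.zeros((6, 6)))
        with pytest.raises(ValueError):
            apply_rule(lat, 0, 2, oracle)
        with pytest.raises(ValueError):
            apply_rule(lat, 0, 6, oracle)


class TestIteration:
    def test_fixpoint_means_zero_swaps(self):
        n = 8
        table = np.ones((n, n))
        np.fill_diagonal(table, 0.0)
        lat = Lattice(np.arange(n))
        assert run_iteration(lat, RuleSchedule(4), table_oracle(table)) == 0

    def test_single_triggering_rule_hand_trace(self):
        # N=6, R=3 only. All distances 2 except d(0,4)=1 < d(0,1)=2, so the
        # sweep's only firing rule is phi_3 at... phi_3 at cell i compares
        # d(x_i,x_{i+1}) vs d(x_i,x_{i+2}). Put 4 two cells after 0:
        # order [0,1,4,3,2,5]: at i=0, d(0,1)=2 > d(0,4)=1 -> swap cells 1,2
        # -> [0,4,1,3,2,5]. Afterwards no other pair is unequal, so the
        # remaining sweep fires nothing (pencil trace).
        n = 6
        table = np.full((n, n), 2.0)
        np.fill_diagonal(table, 0.0)
        table[0, 4] = table[4, 0] = 1.0
        lat = Lattice(np.array([0, 1, 4, 3, 2, 5]))
        swaps = run_iteration(lat, RuleSchedule(3), table_oracle(table))
        assert swaps == 1
        assert lat.order.tolist() == [0, 4, 1, 3, 2, 5]
        # second iteration: 4 now sits next to 0 and nothing else fires
        assert run_iteration(lat, RuleSchedule(3), table_oracle(table)) == 0

    def test_order_stays_permutation(self):
        d = random_spectra_provider(60, seed=5)
        lat = init_lattice(60, seed=6)
        run_iteration(lat, RuleSchedule(compute_R(60)), d)
        assert sorted(lat.order.tolist()) == list(range(60))

    def test_dense_and_callable_paths_agree(self):
        d = random_spectra_provider(40, seed=15)
        lat_fast = init_lattice(40, seed=16)
        lat_slow = lat_fast.copy()
        schedule = RuleSchedule(compute_R(40))
        s_fast = run_iteration(lat_fast, schedule, d)
        s_slow = run_iteration(lat_slow, schedule, table_oracle(d.matrix))
        assert s_fast == s_slow
        np.testing.assert_array_equal(lat_fast.order, lat_slow.order)


class TestConvergence:
    def test_identical_reads_converge_immediately(self):
        n = 10
        table = np.zeros((n, n))
        lat = init_lattice(n, seed=2)
        report = run_to_convergence(lat, RuleSchedule(3), table_oracle(table))
        assert report.converged
        assert report.iterations_run == 1
        assert report.swaps_per_iteration == [0]

    def test_converged_state_is_fixpoint(self, two_group_provider):
        n = two_group_provider.n
        lat = init_lattice(n, seed=32)
        schedule = RuleSchedule(compute_R(n))
        report = run_to_convergence(lat, schedule, two_group_provider)
        assert report.converged
        assert is_fixpoint(lat, schedule, two_group_provider)

    def test_two_separated_groups_become_contiguous(self, separated_groups):
        # R must reach past a foreign run for same-group runs to merge, so
        # give the rules a range on the order of the group size (50)
        d = pairwise_distance_provider(separated_groups, k=4)
        n = len(separated_groups)
        lat = init_lattice(n, seed=33)
        report = run_to_convergence(lat, RuleSchedule(30), d)
        assert report.converged
        labels = [separated_groups[int(r)].truth_label for r in lat.order]
        # on the circle, each group should occupy at most two maximal runs
        runs = [k for k, _ in itertools.groupby(labels)]
        if len(runs) > 1 and runs[0] == runs[-1]:
            runs = runs[:-1]
        assert len(runs) <= 4

    def test_determinism_end_to_end(self):
        d = random_spectra_provider(50, seed=41)
        schedule = RuleSchedule(compute_R(50))
        outs = []
        for _ in range(2):
            lat = init_lattice(50, seed=42)
            rep = run_to_convergence(lat, schedule, d)
            outs.append((lat.order.copy(), rep.swaps_per_iteration))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        assert outs[0][1] == outs[1][1]

    def test_nonconvergence_is_reported_not_raised(self):
        d = random_spectra_provider(100, seed=51)
        lat = init_lattice(100, seed=52)
        with pytest.warns(UserWarning, match="did not converge"):
            report = run_to_convergence(lat, RuleSchedule(compute_R(100)), d, 1)
        assert not report.converged
        assert report.iterations_run == 1

    def test_trace_records_every_iteration(self, two_group_provider):
        lat = init_lattice(two_group_provider.n, seed=62)
        report = run_to_convergence(
            lat, RuleSchedule(5), two_group_provider, trace=True
        )
        assert report.state_trace is not None
        assert len(report.state_trace) == report.iterations_run + 1
        np.testing.assert_array_equal(report.state_trace[-1], lat.order)
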