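import random

import pytest

from helpers import bfs_distances, linear_states, state_to_genome
from pathgroups import Genome, dcj_distance, solve_median
from pathgroups.pathgroups import (
    init_median,
    make_cycles,
    priority_levels,
)


class TestPriorityLevels:
    @pytest.mark.parametrize(
        "scheme,count", [("basic", 7), ("refined", 55), ("lookahead2", 165)]
    )
    def test_level_counts(self, scheme, count):
        levels = priority_levels(scheme)
        assert len(levels) == count
        assert len(set(levels)) == count

    def test_levels_are_in_decreasing_order(self):
        for scheme in ("basic", "refined", "lookahead2"):
            levels = priority_levels(scheme)
            assert levels == sorted(levels, reverse=True)

    def test_basic_enumeration(self):
        # one 3-cycle class, then 2- and 1-cycle classes by look-ahead 3/2/1
        assert priority_levels("basic") == [
            (3, 0),
            (2, 3), (2, 2), (2, 1),
            (1, 3), (1, 2), (1, 1),
        ]

    def test_two_cycle_always_beats_one_cycle(self):
        levels = priority_levels("refined")
        worst_two = max(i for i, l in enumerate(levels) if l[0] == 2)
        best_one = min(i for i, l in enumerate(levels) if l[0] == 1)
        assert worst_two < best_one


class TestInitMedian:
    def test_identical_genomes_fill_top_bucket(self):
        g = Genome("G", [[1, 2, 3, 4]])
        st = init_median(g.renamed("A"), g.renamed("B"), g.renamed("C"))
        top = priority_levels("refined")[0]
        # every adjacency-anchored pathgroup can close three cycles at once
        got = {x for (_, x) in st.buckets[top]}
        assert got == {2, 3, 4, 5, 6, 7}  # all non-telomere extremities
        # telomere-anchored groups have only cap-bounded paths: no priority
        assert st.priority_of(st.ancestors[0], 1) is None
        assert st.priority_of(st.ancestors[0], 8) is None

    def test_single_gene_degenerate(self):
        g = Genome("G", [[1]])
        res = make_cycles(init_median(g.renamed("A"), g.renamed("B"), g.renamed("C")))
        assert res.ancestor == g
        assert res.total == 0

    def test_hand_enumerated_three_gene_instance(self):
        """Three genomes one inversion away from [1,2,3]; all six pathgroups
        were enumerated by hand from the adjacency lists."""
        g1 = Genome("A", [[-1, 2, 3]])
        g2 = Genome("B", [[1, -2, 3]])
        g3 = Genome("C", [[1, 2, -3]])
        st = init_median(g1, g2, g3)
        a = st.ancestors[0]
        # far ends per branch (vertex encoding: tail 2g-1, head 2g)
        expected_far = {
            1: ((3, a), "T", "T"),
            2: ("T", (4, a), (3, a)),
            3: ((1, a), (5, a), (2, a)),
            4: ((5, a), (2, a), (6, a)),
            5: ((4, a), (3, a), "T"),
            6: ("T", "T", (4, a)),
        }
        for x, far in expected_far.items():
            view = st.pathgroup(a, x)
            assert view.far_ends == far
            key, _ = st.priority_of(a, x)
            assert key[0] == 1  # every group closes exactly one cycle
        # Group at 3h (vertex 6): its only candidate, 2h (vertex 4), closes
        # the branch-C path.  Hand derivation of the look-ahead: the leftover
        # branch-A/B paths end at 3t (5) and 1h (2), whose groups can then
        # close one cycle each (best next = 1); joining fragments [2] and [3]
        # makes 3t and 2t (3) the new fragment ends, so 3t loses its only
        # remaining candidate (3t-2t would be circular): net change -1.
        key, target = st.priority_of(a, 6)
        assert (key, target) == ((1, 1, -1), 4)

    def test_circular_completion_gets_no_priority(self):
        # the only candidate of each group joins the two ends of the same
        # single-gene fragment -> circular chromosome, forbidden
        g = Genome("G", [[1], [2]])
        flipped = Genome("H", [[-1], [2]])
        st = init_median(g.renamed("A"), g.renamed("B"), flipped.renamed("C"))
        assert all(st.priority_of(st.ancestors[0], x) is None for x in (1, 2, 3, 4))


class TestApplyStep:
    def test_three_cycle_step_report_and_conservation(self):
        g = Genome("G", [[1, 2, 3, 4]])
        st = init_median(g.renamed("A"), g.renamed("B"), g.renamed("C"))
        before = st.live_pathgroups
        node, x = st._pop_best()
        report = st.apply_step(node, x)
        assert report.cycles == 3
        assert st.live_pathgroups == before - 2
        assert report.n_secondary <= 4 and report.n_tertiary <= 8

    def test_fragment_concatenation(self):
        g = Genome("G", [[1, 2, 3]])
        st = init_median(g.renamed("A"), g.renamed("B"), g.renamed("C"))
        a = st.ancestors[0]
        # red edge 1h-2t joins fragments [1] and [2]
        st.apply_step(a, 2)
        assert st.other_end[a][1] == 4 and st.other_end[a][4] == 1
        # then 2h-3t joins [1,2] with [3]
        st.apply_step(a, 4)
        assert st.other_end[a][1] == 6 and st.other_end[a][6] == 1
        assert st.assemble(a) == g

    def test_step_requires_priority(self):
        g = Genome("G", [[1]])
        st = init_median(g.renamed("A"), g.renamed("B"), g.renamed("C"))
        with pytest.raises(ValueError):
            st.apply_step(st.ancestors[0], 1)


class TestMakeCycles:
    def test_identical_genomes(self):
        g = Genome("G", [[1, 5, 3], [2, 4]])
        res = solve_median(g.renamed("A"), g.renamed("B"), g.renamed("C"))
        assert res.ancestor == g
        assert res.total == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_identical_pair_dominates(self, seed, make_random_genome):
        """With two equal inputs the pair is an optimal median."""
        from pathgroups.simulate import apply_rearrangements

        g = make_random_genome(12, 2, seed=seed, name="G")
        far, _ = apply_rearrangements(g, 4, 0.9, seed=seed + 100)
        res = solve_median(g.renamed("A"), g.renamed("B"), far.renamed("C"))
        assert res.ancestor == g
        assert res.total == dcj_distance(g, far).d

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_at_least_optimal_n3(self, seed):
        states = linear_states(3)
        rng = random.Random(seed)
        picks = rng.sample(states, 3)
        gs = [state_to_genome(s, 3, f"G{i}") for i, s in enumerate(picks)]
        dists = [bfs_distances(s, 3) for s in picks]
        optimal = min(sum(d[s] for d in dists) for s in states)
        res = solve_median(*gs)
        assert res.total >= optimal

    @pytest.mark.parametrize("scheme", ["basic", "refined", "lookahead2"])
    def test_valid_output_and_consistent_total(self, scheme, make_median_instance):
        _, leaves = make_median_instance(n=25, chromosomes=3, ops=6, seed=3)
        res = solve_median(*leaves, scheme=scheme)
        # Genome construction validates gene content and linearity
        assert res.ancestor.n == 25
        assert res.total == sum(dcj_distance(res.ancestor, g).d for g in leaves)

    def test_deterministic(self, make_median_instance):
        _, leaves = make_median_instance(n=40, chromosomes=4, ops=10, seed=9)
        r1 = solve_median(*leaves)
        r2 = solve_median(*leaves)
        assert r1.ancestor.chromosomes == r2.ancestor.chromosomes
        assert r1.distances == r2.distances


class TestInvariants:
    def test_conservation_and_proposition_bounds(self, make_median_instance):
        _, leaves = make_median_instance(n=60, chromosomes=5, ops=15, seed=2)
        st = init_median(*leaves)
        initial = st.live_pathgroups
        assert initial == st.initial_pathgroups == 2 * 60  # one group per extremity
        st.run()
        assert st.live_pathgroups == initial - 2 * st.steps_taken
        assert st.max_secondary <= 4
        assert st.max_tertiary <= 8

    def test_observed_keys_within_scheme_table(self, make_median_instance):
        for scheme in ("basic", "refined", "lookahead2"):
            _, leaves = make_median_instance(n=30, chromosomes=3, ops=8, seed=5)
            st = init_median(*leaves, scheme=scheme)
            table = set(priority_levels(scheme))
            seen = set()
            while (item := st._pop_best()) is not None:
                key, _ = st.priority_of(*item)
                seen.add(key)
                st.apply_step(*item)
            assert seen <= table
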