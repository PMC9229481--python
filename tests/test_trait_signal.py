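"""CTMC likelihood, stochastic mapping, HPD, and the randomization test.

Oracles: exhaustive enumeration over internal-node states for the pruning
likelihood, matrix exponentials for transition probabilities, grid search for
the ML rate, and parity-restricted Poisson closed forms for conditional jump
counts.
"""

import itertools
import math

import dendropy
import numpy as np
import pytest
import scipy.linalg
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from halorange.trait_signal import (
    HPDInterval,
    TreeIndex,
    _partials,
    _sample_states_matrix,
    hpd,
    ml_rate,
    prune_likelihood,
    randomize_traits,
    sample_branch_path,
    sample_node_states,
    signal_test,
    stochastic_map,
    transition_prob,
)
from halorange.simulate import (
    simulate_clade_structured_dataset,
    simulate_trait_history,
    simulate_yule_tree,
)

from conftest import tree_from_newick


# ---------------------------------------------------------------------------
# oracles


def enumeration_likelihood(tree: dendropy.Tree, traits: dict, mu: float) -> float:
    """Sum the joint probability over every internal-node state assignment."""
    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    total = 0.0
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = {id(nd): s for nd, s in zip(internal, assignment)}
        for nd in nodes:
            if nd.is_leaf():
                state[id(nd)] = traits[nd.taxon.label]
        p = 0.5  # stationary root prior
        for nd in nodes:
            if nd.parent_node is None:
                continue
            P = transition_prob(mu, nd.edge.length)
            p *= P[state[id(nd.parent_node)], state[id(nd)]]
        total += p
    return total


def conditional_mean_jumps(lam: float, equal_endpoints: bool) -> float:
    """E[N] for the parity-restricted Poisson(lam) jump count."""
    if equal_endpoints:
        return lam * math.tanh(lam)
    return lam / math.tanh(lam)


# ---------------------------------------------------------------------------
# transition probabilities


class TestTransitionProb:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_prob(1.3, 0.0), np.eye(2))

    def test_long_time_reaches_stationarity(self):
        assert np.allclose(transition_prob(1.0, 1e6), 0.5)

    def test_matches_matrix_exponential(self):
        for mu, t in [(1.0, 1.0), (0.3, 2.5), (4.0, 0.2)]:
            Q = np.array([[-mu, mu], [mu, -mu]])
            assert np.allclose(transition_prob(mu, t), scipy.linalg.expm(Q * t), atol=1e-12)

    @given(mu=st.floats(0.01, 5.0), t1=st.floats(0.0, 10.0), t2=st.floats(0.0, 10.0))
    def test_chapman_kolmogorov(self, mu, t1, t2):
        lhs = transition_prob(mu, t1) @ transition_prob(mu, t2)
        assert np.allclose(lhs, transition_prob(mu, t1 + t2), atol=1e-12)
        assert np.allclose(lhs.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# pruning likelihood


class TestPruneLikelihood:
    def test_zero_length_cherry_equal_states(self):
        tree = tree_from_newick("(A:0,B:0);")
        assert prune_likelihood(tree, {"A": 0, "B": 0}, 1.0) == pytest.approx(0.5)

    def test_zero_length_cherry_conflicting_states(self):
        tree = tree_from_newick("(A:0,B:0);")
        assert prune_likelihood(tree, {"A": 0, "B": 1}, 1.0) == 0.0

    def test_matches_enumeration_on_four_tips(self, four_tip_tree):
        traits = {"A": 0, "B": 1, "C": 1, "D": 0}
        for mu in (0.1, 0.7, 2.0):
            assert prune_likelihood(four_tip_tree, traits, mu) == pytest.approx(
                enumeration_likelihood(four_tip_tree, traits, mu), abs=1e-12
            )

    def test_matches_enumeration_on_random_trees(self, rng):
        for n in (4, 5, 6):
            tree = simulate_yule_tree(n, 1.0, rng)
            labels = [t.label for t in tree.taxon_namespace]
            traits = {l: int(rng.integers(2)) for l in labels}
            mu = float(rng.uniform(0.05, 2.0))
            assert prune_likelihood(tree, traits, mu) == pytest.approx(
                enumeration_likelihood(tree, traits, mu), abs=1e-10
            )

    def test_total_probability_sums_to_one(self, rng):
        tree = simulate_yule_tree(5, 1.0, rng)
        labels = [t.label for t in tree.taxon_namespace]
        total = sum(
            prune_likelihood(tree, dict(zip(labels, states)), 0.6)
            for states in itertools.product((0, 1), repeat=5)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_missing_tip_state_is_error(self, cherry):
        with pytest.raises(KeyError):
            prune_likelihood(cherry, {"A": 0}, 1.0)


# ---------------------------------------------------------------------------
# ML rate


class TestMLRate:
    def test_two_tip_grid_oracle(self, cherry):
        # L(mu) = (1/2)·2·P_same·P_diff, monotone increasing, so the optimum
        # sits on a likelihood plateau: compare attained likelihoods, not mu
        mu_hat = ml_rate(cherry, {"A": 0, "B": 1})
        grid = np.linspace(1e-4, 20, 40001)
        best = max(prune_likelihood(cherry, {"A": 0, "B": 1}, m) for m in grid)
        assert prune_likelihood(cherry, {"A": 0, "B": 1}, mu_hat) >= best - 1e-9

    def test_four_tip_grid_oracle(self, four_tip_tree):
        traits = {"A": 0, "B": 0, "C": 1, "D": 1}
        mu_hat = ml_rate(four_tip_tree, traits)
        grid = np.geomspace(1e-4, 50, 20001)
        lik = [prune_likelihood(four_tip_tree, traits, m) for m in grid]
        mu_grid = grid[int(np.argmax(lik))]
        assert mu_hat == pytest.approx(mu_grid, rel=1e-3)

    def test_doubling_branch_lengths_halves_rate(self, rng):
        tree = simulate_yule_tree(30, 1.0, rng)
        traits, _ = simulate_trait_history(tree, 0.8, rng)
        if len(set(traits.values())) < 2:
            pytest.skip("monomorphic draw")
        mu1 = ml_rate(tree, traits)
        for nd in tree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= 2.0
        mu2 = ml_rate(tree, traits)
        assert mu2 == pytest.approx(mu1 / 2.0, rel=1e-3)

    def test_recovers_simulation_rate_within_factor_two(self, rng):
        estimates = []
        for _ in range(9):
            tree = simulate_yule_tree(200, 1.0, rng)
            traits, _ = simulate_trait_history(tree, 0.5, rng)
            estimates.append(ml_rate(tree, traits))
        med = float(np.median(estimates))
        assert 0.25 < med < 1.0

    def test_monomorphic_returns_floor_with_warning(self, cherry):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert ml_rate(cherry, {"A": 1, "B": 1}) == pytest.approx(1e-6)


# ---------------------------------------------------------------------------
# node-state sampling


class TestSampleNodeStates:
    def test_root_marginal_matches_enumeration(self, rng):
        tree = tree_from_newick("((A:0.4,B:0.7):0.5,C:0.9);")
        traits = {"A": 0, "B": 1, "C": 1}
        mu = 0.8
        # exact root marginal by enumerating the non-root internal node
        idx = TreeIndex(tree)
        nodes = list(tree.preorder_node_iter())
        internal = [nd for nd in nodes if not nd.is_leaf()]
        weights = {0: 0.0, 1: 0.0}
        for assignment in itertools.product((0, 1), repeat=len(internal)):
            state = {id(nd): s for nd, s in zip(internal, assignment)}
            for nd in nodes:
                if nd.is_leaf():
                    state[id(nd)] = traits[nd.taxon.label]
            p = 0.5
            for nd in nodes:
                if nd.parent_node is None:
                    continue
                p *= transition_prob(mu, nd.edge.length)[
                    state[id(nd.parent_node)], state[id(nd)]
                ]
            weights[state[id(nodes[0])]] += p
        exact = weights[1] / (weights[0] + weights[1])

        part, _ = _partials(idx, traits, mu)
        draws = _sample_states_matrix(idx, part, mu, rng, 100_000)
        phat = draws[:, idx.root].mean()
        se = math.sqrt(exact * (1 - exact) / draws.shape[0])
        assert abs(phat - exact) < 3 * se

    def test_short_branches_pin_internal_states(self):
        tree = tree_from_newick("((A:1e-9,B:1e-9):1e-9,C:1e-9);")
        states = sample_node_states(tree, {"A": 0, "B": 0, "C": 0}, 1.0, rng=1)
        assert set(states.values()) == {0}

    def test_symmetric_cherry_root_marginal_is_half(self, cherry):
        idx = TreeIndex(cherry)
        part, _ = _partials(idx, {"A": 0, "B": 1}, 0.7)
        w = 0.5 * part[idx.root]
        assert w[1] / w.sum() == pytest.approx(0.5)

    def test_tips_keep_observed_states(self, four_tip_tree):
        idx = TreeIndex(four_tip_tree)
        traits = {"A": 0, "B": 1, "C": 1, "D": 0}
        states = sample_node_states(idx, traits, 0.5, rng=3)
        for i, label in idx.tip_label.items():
            assert states[i] == traits[label]


# ---------------------------------------------------------------------------
# branch paths


class TestSampleBranchPath:
    def test_equal_endpoints_zero_length(self):
        assert sample_branch_path(0, 0, 0.0, 1.0, rng=0) == []

    def test_unequal_endpoints_zero_length_is_error(self):
        with pytest.raises(ValueError):
            sample_branch_path(0, 1, 0.0, 1.0, rng=0)

    @given(a=st.integers(0, 1), b=st.integers(0, 1),
           t=st.floats(0.01, 5.0), mu=st.floats(0.01, 3.0),
           seed=st.integers(0, 2**16))
    @settings(max_examples=100)
    def test_parity_and_support(self, a, b, t, mu, seed):
        path = sample_branch_path(a, b, t, mu, rng=seed)
        assert len(path) % 2 == (a != b)
        assert all(0 <= x <= t for x in path)
        assert path == sorted(path)

    def test_conditional_means_match_closed_forms(self, rng):
        n = 30_000
        for lam in (0.5, 2.0):
            for eq in (True, False):
                counts = np.array([
                    len(sample_branch_path(0, 0 if eq else 1, lam, 1.0, rng))
                    for _ in range(n)
                ])
                expect = conditional_mean_jumps(lam, eq)
                se = counts.std() / math.sqrt(n)
                assert abs(counts.mean() - expect) < 3 * se


# ---------------------------------------------------------------------------
# stochastic mapping


class TestStochasticMap:
    def test_monomorphic_tiny_rate_gives_zero_jumps(self, four_tip_tree):
        traits = {"A": 0, "B": 0, "C": 0, "D": 0}
        hists = stochastic_map(four_tip_tree, traits, 1e-8, 200, rng=5)
        assert all(h.jump_count == 0 for h in hists)

    def test_two_tip_mean_matches_marginalized_closed_form(self, rng):
        t1, t2, mu = 0.8, 1.5, 0.9
        tree = tree_from_newick(f"(A:{t1},B:{t2});")
        traits = {"A": 0, "B": 1}
        # root posterior, then branch-level conditional expectations
        w = np.array([
            0.5 * transition_prob(mu, t1)[r, 0] * transition_prob(mu, t2)[r, 1]
            for r in (0, 1)
        ])
        w /= w.sum()
        expect = sum(
            w[r] * (conditional_mean_jumps(mu * t1, r == 0)
                    + conditional_mean_jumps(mu * t2, r == 1))
            for r in (0, 1)
        )
        hists = stochastic_map(tree, traits, mu, 40_000, rng)
        counts = np.array([h.jump_count for h in hists], dtype=float)
        se = counts.std() / math.sqrt(counts.size)
        assert abs(counts.mean() - expect) < 3 * se

    def test_clade_partitioned_traits_need_one_jump(self):
        tree = tree_from_newick("((A:0.1,B:0.1):5,(C:0.1,D:0.1):5);")
        traits = {"A": 0, "B": 0, "C": 1, "D": 1}
        hists = stochastic_map(tree, traits, 0.1, 2000, rng=11)
        counts = np.array([h.jump_count for h in hists])
        values, freq = np.unique(counts, return_counts=True)
        assert values[np.argmax(freq)] == 1

    def test_history_jump_count_totals_branch_events(self, four_tip_tree):
        traits = {"A": 0, "B": 1, "C": 1, "D": 0}
        for h in stochastic_map(four_tip_tree, traits, 0.8, 50, rng=2):
            assert h.jump_count == sum(len(v) for v in h.branch_events.values())

    def test_endpoint_parity_per_branch(self, four_tip_tree):
        idx = TreeIndex(four_tip_tree)
        traits = {"A": 0, "B": 1, "C": 1, "D": 0}
        for h in stochastic_map(idx, traits, 0.8, 100, rng=4):
            for i in range(idx.n_nodes - 1):
                n_events = len(h.branch_events.get(idx.branch_key[i], []))
                differ = h.node_states[i] != h.node_states[idx.parent[i]]
                assert n_events % 2 == differ


# ---------------------------------------------------------------------------
# HPD


class TestHPD:
    def test_constant_sample(self):
        assert hpd([4.0] * 10) == HPDInterval(4.0, 4.0, 0.95)

    def test_uniform_integers(self):
        interval = hpd(list(range(1, 101)), 0.95)
        assert interval.upper - interval.lower == 94

    def test_full_mass_is_range(self):
        assert hpd([3.0, 1.0, 9.0], 1.0) == HPDInterval(1.0, 9.0, 1.0)

    def test_ties_broken_toward_smaller_lower_bound(self):
        assert hpd([0.0, 1.0, 2.0, 3.0], 0.5) == HPDInterval(0.0, 1.0, 0.5)

    def test_skewed_sample_prefers_dense_region(self):
        samples = [0.0] * 90 + [100.0] * 10
        interval = hpd(samples, 0.9)
        assert interval == HPDInterval(0.0, 0.0, 0.9)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            hpd([])

    @given(samples=st.lists(st.floats(-100, 100), min_size=1, max_size=60),
           mass=st.floats(0.5, 1.0))
    def test_interval_covers_requested_mass(self, samples, mass):
        interval = hpd(samples, mass)
        inside = sum(interval.lower <= x <= interval.upper for x in samples)
        assert inside >= math.ceil(mass * len(samples))


class TestRatePosterior:
    def test_weights_normalized_and_positive_support(self, four_tip_tree):
        from halorange.trait_signal import rate_posterior

        grid, w = rate_posterior(four_tip_tree, {"A": 0, "B": 0, "C": 1, "D": 1})
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all() and (grid > 0).all()

    def test_structured_trait_concentrates_low_scrambled_spreads_high(self):
        from halorange.trait_signal import rate_posterior

        tree, traits = simulate_clade_structured_dataset(32, rng=2)
        scrambled = randomize_traits(traits, rng=2)
        g1, w1 = rate_posterior(tree, traits)
        g2, w2 = rate_posterior(tree, scrambled)
        assert float(np.sum(g1 * w1)) < float(np.sum(g2 * w2))

    def test_marginal_map_returns_requested_samples(self, four_tip_tree):
        from halorange.trait_signal import stochastic_map_marginal

        hists = stochastic_map_marginal(
            four_tip_tree, {"A": 0, "B": 1, "C": 1, "D": 0}, 120, rng=7
        )
        assert len(hists) == 120


# ---------------------------------------------------------------------------
# randomization and the signal test


class TestRandomizeTraits:
    @given(seed=st.integers(0, 2**16),
           states=st.lists(st.integers(0, 1), min_size=2, max_size=20))
    def test_state_counts_preserved(self, seed, states):
        traits = {f"t{i}": s for i, s in enumerate(states)}
        shuffled = randomize_traits(traits, rng=seed)
        assert sorted(shuffled.values()) == sorted(traits.values())
        assert set(shuffled) == set(traits)

    def test_assignments_uniform_chi_square(self, rng):
        traits = {f"t{i}": s for i, s in enumerate([1, 1, 1, 0, 0])}
        counts: dict[tuple, int] = {}
        n = 10_000
        for _ in range(n):
            key = tuple(sorted(randomize_traits(traits, rng).items()))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 10  # C(5, 3) distinct assignments
        stat, p = scipy.stats.chisquare(list(counts.values()))
        assert p > 0.01


def _balanced_split_tree():
    """16 tips, perfect trait split across long root-adjacent branches."""
    sub = "({}:0.1,{}:0.1):0.1,({}:0.1,{}:0.1):0.1"
    left = f"(({sub.format('a1','a2','a3','a4')}):0.1,({sub.format('a5','a6','a7','a8')}):0.1):6"
    right = f"(({sub.format('b1','b2','b3','b4')}):0.1,({sub.format('b5','b6','b7','b8')}):0.1):6"
    tree = tree_from_newick(f"({left},{right});")
    traits = {f"a{i}": 0 for i in range(1, 9)} | {f"b{i}": 1 for i in range(1, 9)}
    return tree, traits


class TestSignalTest:
    def test_perfect_root_split_declares_signal_plugin_rate(self):
        # conditioning on the ML rate: the perfectly partitioned trait pins the
        # rate low, real jumps concentrate at 1, nulls land far above
        tree, traits = _balanced_split_tree()
        result = signal_test(
            tree, traits, n_map_samples=400, n_null=10, rng=17, marginalize_rate=False
        )
        assert result.decision == "signal"
        assert not any(result.overlap_flags)
        assert result.real_hpd.upper < min(h.lower for h in result.null_hpds)

    def test_clade_structured_dataset_declares_signal(self):
        tree, traits = simulate_clade_structured_dataset(32, rng=1)
        result = signal_test(tree, traits, n_map_samples=300, n_null=10, rng=1)
        assert result.decision == "signal"
        assert result.real_hpd.upper < min(h.lower for h in result.null_hpds)

    def test_invariant_under_state_relabeling(self):
        tree, traits = simulate_clade_structured_dataset(32, rng=5)
        flipped = {k: 1 - v for k, v in traits.items()}
        a = signal_test(tree, traits, n_map_samples=300, n_null=8, rng=3)
        b = signal_test(tree, flipped, n_map_samples=300, n_null=8, rng=3)
        assert a.decision == b.decision == "signal"

    def test_permuted_traits_declare_no_signal(self, rng):
        tree = simulate_yule_tree(32, 1.0, rng)
        labels = [t.label for t in tree.taxon_namespace]
        states = [1] * 8 + [0] * 24
        traits = dict(zip(labels, np.array(states)[rng.permutation(32)]))
        traits = {k: int(v) for k, v in traits.items()}
        result = signal_test(tree, traits, n_map_samples=300, n_null=10, rng=rng)
        assert result.decision == "no_signal"
        assert any(result.overlap_flags)

    def test_monomorphic_is_degenerate(self, cherry):
        result = signal_test(cherry, {"A": 1, "B": 1}, rng=0)
        assert result.degenerate
        assert result.decision is None

    def test_tree_sample_pools_equally(self, rng):
        trees = [simulate_yule_tree(8, 1.0, rng) for _ in range(3)]
        labels = [t.label for t in trees[0].taxon_namespace]
        traits = {l: i % 2 for i, l in enumerate(labels)}
        result = signal_test(trees, traits, n_map_samples=90, n_null=2, rng=rng)
        assert result.real_jumps.size == 90
        assert len(result.mu_real) == 3
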