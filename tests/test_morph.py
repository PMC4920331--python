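"""Lewis-Mk likelihood: transition matrices, rate heterogeneity, clocks,
and Felsenstein pruning against a brute-force enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.linalg import expm

from fossildater.morph import (
    CharacterMatrix,
    ClockModel,
    MkModelConfig,
    discrete_gamma_rates,
    mk_transition_matrix,
    partition_by_state_count,
    tree_log_likelihood,
    ucln_branch_rates,
)
from fossildater.trees import Node, SampledTree

from conftest import build_sampled_ancestor_tree, build_three_taxon_tree


class TestCharacterMatrix:
    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValueError):
            CharacterMatrix(["a", "a"], np.zeros((2, 1)), [2])

    def test_codes_must_fit_declared_k(self):
        with pytest.raises(ValueError):
            CharacterMatrix(["a", "b"], [[0], [2]], [2])

    def test_observed_state_counts_resolution(self):
        m = CharacterMatrix(
            ["a", "b", "c"],
            [[0, 0, -1], [1, 0, -1], [2, 0, -1]],
            [3, 2, 2],
        )
        # constant and all-missing characters resolve to the minimal k = 2
        assert m.observed_state_counts().tolist() == [3, 2, 2]


class TestPartition:
    def test_two_state_counts_two_partitions(self):
        m = CharacterMatrix(
            ["a", "b", "c"],
            [[0, 0], [1, 1], [1, 2]],
            [2, 3],
        )
        parts = partition_by_state_count(m)
        assert len(parts) == 2
        assert parts[0].n_chars == 1 and parts[1].n_chars == 1

    def test_penguin_like_partition_count(self, penguin_small):
        _, matrix, _ = penguin_small
        parts = partition_by_state_count(matrix)
        assert 1 <= len(parts) <= 6
        assert sum(p.n_chars for p in parts) == matrix.n_chars

    def test_constant_characters_not_dropped(self):
        m = CharacterMatrix(["a", "b"], [[0, -1], [0, -1]], [2, 2])
        parts = partition_by_state_count(m)
        assert sum(p.n_chars for p in parts) == 2

    def test_empty_matrix_rejected(self):
        m = CharacterMatrix(["a"], np.zeros((1, 1), dtype=np.int8), [2])
        m.data = np.zeros((1, 0), dtype=np.int8)
        m.state_counts = np.zeros(0, dtype=np.int64)
        with pytest.raises(ValueError):
            partition_by_state_count(m)


class TestTransitionMatrix:
    def test_identity_at_zero_duration(self):
        assert mk_transition_matrix(4, 0.3, 0.0) == pytest.approx(np.eye(4))

    def test_stationary_limit(self):
        P = mk_transition_matrix(3, 1.0, 1e6)
        assert P == pytest.approx(np.full((3, 3), 1 / 3))

    @pytest.mark.parametrize("k", [2, 3, 5, 7])
    def test_matches_matrix_exponential(self, k):
        rate, t = 0.02, 10.0
        Q = np.full((k, k), rate / (k - 1))
        np.fill_diagonal(Q, -rate)
        assert np.abs(mk_transition_matrix(k, rate, t) - expm(Q * t)).max() < 1e-10

    def test_rows_sum_to_one(self):
        P = mk_transition_matrix(5, 0.7, 3.0)
        assert P.sum(axis=1) == pytest.approx(np.ones(5))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            mk_transition_matrix(1, 0.1, 1.0)


class TestDiscreteGamma:
    def test_single_category(self):
        assert discrete_gamma_rates(0.7, 1).tolist() == [1.0]

    @pytest.mark.parametrize("alpha,ncat", [(0.2, 4), (0.5, 4), (2.0, 8)])
    def test_unit_mean_and_ordering(self, alpha, ncat):
        rates = discrete_gamma_rates(alpha, ncat)
        assert rates.mean() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(rates) >= 0)

    def test_against_quadrature_oracle(self):
        # conditional means of Gamma(alpha, mean 1) between its quartiles
        alpha, ncat = 0.5, 4
        edges = stats.gamma.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1 / alpha)
        expected = []
        for a, b in zip(edges[:-1], edges[1:]):
            num = integrate.quad(
                lambda x: x * stats.gamma.pdf(x, a=alpha, scale=1 / alpha), a, b
            )[0]
            expected.append(num * ncat)
        assert discrete_gamma_rates(alpha, ncat) == pytest.approx(
            np.array(expected), abs=1e-6
        )


class TestUCLN:
    def test_zero_log_sd_collapses_to_strict(self):
        q = np.linspace(0.05, 0.95, 10)
        assert ucln_branch_rates(0.02, 0.0, q) == pytest.approx(np.full(10, 0.02))

    def test_real_space_mean(self, rng):
        q = rng.uniform(size=100000)
        rates = ucln_branch_rates(0.02, 0.8, q)
        assert rates.mean() == pytest.approx(0.02, rel=0.01)

    def test_median_identity(self):
        mu, S = 0.05, 0.6
        med = ucln_branch_rates(mu, S, np.array([0.5]))[0]
        assert med == pytest.approx(mu * math.exp(-(S**2) / 2))

    def test_quantiles_out_of_range(self):
        with pytest.raises(ValueError):
            ucln_branch_rates(0.02, 0.5, np.array([0.0, 0.5]))


def _enumeration_loglik(tree, matrix, rate):
    """Independent oracle: sum over all interior state assignments."""
    arr = tree.to_arrays()
    dur = arr.durations()
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    nodes = arr.nodes
    id2idx = {id(n): i for i, n in enumerate(nodes)}
    total = 0.0
    for j in range(matrix.n_chars):
        col = matrix.data[:, j]
        observed = sorted(set(int(x) for x in col if x >= 0))
        smap = {s: i for i, s in enumerate(observed)}
        k = max(len(observed), 2)
        Ps = [mk_transition_matrix(k, rate, dur[i]) for i in range(len(nodes))]
        like = 0.0
        for assign in itertools.product(range(k), repeat=len(nodes)):
            pr = 1.0 / k
            ok = True
            for i, node in enumerate(nodes):
                for child in node.children:
                    ci = id2idx[id(child)]
                    pr *= Ps[ci][assign[i], assign[ci]]
                if node.is_tip:
                    code = matrix.data[row_of[node.label], j]
                    if code >= 0 and assign[i] != smap[int(code)]:
                        ok = False
                        break
            if ok:
                like += pr
        total += math.log(like)
    return total


def _random_small_tree(rng, n_tips, with_sa):
    nodes = [Node(0.0, "extant", f"t{i}") for i in range(n_tips)]
    age = 0.0
    while len(nodes) > 1:
        age += rng.exponential(1.0) + 0.1
        a = nodes.pop(rng.integers(len(nodes)))
        b = nodes.pop(rng.integers(len(nodes)))
        p = Node(age, "internal")
        p.add_child(a)
        p.add_child(b)
        nodes.append(p)
    tree = SampledTree(nodes[0], age * 1.2)
    tips = tree.tips()
    f = tips[rng.integers(len(tips))]
    f.kind = "fossil"
    f.age = f.parent.age if with_sa else f.parent.age * rng.uniform(0.2, 0.8)
    return tree


class TestPruningLikelihood:
    def test_zero_durations_root_draw_only(self):
        root = Node(0.0, "internal")
        root.add_child(Node(0.0, "extant", "a"))
        root.add_child(Node(0.0, "extant", "b"))
        tree = SampledTree(root, 0.5)
        m = CharacterMatrix(["a", "b"], [[0], [0]], [2])
        ll = tree_log_likelihood(tree, m, MkModelConfig(), ClockModel(mean=0.1))
        assert ll == pytest.approx(math.log(0.5))

    def test_all_missing_character_contributes_zero(self):
        tree = build_three_taxon_tree()
        m = CharacterMatrix(
            ["fossil_1", "extant_1", "extant_2"],
            [[0, -1], [1, -1], [0, -1]],
            [2, 2],
        )
        m_one = CharacterMatrix(
            ["fossil_1", "extant_1", "extant_2"], [[0], [1], [0]], [2]
        )
        clock = ClockModel(mean=0.05)
        assert tree_log_likelihood(tree, m, clock=clock) == pytest.approx(
            tree_log_likelihood(tree, m_one, clock=clock)
        )

    def test_matches_enumeration_oracle(self, rng):
        worst = 0.0
        for case in range(100):
            tree = _random_small_tree(rng, int(rng.integers(3, 6)), case % 2 == 0)
            tips = tree.tips()
            k = int(rng.integers(2, 4))
            data = rng.integers(0, k, size=(len(tips), 2)).astype(np.int8)
            data[rng.random(data.shape) < 0.2] = -1
            m = CharacterMatrix([t.label for t in tips], data, np.full(2, k))
            ll = tree_log_likelihood(tree, m, MkModelConfig(), ClockModel(mean=0.3))
            oracle = _enumeration_loglik(tree, m, 0.3)
            worst = max(worst, abs(ll - oracle))
        assert worst < 1e-8

    def test_invariant_to_character_and_taxon_order(self, rng):
        tree = build_three_taxon_tree()
        taxa = ["fossil_1", "extant_1", "extant_2"]
        data = rng.integers(0, 2, size=(3, 20)).astype(np.int8)
        m = CharacterMatrix(taxa, data, np.full(20, 2))
        clock = ClockModel(mean=0.07)
        base = tree_log_likelihood(tree, m, clock=clock)
        perm = rng.permutation(20)
        m_chars = CharacterMatrix(taxa, data[:, perm], np.full(20, 2))
        assert tree_log_likelihood(tree, m_chars, clock=clock) == pytest.approx(base)
        order = [2, 0, 1]
        m_taxa = CharacterMatrix(
            [taxa[i] for i in order], data[order], np.full(20, 2)
        )
        assert tree_log_likelihood(tree, m_taxa, clock=clock) == pytest.approx(base)

    def test_rate_time_confounding(self, rng):
        tree = build_three_taxon_tree()
        data = rng.integers(0, 2, size=(3, 15)).astype(np.int8)
        m = CharacterMatrix(
            ["fossil_1", "extant_1", "extant_2"], data, np.full(15, 2)
        )
        base = tree_log_likelihood(tree, m, clock=ClockModel(mean=0.08))
        scaled = tree.copy()
        c = 3.0
        for node in scaled.postorder():
            node.age *= c
        scaled.origin_T *= c
        assert tree_log_likelihood(
            scaled, m, clock=ClockModel(mean=0.08 / c)
        ) == pytest.approx(base)

    def test_strict_equals_ucln_with_zero_sd(self, rng):
        tree = build_sampled_ancestor_tree()
        data = rng.integers(0, 3, size=(3, 10)).astype(np.int8)
        m = CharacterMatrix(
            ["fossil_1", "extant_1", "extant_2"], data, np.full(10, 3)
        )
        n_nodes = len(list(tree.postorder()))
        strict = tree_log_likelihood(tree, m, clock=ClockModel(mean=0.04))
        ucln = tree_log_likelihood(
            tree,
            m,
            clock=ClockModel(
                kind="ucln",
                mean=0.04,
                log_sd=0.0,
                branch_quantiles=np.full(n_nodes, 0.3),
            ),
        )
        assert strict == ucln

    def test_gamma_rate_variation_changes_likelihood(self, rng):
        tree = build_three_taxon_tree()
        data = rng.integers(0, 2, size=(3, 30)).astype(np.int8)
        m = CharacterMatrix(
            ["fossil_1", "extant_1", "extant_2"], data, np.full(30, 2)
        )
        clock = ClockModel(mean=0.08)
        plain = tree_log_likelihood(tree, m, MkModelConfig(), clock)
        gamma = tree_log_likelihood(
            tree, m, MkModelConfig(gamma_shape=0.3, gamma_ncat=4), clock
        )
        assert plain != gamma

    def test_mkv_correction_penalizes_constant_probability(self, rng):
        tree = build_three_taxon_tree()
        data = rng.integers(0, 2, size=(3, 10)).astype(np.int8)
        m = CharacterMatrix(
            ["fossil_1", "extant_1", "extant_2"], data, np.full(10, 2)
        )
        clock = ClockModel(mean=0.02)
        plain = tree_log_likelihood(tree, m, MkModelConfig(), clock)
        mkv = tree_log_likelihood(
            tree, m, MkModelConfig(ascertainment="variable"), clock
        )
        assert mkv > plain  # dividing by (1 - P(constant)) < 1 raises each term

    def test_taxon_mismatch_raises(self):
        tree = build_three_taxon_tree()
        m = CharacterMatrix(["nope"], [[0]], [2])
        with pytest.raises(ValueError, match="nope"):
            tree_log_likelihood(tree, m)
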