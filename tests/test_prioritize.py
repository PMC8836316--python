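import numpy as np
import pytest

from conplan import (
    PrioritizerConfig,
    RankState,
    assign_aggregate_weights,
    marginal_loss,
    rank_abf,
    rank_with_mask,
)

from conftest import make_stack, random_stack


def abf_oracle_order(q, w, z):
    """Brute-force greedy: full marginal-loss recomputation every step,
    pure-Python arithmetic, first-index tie break."""
    n, m = len(q), len(w)
    Q = [sum(q[i][j] for i in range(n)) for j in range(m)]
    R = [1.0] * m
    alive = list(range(n))
    order = []
    while alive:
        best, best_d = None, None
        for i in alive:
            d = 0.0
            for j in range(m):
                if Q[j] <= 0:
                    continue
                p = q[i][j] / Q[j]
                after = R[j] - p
                if after < 0:
                    after = 0.0
                d += w[j] * (R[j] ** z - after**z)
            if best is None or d < best_d:
                best, best_d = i, d
        order.append(best)
        for j in range(m):
            if Q[j] > 0:
                R[j] = max(R[j] - q[best][j] / Q[j], 0.0)
        alive.remove(best)
    return order


class TestAggregateWeights:
    def test_group_of_137_sums_to_one(self):
        vals = np.ones((137, 2, 3))
        stack = make_stack(vals, groups=["species"] * 137)
        out = assign_aggregate_weights(stack, {"species": 1.0})
        assert np.allclose(out.weights, 1 / 137)
        assert out.weights.sum() == pytest.approx(1.0)

    def test_builtup_cumulative_minus_one_split_equally(self):
        groups = ["species"] * 3 + ["builtup"] * 6
        stack = make_stack(np.ones((9, 2, 2)), groups=groups)
        out = assign_aggregate_weights(stack, {"species": 1.0})
        bu = out.weights[3:]
        assert np.allclose(bu, -1 / 6)
        assert bu.sum() == pytest.approx(-1.0)

    def test_single_feature(self):
        stack = make_stack(np.ones((1, 2, 2)), groups=["g"])
        out = assign_aggregate_weights(stack, {"g": 1.0})
        assert out.weights[0] == 1.0

    def test_missing_group_rejected(self):
        stack = make_stack(np.ones((2, 2, 2)), groups=["a", "b"])
        with pytest.raises(ValueError, match="without an aggregate weight"):
            assign_aggregate_weights(stack, {"a": 1.0})

    def test_empty_group_with_weight_rejected(self):
        stack = make_stack(np.ones((1, 2, 2)), groups=["a"])
        with pytest.raises(ValueError, match="no members"):
            assign_aggregate_weights(stack, {"a": 1.0, "ghost": 0.5})


class TestMarginalLoss:
    def test_linear_case(self):
        # z=1: delta equals the cell's share of the distribution
        stack = make_stack([[[0.2, 0.3], [0.5, 0.0]]])
        state = RankState(np.ones(1))
        assert marginal_loss(0, stack, state, z=1.0) == pytest.approx(0.2)

    def test_empty_cell_costs_nothing(self):
        stack = make_stack([[[0.0, 1.0], [1.0, 1.0]]])
        state = RankState(np.ones(1))
        assert marginal_loss(0, stack, state, z=0.25) == 0.0

    def test_concave_closed_form(self):
        # single feature, p = 0.5, R = 1, z = 0.25: 1 - 0.5**0.25
        stack = make_stack([[[0.5, 0.5]]])
        state = RankState(np.ones(1))
        expected = 1.0 - 0.5**0.25  # = 0.15910358474628545
        assert marginal_loss(0, stack, state, z=0.25) == pytest.approx(
            expected, abs=1e-15)

    def test_removed_cell_rejected(self):
        stack = make_stack([[[0.5, 0.5]]])
        state = RankState(np.ones(1), removed_order=[0])
        with pytest.raises(ValueError, match="removed"):
            marginal_loss(0, stack, state, z=1.0)


class TestRankABF:
    def test_single_feature_ranks_by_ascending_value(self):
        stack = make_stack([[[0.2, 0.3, 0.5]]])
        for z in (0.25, 1.0, 2.0):
            rank = rank_abf(stack, PrioritizerConfig(z=z))
            assert np.allclose(rank.rank[0], [1 / 3, 2 / 3, 1.0])

    def test_ties_break_in_row_major_order(self):
        stack = make_stack([np.full((2, 3), 0.5)])
        rank = rank_abf(stack, PrioritizerConfig(tie_rule="stable_index"))
        assert np.allclose(rank.values_valid, np.arange(1, 7) / 6)

    def test_rank_histogram_is_uniform_permutation(self):
        stack = random_stack(5)
        rank = rank_abf(stack)
        n = stack.n_valid
        assert np.array_equal(np.sort(rank.values_valid), np.arange(1, n + 1) / n)

    def test_negative_weight_layer_gets_lowest_ranks(self):
        rng = np.random.default_rng(8)
        species = rng.uniform(0.1, 1.0, size=(3, 5, 5))
        builtup = np.zeros((5, 5))
        builtup[:2, :2] = 1.0
        species[:, :2, :2] = 0.0  # spatially separable
        stack = make_stack(
            np.concatenate([species, builtup[None]]),
            weights=[1 / 3, 1 / 3, 1 / 3, -1.0],
            groups=["species"] * 3 + ["builtup"],
        )
        rank = rank_abf(stack)
        assert rank.rank[:2, :2].max() < rank.rank[2:, :].min()

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_oracle(self, seed):
        stack = random_stack(seed)
        cfg = PrioritizerConfig(z=0.25 if seed % 2 else 1.0)
        rank = rank_abf(stack, cfg)
        q = stack.feature_matrix().tolist()
        expected = abf_oracle_order(q, stack.weights.tolist(), cfg.z)
        assert rank.removal_order.tolist() == expected

    def test_full_removal_conserves_distributions(self):
        stack = random_stack(17)
        rank = rank_abf(stack)
        p = stack.feature_matrix() / stack.totals
        removed = p[rank.removal_order].sum(axis=0)
        assert np.allclose(removed, 1.0, atol=1e-9)

    def test_doubling_a_weight_never_demotes_its_best_cell(self):
        for seed in range(10):
            stack = random_stack(seed + 100)
            if stack.n_features < 2:
                continue
            j = 0
            best_cell = np.argmax(stack.feature_matrix()[:, j])
            r1 = rank_abf(stack)
            w2 = stack.weights.copy()
            w2[j] *= 2
            r2 = rank_abf(stack.with_weights(w2))
            assert (r2.values_valid[best_cell]
                    >= r1.values_valid[best_cell] - 1e-12)

    def test_batch_removal_approximates_exact_greedy(self):
        stack = random_stack(3)
        exact = rank_abf(stack, PrioritizerConfig(batch_size=1))
        batched = rank_abf(stack, PrioritizerConfig(batch_size=5))
        rho = np.corrcoef(exact.values_valid, batched.values_valid)[0, 1]
        assert rho > 0.9

    def test_all_zero_stack_rejected(self):
        stack = make_stack(np.zeros((1, 2, 2)), weights=[0.0])
        with pytest.raises(ValueError):
            rank_abf(stack)

    def test_seeded_random_ties_are_reproducible(self):
        stack = make_stack([np.full((3, 3), 0.5)])
        cfg = PrioritizerConfig(tie_rule="seeded_random", seed=5)
        a = rank_abf(stack, cfg)
        b = rank_abf(stack, cfg)
        assert np.array_equal(a.rank, b.rank)
        c = rank_abf(stack, PrioritizerConfig(tie_rule="stable_index"))
        assert not np.array_equal(a.rank, c.rank)


class TestRankWithMask:
    def test_mask_occupies_top_ranks(self):
        stack = random_stack(9)
        rng = np.random.default_rng(1)
        mask = rng.uniform(size=stack.shape) < 0.3
        mask &= stack.valid
        if not mask.any():
            mask.ravel()[0] = True
        rank = rank_with_mask(stack, mask)
        k = mask.sum()
        n = stack.n_valid
        assert rank.rank[mask].min() == pytest.approx((n - k + 1) / n)
        assert rank.rank[mask].min() > rank.rank[stack.valid & ~mask].max()

    def test_empty_mask_is_plain_ranking(self):
        stack = random_stack(10)
        a = rank_abf(stack)
        b = rank_with_mask(stack, np.zeros(stack.shape, bool))
        assert np.array_equal(a.rank[stack.valid], b.rank[stack.valid])

    def test_masked_low_value_cell_stays_on_top(self):
        # 4 cells; the mask sits on the lowest-value cell
        stack = make_stack([[[0.1, 0.2], [0.3, 0.4]]])
        mask = np.array([[True, False], [False, False]])
        rank = rank_with_mask(stack, mask)
        assert rank.rank[0, 0] == 1.0
        # the rest follow the ABF (ascending value) order below it
        assert np.allclose(rank.rank, [[1.0, 0.25], [0.5, 0.75]])

    def test_flatten_sets_mask_ranks_to_one(self):
        stack = make_stack([[[0.1, 0.2], [0.3, 0.4]]])
        mask = np.array([[True, False], [True, False]])
        rank = rank_with_mask(stack, mask, flatten_mask_rank=True)
        assert np.all(rank.rank[mask] == 1.0)

    def test_full_mask_rejected(self):
        stack = make_stack([[[0.1, 0.2], [0.3, 0.4]]])
        with pytest.raises(ValueError, match="mask"):
            rank_with_mask(stack, np.ones(stack.shape, bool))
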