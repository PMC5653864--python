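"""Rate machinery against independent oracles: exhaustive-enumeration ASR,
Fitch parsimony lower bound, numeric likelihood maximization for the LRT,
and hand-applied Benjamini-Hochberg."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from paleotempo import (
    CharacterMatrix,
    TimeTree,
    Timescale,
    aggregate_over_trees,
    bh_adjust,
    bin_lrt,
    branch_rate,
    count_branch_changes,
    mk_asr,
    mk_asr_all,
    partition_by_bins,
    rate_trend,
)
from paleotempo.data_io import TimeBin
from paleotempo.rates import BinSegmentTable, RateAnalysisError

from conftest import random_matrix, random_time_tree


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def mk_p(same: bool, k: int, rate: float, t: float) -> float:
    """Closed-form symmetric Mk transition probability (oracle copy)."""
    a = np.exp(-k * rate * t / (k - 1))
    return 1 / k + (k - 1) / k * a if same else (1 - a) / k


def enumeration_marginals(tree: TimeTree, tip_states: dict, k: int, rate: float):
    """Brute-force marginal ancestral probabilities: sum the joint likelihood
    over every assignment of states to internal nodes (flat 1/k root prior).
    MISSING tips (state None) are summed over as well."""
    internals = [i for i in range(tree.n_nodes) if not tree.is_tip[i]]
    free_tips = [
        int(i) for i in tree.tip_indices if tip_states[tree.labels[int(i)]] is None
    ]
    free = internals + free_tips
    post = {i: np.zeros(k) for i in range(tree.n_nodes)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(free)):
        st = dict(zip(free, assign))
        for i in tree.tip_indices:
            s = tip_states[tree.labels[int(i)]]
            if s is not None:
                st[int(i)] = s
        lik = 1.0 / k
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            lik *= mk_p(st[i] == st[tree.parent[i]], k, rate, float(tree.duration[i]))
        total += lik
        for i in range(tree.n_nodes):
            post[i][st[i]] += lik
    return {i: post[i] / total for i in post}, total


def fitch_steps(tree: TimeTree, states: dict) -> int:
    """Fitch small-parsimony step count (unordered states, scored tips only;
    oracle restricted to trees whose internal nodes all have 2 children)."""
    sets = {}
    steps = 0
    for i in tree.postorder:
        i = int(i)
        if tree.is_tip[i]:
            sets[i] = {states[tree.labels[i]]}
        else:
            a, b = (sets[c] for c in tree.children[i])
            inter = a & b
            if inter:
                sets[i] = inter
            else:
                sets[i] = a | b
                steps += 1
    return steps


def numeric_lrt(Cb, Tb, Cr, Tr) -> float:
    """LRT statistic via numeric maximization of the (gamma-generalized)
    Poisson likelihoods, no closed-form MLEs."""

    def negll(lam, C, T):
        lam = float(lam)
        return -(special.xlogy(C, lam * T) - lam * T - special.gammaln(C + 1))

    def best(C, T):
        res = optimize.minimize_scalar(
            negll, args=(C, T), bounds=(1e-12, 1e3), method="bounded",
            options={"xatol": 1e-13},
        )
        return -res.fun

    l1 = best(Cb, Tb) + best(Cr, Tr)

    def negll0(lam):
        return negll(lam, Cb, Tb) + negll(lam, Cr, Tr)

    res0 = optimize.minimize_scalar(
        negll0, bounds=(1e-12, 1e3), method="bounded", options={"xatol": 1e-13}
    )
    return 2 * (l1 + res0.fun)


def _matrix_from_states(labels, columns):
    cols = np.array(columns).T
    syms = [sorted({str(s) for s in col if s >= 0} | {"0", "1"}) for col in cols.T]
    return CharacterMatrix(
        taxon_labels=list(labels),
        state_symbols=[[str(j) for j in range(int(max(col.max() + 1, 2)))] for col in cols.T],
        codes=cols,
    )


# ---------------------------------------------------------------------------
# mk_asr
# ---------------------------------------------------------------------------


class TestMkASR:
    def test_concordant_tips_reconstruct_shared_state(self, cherry_tree):
        m = CharacterMatrix(["A", "B"], [["0", "1"]], np.array([[0], [0]]))
        with pytest.raises(RateAnalysisError):
            mk_asr(cherry_tree, m, 0)  # invariant on these tips -> excluded

    def test_two_state_symmetry_gives_even_root(self, cherry_tree):
        m = CharacterMatrix(["A", "B"], [["0", "1"]], np.array([[0], [1]]))
        res = mk_asr(cherry_tree, m, 0, rate=0.05)
        root_marg = res.marginals[cherry_tree.root]
        assert root_marg[0] == pytest.approx(0.5, abs=1e-12)
        assert res.map_state[cherry_tree.root] == 0  # tie -> lowest symbol

    def test_map_at_scored_tips_matches_observation(self, four_tip_tree):
        m = CharacterMatrix(
            ["A", "B", "C", "D"], [["0", "1"]], np.array([[0], [1], [1], [0]])
        )
        res = mk_asr(four_tip_tree, m, 0, rate=0.02)
        for i, lbl in zip(four_tip_tree.tip_indices, four_tip_tree.tip_labels):
            assert res.map_state[int(i)] == m.codes[m.taxon_labels.index(lbl), 0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_marginals_match_enumeration_with_missing(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_time_tree(rng, 4)
        k = 3
        # all k states observed among scored tips (k = observed state count)
        states = [0, 1, 2, int(rng.integers(0, k))]
        tips = dict(zip(tree.tip_labels, states))
        tips[tree.tip_labels[3]] = None  # one MISSING tip
        codes = np.array(
            [[tips[l] if tips[l] is not None else -1] for l in tree.tip_labels]
        )
        m = CharacterMatrix(
            list(tree.tip_labels), [[str(i) for i in range(k)]], codes
        )
        rate = 0.5 / tree.total_branch_length() * 4
        res = mk_asr(tree, m, 0, rate=rate)
        oracle, _ = enumeration_marginals(tree, tips, k, rate)
        for i in range(tree.n_nodes):
            if not tree.is_tip[i]:
                assert np.allclose(res.marginals[i], oracle[i], atol=1e-10)

    def test_fitted_rate_beats_neighbours(self, rng):
        tree = random_time_tree(rng, 8)
        m = random_matrix(rng, 8, 5, p_miss=0.0)
        m.taxon_labels = list(tree.tip_labels)
        res = mk_asr(tree, m, 0)
        ll = res.loglik
        for r in (res.rate * 0.5, res.rate * 2.0):
            assert mk_asr(tree, m, 0, rate=r).loglik <= ll + 1e-9


# ---------------------------------------------------------------------------
# branch changes and rates
# ---------------------------------------------------------------------------


class TestBranchChanges:
    def test_change_scored_when_endpoint_states_differ(self, cherry_tree):
        m = CharacterMatrix(
            ["A", "B"], [["0", "1"], ["0", "1"]], np.array([[0, 0], [1, -1]])
        )
        asr = mk_asr_all(cherry_tree, m)  # char 1 invariant-after-missing
        table = count_branch_changes(cherry_tree, m, asr)
        # char 0: root MAP is one of {0,1}; exactly one tip differs from it
        assert table.changes.sum() == 1
        # the MISSING tip cell is not comparable on that terminal branch
        row_b = list(table.node).index(
            int(cherry_tree.tip_indices[cherry_tree.tip_labels.index("B")])
        )
        assert table.n_comparable[row_b] == 1

    def test_complete_binary_changes_bounded_by_fitch(self, rng):
        """Endpoint-MAP total steps >= the minimum (Fitch) parsimony steps."""
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            tree = random_time_tree(r2, 6)
            m = random_matrix(r2, 6, 8, p_miss=0.0, max_states=3)
            m.taxon_labels = list(tree.tip_labels)
            info = np.flatnonzero(m.informative_mask())
            asr = mk_asr_all(tree, m)
            table = count_branch_changes(tree, m, asr)
            fitch_total = sum(
                fitch_steps(tree, {l: int(m.codes[m.taxon_labels.index(l), k])
                                   for l in tree.tip_labels})
                for k in info
            )
            assert table.changes.sum() >= fitch_total

    def test_branch_rate_formula(self):
        assert branch_rate(3, 5.0, 0.6) == pytest.approx(1.0)
        assert branch_rate(0, 5.0, 0.6) == 0.0
        assert np.isnan(branch_rate(2, 0.0, 0.6))
        assert np.isnan(branch_rate(2, 5.0, 0.0))
        assert branch_rate(3, 5.0, 0.6, n_characters=10) == pytest.approx(0.1)

    def test_branch_rate_inverts_exactly(self, rng):
        for _ in range(50):
            C = rng.integers(0, 30)
            d = rng.uniform(0.1, 20)
            p = rng.uniform(0.05, 1.0)
            assert branch_rate(C, d, p) * d * p == pytest.approx(float(C), abs=1e-9)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------


class TestPartition:
    def _table(self, tree, changes):
        from paleotempo.rates import BranchChangeTable

        nodes = np.array([i for i in range(tree.n_nodes) if i != tree.root])
        nc = 4
        return BranchChangeTable(
            node=nodes,
            duration=tree.duration[nodes],
            n_comparable=np.full(nodes.size, nc),
            changes=np.asarray(changes, dtype=float),
            n_characters=nc,
            change_flags=np.zeros((nodes.size, nc), dtype=bool),
        )

    def test_even_split_across_two_bins(self):
        tree = TimeTree(np.array([-1, 0]), np.array([20.0, 0.0]), [None, "A"])
        ts = Timescale([TimeBin("old", 20, 10), TimeBin("young", 10, 0)])
        seg = partition_by_bins(self._table(tree, [2.0]), tree, ts)
        assert np.allclose(seg.changes, [1.0, 1.0])
        assert np.allclose(seg.opportunity, [10.0, 10.0])

    def test_containment_in_single_bin(self):
        tree = TimeTree(np.array([-1, 0]), np.array([8.0, 3.0]), [None, "A"])
        ts = Timescale([TimeBin("old", 20, 10), TimeBin("young", 10, 0)])
        seg = partition_by_bins(self._table(tree, [3.0]), tree, ts)
        assert seg.changes[1] == pytest.approx(3.0) and seg.changes[0] == 0.0

    def test_conservation_on_random_trees(self, rng):
        for _ in range(10):
            tree = random_time_tree(rng, 10)
            ts = Timescale.equal_bins(tree.root_age, tree.youngest_tip_age, 6)
            changes = rng.integers(0, 5, size=tree.n_nodes - 1).astype(float)
            table = self._table(tree, changes)
            seg = partition_by_bins(table, tree, ts)
            kept = ~np.isin(
                table.node, [e["node"] for e in seg.excluded_branches]
            )
            assert seg.changes.sum() == pytest.approx(changes[kept].sum(), abs=1e-9)
            assert seg.opportunity.sum() == pytest.approx(
                (table.duration * table.proportion_comparable)[kept].sum(), abs=1e-9
            )

    def test_out_of_span_branch_errors_unless_extended(self):
        tree = TimeTree(np.array([-1, 0]), np.array([25.0, 5.0]), [None, "A"])
        ts = Timescale([TimeBin("only", 20, 0)])
        table = self._table(tree, [1.0])
        with pytest.raises(RateAnalysisError, match="outside"):
            partition_by_bins(table, tree, ts)
        seg = partition_by_bins(table, tree, ts, extend_edges=True)
        assert seg.changes[0] == pytest.approx(1.0)
        assert seg.opportunity[0] == pytest.approx(20.0)

    def test_midpoint_allocation_whole_branch(self):
        tree = TimeTree(np.array([-1, 0]), np.array([12.0, 8.0]), [None, "A"])
        ts = Timescale([TimeBin("old", 20, 10), TimeBin("young", 10, 0)])
        seg = partition_by_bins(self._table(tree, [2.0]), tree, ts, allocation="midpoint")
        assert seg.changes.tolist() == [2.0, 0.0]  # midpoint 10 Ma -> older bin


# ---------------------------------------------------------------------------
# LRT, B-H, aggregation, trend
# ---------------------------------------------------------------------------


class TestBinLRT:
    def test_identical_rates_give_zero_statistic(self):
        seg = BinSegmentTable(["a", "b"], np.array([10.0, 20.0]), np.array([5.0, 10.0]))
        stat, p, _ = bin_lrt(seg, 0)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_statistic_matches_numeric_maximization(self):
        seg = BinSegmentTable(["a", "b"], np.array([10.0, 10.0]), np.array([20.0, 10.0]))
        stat, p, direction = bin_lrt(seg, 0)
        assert stat == pytest.approx(numeric_lrt(20, 10, 10, 10), abs=1e-8)
        assert direction == "high"
        assert p == pytest.approx(stats.chi2.sf(stat, 1))

    def test_zero_opportunity_reports_na(self):
        seg = BinSegmentTable(["a", "b"], np.array([0.0, 10.0]), np.array([0.0, 5.0]))
        stat, p, direction = bin_lrt(seg, 0)
        assert np.isnan(stat) and np.isnan(p) and direction == "na"

    def test_monotone_in_focal_count(self, rng):
        """More changes at fixed opportunity never lowers rate or the
        high-direction statistic."""
        T = np.array([15.0, 40.0])
        last = -np.inf
        for C in np.linspace(30, 60, 7):  # focal rate above remainder
            seg = BinSegmentTable(["a", "b"], T, np.array([C, 20.0]))
            stat, _, direction = bin_lrt(seg, 0)
            assert direction == "high"
            assert stat >= last - 1e-12
            last = stat

    @pytest.mark.parametrize("seed", range(4))
    def test_random_instances_match_numeric_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            Cb, Cr = rng.uniform(0.5, 40, size=2)
            Tb, Tr = rng.uniform(1, 60, size=2)
            seg = BinSegmentTable(["a", "b"], np.array([Tb, Tr]), np.array([Cb, Cr]))
            stat, _, _ = bin_lrt(seg, 0)
            assert stat == pytest.approx(numeric_lrt(Cb, Tb, Cr, Tr), abs=1e-8)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        adj, rej = bh_adjust([0.004], alpha=0.01)
        assert adj[0] == pytest.approx(0.004)
        assert rej[0]

    def test_step_up_hand_example(self):
        adj, rej = bh_adjust([0.001, 0.02, 0.03], alpha=0.01)
        # hand application: sorted p (0.001, 0.02, 0.03), adjusted
        # (0.003, 0.03, 0.03); only the first clears alpha=0.01
        assert np.allclose(adj, [0.003, 0.03, 0.03])
        assert rej.tolist() == [True, False, False]

    def test_ties_adjust_together(self):
        adj, rej = bh_adjust([0.02, 0.02, 0.02], alpha=0.05)
        assert np.allclose(adj, 0.02)
        assert rej.all()

    def test_nan_passthrough(self):
        adj, rej = bh_adjust([0.001, np.nan], alpha=0.01)
        assert np.isnan(adj[1]) and not rej[1] and rej[0]

    def test_matches_hand_stepup_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(2, 12))
            adj, _ = bh_adjust(p)
            m = p.size
            order = np.argsort(p)
            hand = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            hand_full = np.empty(m)
            hand_full[order] = np.minimum(hand, 1.0)
            assert np.allclose(adj, hand_full)


class TestAggregation:
    def _df(self, sig, direction, rate=1.0):
        return pd.DataFrame(
            {
                "bin": ["b1"],
                "changes": [1.0],
                "opportunity": [1.0],
                "rate": [rate],
                "rate_per_char": [rate],
                "lrt_stat": [1.0],
                "p": [0.005],
                "p_adj": [0.005],
                "direction": [direction],
                "significant": [sig],
            }
        )

    def test_majority_high_is_high(self):
        dfs = [self._df(True, "high")] * 60 + [self._df(False, "low")] * 40
        res = aggregate_over_trees(dfs, threshold=0.55)
        assert res.summary["class"][0] == "HIGH"

    def test_exact_threshold_is_background(self):
        dfs = [self._df(True, "high")] * 55 + [self._df(False, "low")] * 45
        res = aggregate_over_trees(dfs, threshold=0.55)
        assert res.summary["frac_high"][0] == pytest.approx(0.55)
        assert res.summary["class"][0] == "BACKGROUND"  # strict inequality

    def test_split_verdicts_are_background(self):
        dfs = (
            [self._df(True, "high")] * 30
            + [self._df(True, "low")] * 30
            + [self._df(False, "high")] * 40
        )
        res = aggregate_over_trees(dfs, threshold=0.55)
        assert res.summary["class"][0] == "BACKGROUND"

    def test_rate_interval_is_percentile_based(self):
        dfs = [self._df(False, "high", rate=r) for r in np.linspace(0, 1, 101)]
        res = aggregate_over_trees(dfs)
        assert res.summary["lo95_rate"][0] == pytest.approx(0.025)
        assert res.summary["hi95_rate"][0] == pytest.approx(0.975)


class TestRateTrend:
    def test_perfect_decline_gives_minus_one(self):
        out = rate_trend([5, 4, 3, 2, 1], [50, 40, 30, 20, 10])
        assert out["rho"] == pytest.approx(-1.0)

    def test_matches_rank_formula_without_ties(self, rng):
        rates = rng.permutation(10).astype(float)
        mids = np.linspace(100, 10, 10)
        out = rate_trend(rates, mids)
        ranks_t = stats.rankdata(-mids)
        ranks_r = stats.rankdata(rates)
        d2 = ((ranks_t - ranks_r) ** 2).sum()
        rho_hand = 1 - 6 * d2 / (10 * (100 - 1))
        assert out["rho"] == pytest.approx(rho_hand)

    def test_constant_series_is_na(self):
        out = rate_trend([1.0] * 6, np.linspace(60, 10, 6))
        assert np.isnan(out["rho"])

    def test_too_few_bins_error(self):
        with pytest.raises(RateAnalysisError, match=">= 4"):
            rate_trend([1, 2, np.nan, np.nan, np.nan], [5, 4, 3, 2, 1])
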