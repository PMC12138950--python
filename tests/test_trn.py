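import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metaregnet.trn import (
    Network,
    TrnError,
    TrnParams,
    apply_dpi,
    assign_edge_sign,
    bootstrap_support,
    infer_network,
    mutual_information,
    permutation_adjusted_p,
    rank_bins,
)


def brute_force_mi(x, y, B):
    """Independent oracle: explicit contingency-table MI on rank bins."""
    bx, by = rank_bins(np.asarray(x, float), B), rank_bins(np.asarray(y, float), B)
    n = len(bx)
    mi = 0.0
    for i in range(B):
        for j in range(B):
            c = np.sum((bx == i) & (by == j))
            if c:
                px = np.sum(bx == i) / n
                py = np.sum(by == j) / n
                mi += (c / n) * np.log2((c / n) / (px * py))
    return mi


class TestMutualInformation:
    def test_identity_is_log2_bins(self):
        x = np.arange(100.0)
        assert mutual_information(x, x, 10) == pytest.approx(np.log2(10), abs=1e-12)

    def test_rank_invariance_under_negation_and_monotone_maps(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(size=80)
        base = mutual_information(x, y, 8)
        assert mutual_information(x, -y, 8) == pytest.approx(base, abs=1e-12)
        assert mutual_information(np.exp(x), y**3 + 5 * y, 8) == pytest.approx(
            base, abs=1e-12
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        ours = mutual_information(x, y, 2)
        assert ours == pytest.approx(mutual_information(y, x, 2), abs=1e-12)
        assert ours == pytest.approx(brute_force_mi(x, y, 2), abs=1e-12)

    def test_independent_vectors_have_small_mi(self, rng):
        x = rng.uniform(size=10_000)
        y = rng.uniform(size=10_000)
        assert mutual_information(x, y, 10) <= 0.02

    def test_constant_input_returns_zero(self):
        assert mutual_information(np.ones(20), np.arange(20.0)) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(TrnError):
            mutual_information(np.arange(5.0), np.arange(5.0))


def _frame(rows, n, rng):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=[f"s{j}" for j in range(n)])


class TestPermutationFilter:
    def test_deterministic_pair_hits_empirical_floor(self, rng):
        n = 60
        x = rng.normal(size=n)
        others = rng.normal(size=(6, n))
        df = pd.DataFrame(np.vstack([x, x + 0.0, others]),
                          index=["tf", "copy"] + [f"g{i}" for i in range(6)],
                          columns=[f"s{j}" for j in range(n)])
        params = TrnParams(n_perm=100, pool_across_tfs=False, seed=5)
        out = permutation_adjusted_p(df, ["tf"], params)
        row = out[out["target"] == "copy"].iloc[0]
        assert row["p"] == pytest.approx(1.0 / (1 + 100 * 7))

    def test_pooled_floor_with_cross_tf_pooling(self, rng):
        n = 60
        x = rng.normal(size=n)
        df = pd.DataFrame(np.vstack([x, x, rng.normal(size=(4, n))]),
                          index=["tf", "copy"] + [f"g{i}" for i in range(4)],
                          columns=[f"s{j}" for j in range(n)])
        params = TrnParams(n_perm=100, seed=5)
        out = permutation_adjusted_p(df, ["tf"], params)
        row = out[out["target"] == "copy"].iloc[0]
        assert row["p"] == pytest.approx(1.0 / (1 + 100 * 5))

    def test_type_one_error_controlled_under_global_null(self, rng):
        # global null: 500 independent genes, 5 TFs, BH level 0.05
        n = 100
        df = _frame(rng.normal(size=(500, n)), n, rng)
        params = TrnParams(n_perm=200, adj_p_cutoff=0.05, seed=11)
        out = permutation_adjusted_p(df, [f"g{i}" for i in range(5)], params)
        frac = (out["adj_p"] < 0.05).mean()
        assert frac <= 0.05

    def test_small_n_perm_rejected(self, rng):
        df = _frame(rng.normal(size=(3, 20)), 20, rng)
        with pytest.raises(TrnError):
            permutation_adjusted_p(df, ["g0"], TrnParams(n_perm=5))


class TestBootstrapSupport:
    def test_deterministic_edge_has_full_support(self, rng):
        n = 50
        x = rng.normal(size=n)
        df = pd.DataFrame(np.vstack([x, 2 * x + 1, rng.normal(size=(5, n))]),
                          index=["tf", "dup"] + [f"g{i}" for i in range(5)],
                          columns=[f"s{j}" for j in range(n)])
        cand = pd.DataFrame({"tf": ["tf"], "target": ["dup"]})
        params = TrnParams(n_boot=100, n_perm_boot=10, seed=2)
        support = bootstrap_support(df, cand, params)
        assert support.loc[("tf", "dup")] == 1.0

    def test_null_edge_has_low_support(self, rng):
        n = 50
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        df = pd.DataFrame(np.vstack([x, 2 * x, noise, rng.normal(size=(4, n))]),
                          index=["tf", "dup", "null"] + [f"g{i}" for i in range(4)],
                          columns=[f"s{j}" for j in range(n)])
        cand = pd.DataFrame({"tf": ["tf", "tf"], "target": ["dup", "null"]})
        params = TrnParams(n_boot=200, n_perm_boot=10, seed=2)
        support = bootstrap_support(df, cand, params)
        assert support.loc[("tf", "null")] < 0.5
        assert support.loc[("tf", "dup")] > 0.95


class TestDpi:
    def _edges(self, triples):
        return pd.DataFrame(triples, columns=["tf", "target", "mi"])

    def test_weak_chain_shortcut_removed(self):
        e = self._edges([("A", "B", 0.5), ("B", "C", 0.4), ("A", "C", 0.1)])
        out = apply_dpi(e)
        assert set(map(tuple, out[["tf", "target"]].values)) == {("A", "B"), ("B", "C")}

    def test_exact_ties_kept(self):
        e = self._edges([("A", "B", 0.3), ("B", "C", 0.3), ("A", "C", 0.3)])
        assert len(apply_dpi(e)) == 3

    def test_tolerance_protects_near_ties(self):
        e = self._edges([("A", "B", 0.31), ("B", "C", 0.35), ("A", "C", 0.30)])
        assert len(apply_dpi(e, tolerance=0.05)) == 3
        assert len(apply_dpi(e, tolerance=0.0)) == 2

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_never_grows_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list("ABCDEF")
        pairs = list(itertools.combinations(nodes, 2))
        keep = rng.random(len(pairs)) < 0.6
        e = self._edges([
            (a, b, float(rng.uniform(0.05, 1.0)))
            for (a, b), k in zip(pairs, keep) if k
        ])
        once = apply_dpi(e)
        assert len(once) <= len(e)
        pd.testing.assert_frame_equal(apply_dpi(once), once)


class TestSignAssignment:
    def test_perfect_signs(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame(np.vstack([x, 3 * x, -2 * x]),
                          index=["a", "up", "down"],
                          columns=[f"s{i}" for i in range(30)])
        assert assign_edge_sign(df, "a", "up") == 1
        assert assign_edge_sign(df, "a", "down") == -1

    def test_constant_profile_unsigned(self):
        df = pd.DataFrame([[1.0] * 10, list(range(10))], index=["flat", "x"],
                          columns=[f"s{i}" for i in range(10)])
        assert assign_edge_sign(df, "flat", "x") == 0

    def test_planted_negative_sign_recovered(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.normal(size=100)
            y = -x + 0.1 * rng.normal(size=100)
            df = pd.DataFrame(np.vstack([x, y]), index=["tf", "t"],
                              columns=[f"s{i}" for i in range(100)])
            hits += assign_edge_sign(df, "tf", "t") == -1
        assert hits >= 99


class TestInferNetwork:
    def _chain_matrix(self, rng, n=80):
        a = rng.normal(size=n)
        b = a + 0.25 * rng.normal(size=n)
        c = b + 0.25 * rng.normal(size=n)
        rest = rng.normal(size=(3, n))
        return pd.DataFrame(np.vstack([a, b, c, rest]),
                            index=["A", "B", "C", "x1", "x2", "x3"],
                            columns=[f"s{j}" for j in range(n)])

    def test_recovers_chain_and_prunes_shortcut(self, rng):
        df = self._chain_matrix(rng)
        params = TrnParams(n_perm=200, adj_p_cutoff=0.05, n_boot=100,
                           n_perm_boot=10, mi_bins=4, seed=3)
        net = infer_network(df, ["A", "B"], params)
        found = set(map(tuple, net.edges[["tf", "target"]].values))
        assert ("A", "B") in found and ("B", "C") in found
        assert ("A", "C") not in found  # DPI removes the indirect shortcut

    def test_deterministic_under_seed(self, rng):
        df = self._chain_matrix(rng)
        params = TrnParams(n_perm=100, adj_p_cutoff=0.05, n_boot=50,
                           n_perm_boot=10, mi_bins=4, seed=9)
        n1 = infer_network(df, ["A", "B"], params)
        n2 = infer_network(df, ["A", "B"], params)
        pd.testing.assert_frame_equal(n1.edges, n2.edges)

    def test_empty_tf_list_rejected(self, rng):
        df = self._chain_matrix(rng)
        with pytest.raises(TrnError):
            infer_network(df, [], TrnParams())

    def test_network_invariants(self):
        edges = pd.DataFrame({"tf": ["a", "a"], "target": ["b", "b"],
                              "mi": [0.1, 0.2], "sign": [1, 1],
                              "adj_p": [0.01, 0.01], "support": [1.0, 1.0]})
        with pytest.raises(TrnError, match="duplicate"):
            Network(edges, ("a",), ("a", "b"))
        with pytest.raises(TrnError, match="outside"):
            Network(edges.iloc[:1], ("zz",), ("a", "b"))
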