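"""Sankoff ancestral counts, branch deltas, PGLS, family filtering."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest

from _oracles import (ols_slope_intercept, parsimony_min_cost,
                      random_tuple_tree, tuple_to_newick, wagner_root_interval)
from orsel.errors import ConfigurationError
from orsel.gene_family_dynamics import (branch_deltas, filter_families,
                                        pgls_fit, phylo_covariance,
                                        sankoff_counts)
from orsel.treeio import parse_newick


class TestSankoff:
    def test_constant_character_costs_nothing(self, balanced4):
        anc = sankoff_counts(balanced4, {s: 7 for s in "ABCD"}, max_count=10)
        assert anc.cost == 0
        assert all(v == 7 for v in anc.states.values())

    def test_three_leaf_example_matches_enumeration(self, species_abc):
        counts = {"A": 2, "B": 4, "C": 10}
        anc = sankoff_counts(species_abc, counts)
        leaf_states = {species_abc.leaf_index()[s]: c for s, c in counts.items()}
        oracle = parsimony_min_cost(species_abc.parent, leaf_states, 11)
        assert anc.cost == oracle
        # root within the Farris interval of the only internal reconstruction
        assert 2 <= anc.states[species_abc.root] <= 10

    def test_two_leaf_interval_midpoint_tiebreak(self):
        t = parse_newick("(A:1,B:1);")
        anc = sankoff_counts(t, {"A": 0, "B": 6})
        assert anc.cost == 6
        assert anc.states[t.root] == 3  # midpoint of [0, 6], rounded down

    def test_missing_leaf_and_bad_cap_raise(self, species_abc):
        with pytest.raises(ConfigurationError):
            sankoff_counts(species_abc, {"A": 1, "B": 2})
        with pytest.raises(ConfigurationError):
            sankoff_counts(species_abc, {"A": 1, "B": 2, "C": 9}, max_count=5)

    @pytest.mark.parametrize("newick", [
        "((A:1,B:1):1,C:1);",
        "((A:1,B:1):1,(C:1,D:1):1);",
        "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);",
        "((((A:1,B:1):1,C:1):1,D:1):1,(E:1,F:1):1);",
    ])
    def test_exhaustive_enumeration_oracle(self, newick):
        tree = parse_newick(newick)
        labels = tree.leaf_labels
        r = random.Random(hash(newick) & 0xFFFF)
        for _ in range(60):
            counts = {s: r.randint(0, 6) for s in labels}
            anc = sankoff_counts(tree, counts, max_count=6)
            leaf_states = {tree.leaf_index()[s]: c for s, c in counts.items()}
            assert anc.cost == parsimony_min_cost(tree.parent, leaf_states, 7)

    def test_linear_cost_root_in_wagner_interval(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        r = random.Random(3)
        for _ in range(40):
            counts = {s: r.randint(0, 6) for s in "ABCDE"}
            anc = sankoff_counts(tree, counts, max_count=6)
            leaf_states = {tree.leaf_index()[s]: c for s, c in counts.items()}
            lo, hi = wagner_root_interval(tree.parent, tree.children, leaf_states)
            assert lo <= anc.states[tree.root] <= hi

    def test_custom_cost_matrix(self, species_abc):
        # asymmetric: losses free, gains cost 1 per copy
        S = 11
        C = np.zeros((S, S))
        for i in range(S):
            for j in range(S):
                C[i, j] = max(j - i, 0)
        anc = sankoff_counts(species_abc, {"A": 2, "B": 4, "C": 10},
                             cost=C, max_count=10)
        leaf_states = {species_abc.leaf_index()[s]: c
                       for s, c in {"A": 2, "B": 4, "C": 10}.items()}
        oracle = parsimony_min_cost(species_abc.parent, leaf_states, S,
                                    cost=lambda i, j: max(j - i, 0))
        assert anc.cost == oracle


class TestBranchDeltas:
    def test_constant_character_all_zero(self, balanced4):
        anc = sankoff_counts(balanced4, {s: 3 for s in "ABCD"})
        assert set(branch_deltas(anc).values()) == {0}

    def test_sum_abs_delta_equals_cost(self, rng):
        r = random.Random(9)
        tup = random_tuple_tree(r, list("ABCDEFG"))
        tree = parse_newick(tuple_to_newick(tup))
        for _ in range(25):
            counts = {s: int(rng.integers(0, 12)) for s in "ABCDEFG"}
            anc = sankoff_counts(tree, counts)
            deltas = branch_deltas(anc)
            assert sum(abs(d) for d in deltas.values()) == anc.cost


class TestPGLS:
    def star(self, n=8):
        tips = ",".join(f"t{i}:1.0" for i in range(n))
        return parse_newick(f"({tips});"), [f"t{i}" for i in range(n)]

    def test_star_tree_lambda1_equals_ols(self, rng):
        tree, sp = self.star()
        x = rng.normal(size=8)
        y = 2.0 * x + rng.normal(size=8)
        fit = pgls_fit(tree, x, y, sp, lambda_mode="fixed", lam=1.0)
        slope, intercept, se_s, se_i = ols_slope_intercept(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-8)
        assert fit.intercept == pytest.approx(intercept, abs=1e-8)
        assert fit.slope_se == pytest.approx(se_s, abs=1e-8)

    def test_perfect_fit_recovers_exact_line(self, balanced4):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = pgls_fit(balanced4, x, 3.0 * x, list("ABCD"))
        assert fit.slope == pytest.approx(3.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_lambda0_equals_ols_on_ultrametric_tree(self, rng):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        x = rng.normal(size=4)
        y = rng.normal(size=4)
        fit = pgls_fit(tree, x, y, list("ABCD"), lam=0.0)
        slope, intercept, *_ = ols_slope_intercept(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-8)
        assert fit.intercept == pytest.approx(intercept, abs=1e-8)

    def test_covariance_is_shared_path_length(self, balanced4):
        V = phylo_covariance(balanced4, list("ABCD"))
        assert V[0, 1] == pytest.approx(1.0)   # A,B share the root->AB branch
        assert V[0, 2] == pytest.approx(0.0)   # A,C diverge at the root
        assert np.allclose(np.diag(V), 2.0)

    def test_ml_lambda_recovers_brownian_on_clean_data(self, rng):
        # strongly phylogenetic residuals: ML lambda should land near 1
        text = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        tree = parse_newick(text)
        sp = list("ABCDEFGH")
        V = phylo_covariance(tree, sp)
        L = np.linalg.cholesky(V)
        lams = []
        for _ in range(20):
            x = rng.normal(size=8)
            y = 1.5 * x + L @ rng.normal(size=8)
            lams.append(pgls_fit(tree, x, y, sp, lambda_mode="ML").lam)
        assert np.median(lams) > 0.5

    def test_planted_slope_recovered_on_brownian_replicates(self, rng):
        text = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        tree = parse_newick(text)
        sp = list("ABCDEFGH")
        V = phylo_covariance(tree, sp)
        L = np.linalg.cholesky(V)
        beta = 1.3
        est = []
        for _ in range(200):
            x = L @ rng.normal(size=8)
            y = beta * x + L @ rng.normal(size=8)
            est.append(pgls_fit(tree, x, y, sp).slope)
        mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - beta) < 2 * mc_se


class TestFilterFamilies:
    def frame(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "all_single": np.ones(10, dtype=int),
            "expanded": np.full(10, 40),
            "boundary": [0, 1, 1, 1, 1, 1, 1, 1, 5, 6],  # 80% <= 1: kept
            "mostly_single": [1, 1, 1, 1, 1, 1, 1, 1, 1, 9],  # 90% <= 1
        }, index=[f"s{i}" for i in range(10)])

    def test_threshold_is_strict(self):
        kept = filter_families(self.frame(), single_copy_frac=0.8)
        assert list(kept.columns) == ["expanded", "boundary"]
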