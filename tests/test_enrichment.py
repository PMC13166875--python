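"""Length normalization, contingency tallies, hypergeometric tails, BH."""

import numpy as np
import pandas as pd
import pytest

from _oracles import bh_stepup, hypergeom_tails
from orsel.errors import (DegenerateLengthsError, EmptyPopulationError,
                          UnknownBranchError)
from orsel.selection_enrichment import (ContingencyTally, TransitionSet,
                                        bh_correct, enrichment_analysis,
                                        hypergeom_test, normalize_weights,
                                        pool, records_from_frame, tally)


def frame(lengths, pvalues, dataset="d0"):
    return pd.DataFrame({
        "dataset_id": dataset,
        "gene_tree_id": "g0",
        "gene_branch_id": range(len(lengths)),
        "branch_length": lengths,
        "p_value": pvalues,
    })


class TestNormalizeWeights:
    def test_equal_lengths_give_unit_weights(self):
        w = normalize_weights(frame([2, 2, 2], [0.5] * 3))
        assert np.allclose(w, 1.0)

    def test_weights_are_length_over_dataset_mean(self):
        w = normalize_weights(frame([1, 3], [0.5, 0.5]))
        assert np.allclose(w, [0.5, 1.5])

    def test_weights_sum_to_record_count_per_dataset(self, rng):
        lengths = rng.exponential(0.1, 1000)
        df = frame(lengths, rng.uniform(0, 1, 1000))
        df.loc[500:, "dataset_id"] = "d1"
        w = normalize_weights(df)
        for ds, idx in df.groupby("dataset_id").indices.items():
            assert abs(w[idx].sum() - len(idx)) < 1e-6

    def test_all_zero_lengths_raise_or_fall_back(self):
        df = frame([0, 0], [0.1, 0.2])
        with pytest.raises(DegenerateLengthsError):
            normalize_weights(df)
        assert np.allclose(normalize_weights(df, strict=False), 1.0)


class TestTally:
    def test_direct_count_example(self):
        df = frame([1, 1, 1, 1], [0.01, 0.2, 0.04, 0.5])
        w = normalize_weights(df)
        tr = TransitionSet("x", [("d0", 7)])
        assign = np.array([7, 7, 5, 5], dtype=object)
        t = tally(df, w, assign, tr)
        assert (t.N_w, t.K, t.n_w, t.k) == (4, 2, 2, 1)

    def test_empty_draw(self):
        df = frame([1, 1], [0.01, 0.2])
        w = normalize_weights(df)
        t = tally(df, w, np.array([5, 5], dtype=object),
                  TransitionSet("x", [("d0", 7)]))
        assert t.n_w == 0 and t.k == 0

    def test_weighted_rounding_half_to_even(self):
        # lengths [1,1,2]: weights [0.75, 0.75, 1.5]; draw weight 1.5 -> 2
        df = frame([1, 1, 2], [0.01, 0.5, 0.01])
        w = normalize_weights(df)
        t = tally(df, w, np.array([5, 5, 7], dtype=object),
                  TransitionSet("x", [("d0", 7)]))
        assert (t.N_w, t.K, t.n_w, t.k) == (3, 2, 2, 1)

    def test_weighted_success_counts_behind_flag(self):
        df = frame([1, 1, 2], [0.01, 0.5, 0.01])
        w = normalize_weights(df)
        t = tally(df, w, np.array([5, 5, 7], dtype=object),
                  TransitionSet("x", [("d0", 7)]), weighted_successes=True)
        # significant weights: 0.75 + 1.5 -> K = round(2.25) = 2; k = round(1.5) = 2
        assert (t.N_w, t.K, t.n_w, t.k) == (3, 2, 2, 2)

    def test_unknown_transition_member_raises(self):
        df = frame([1, 1], [0.01, 0.2])
        w = normalize_weights(df)
        with pytest.raises(UnknownBranchError):
            tally(df, w, np.array([5, 5], dtype=object),
                  TransitionSet("x", [("d0", 99)]),
                  known_branches={("d0", 5)})

    def test_invariants_survive_rounding(self, rng):
        for _ in range(50):
            m = rng.integers(2, 40)
            df = frame(rng.exponential(1.0, m), rng.uniform(0, 1, m))
            assign = rng.choice(np.array([3, 5, 7], dtype=object), m)
            w = normalize_weights(df)
            t = tally(df, w, assign, TransitionSet("x", [("d0", 7)]))
            assert 0 <= t.k <= min(t.K, t.n_w) and t.n_w <= t.N_w and t.K <= t.N_w


class TestHypergeomTest:
    def test_expected_and_fold(self):
        r = hypergeom_test(ContingencyTally(20, 5, 8, 2))
        assert r.expected == 2.0 and r.fold == 1.0
        oracle_up, _ = hypergeom_tails(2, 20, 5, 8)
        assert abs(r.p_enrich - oracle_up) < 1e-12

    def test_saturated_case(self):
        r = hypergeom_test(ContingencyTally(5, 5, 5, 5))
        assert r.fold == 1.0 and r.p_enrich == 1.0

    def test_twofold_enrichment_matches_enumeration(self):
        r = hypergeom_test(ContingencyTally(20, 5, 8, 4))
        assert r.fold == 2.0
        up, down = hypergeom_tails(4, 20, 5, 8)
        assert abs(r.p_enrich - up) < 1e-12
        assert abs(r.p_deplete - down) < 1e-12
        assert r.direction == "enrichment" and r.p_reported == r.p_enrich

    def test_depletion_direction_reported(self):
        r = hypergeom_test(ContingencyTally(100, 50, 40, 10))
        assert r.fold < 1 and r.direction == "depletion"
        assert r.p_reported == r.p_deplete

    def test_zero_expected_flags_nan_fold(self):
        r = hypergeom_test(ContingencyTally(10, 0, 5, 0))
        assert np.isnan(r.fold) and r.p_enrich == 1.0

    def test_empty_population_raises(self):
        with pytest.raises(EmptyPopulationError):
            hypergeom_test(ContingencyTally(0, 0, 0, 0))

    def test_one_sided_tails_share_point_mass(self, rng):
        for _ in range(100):
            N = int(rng.integers(1, 50))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k_lo = max(0, n + K - N)
            k = int(rng.integers(k_lo, min(K, n) + 1))
            r = hypergeom_test(ContingencyTally(N, K, n, k))
            assert r.p_enrich + r.p_deplete >= 1.0 - 1e-12


class TestPool:
    def test_single_tally_identity(self):
        t = ContingencyTally(10, 1, 2, 1)
        assert pool([t]) == t

    def test_component_sums(self):
        a = ContingencyTally(10, 1, 2, 1)
        b = ContingencyTally(10, 1, 2, 0)
        assert pool([a, b]) == ContingencyTally(20, 2, 4, 1)

    def test_order_invariance(self, rng):
        ts = [ContingencyTally(20, int(rng.integers(0, 5)), int(rng.integers(0, 5)), 0)
              for _ in range(6)]
        perm = list(rng.permutation(len(ts)))
        assert pool(ts) == pool([ts[i] for i in perm])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_correct([0.05]) == pytest.approx([0.05])

    def test_stepup_hand_example(self):
        q = bh_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_stepup_oracle_and_dominates_p(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 30)))
            q = bh_correct(p)
            assert np.allclose(q, bh_stepup(list(p)))
            assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)


class TestAnalysis:
    def test_full_table_pools_members_and_corrects(self, rng):
        m = 400
        df = frame(rng.exponential(0.1, m), rng.uniform(0, 1, m))
        assign = rng.choice(np.array([3, 5, 7, 9], dtype=object), m)
        ts = [TransitionSet("up", [("d0", 7), ("d0", 9)]),
              TransitionSet("down", [("d0", 3)])]
        res = enrichment_analysis(df, assign, ts)
        assert list(res["label"]) == ["up", "down"]
        w = normalize_weights(records_from_frame(df))
        t7 = tally(df, w, assign, TransitionSet("a", [("d0", 7)]))
        t9 = tally(df, w, assign, TransitionSet("b", [("d0", 9)]))
        pooled = res.iloc[0]
        # pooled tally equals member tallies on the union of members
        t_union = tally(df, w, assign, ts[0])
        assert pooled.k == t_union.k == t7.k + t9.k
        assert pooled.K == t_union.K
        assert (res["q"] >= res["p_reported"] - 1e-12).all()


# property tests ------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_property_matches_stepup_oracle(p):
    q = bh_correct(p)
    assert np.allclose(q, bh_stepup(p))
    assert np.all(q >= np.asarray(p) - 1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.integers(min_value=1, max_value=60), st.data())
def test_hypergeom_tails_property(N, data):
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    k = data.draw(st.integers(0, min(K, n)))
    r = hypergeom_test(ContingencyTally(N, K, n, k))
    up, down = hypergeom_tails(k, N, K, n)
    assert r.p_enrich == pytest.approx(up, rel=1e-10, abs=1e-300)
    assert r.p_deplete == pytest.approx(down, rel=1e-10, abs=1e-300)
    assert r.p_enrich + r.p_deplete >= 1.0 - 1e-12
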