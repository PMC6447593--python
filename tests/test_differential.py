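"""Isoform ratios, sqrt-JSD statistic, permutation null and dAS calling."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from splicepav import (
    Condition,
    DasResult,
    call_das,
    ecotype_overlap,
    filter_low_ratio,
    isoform_ratios,
    jsd_sqrt,
    permutation_test,
    score_tss_group,
)
from splicepav.transcriptome import TssGroup

from conftest import one_pair_matrix

FLIGHT = Condition("Col-0", 4, "flight")
GROUND = Condition("Col-0", 4, "ground")
PAIR = (FLIGHT, GROUND)


def group_of(*member_ids):
    return TssGroup("g", "chr1", "+", 100, tuple(member_ids))


# ---------------------------------------------------------------------------
# isoform ratios
# ---------------------------------------------------------------------------

class TestIsoformRatios:
    def test_condition_mean_arithmetic(self):
        m = one_pair_matrix({
            "a": [30] * 4 + [1] * 4,
            "b": [60] * 4 + [1] * 4,
            "c": [10] * 4 + [1] * 4,
        })
        t = isoform_ratios(m, group_of("a", "b", "c"), FLIGHT)
        assert t.ratios == pytest.approx((0.3, 0.6, 0.1))
        assert sum(t.ratios) == pytest.approx(1.0, abs=1e-9)

    def test_singleton_group_ratio_one(self):
        m = one_pair_matrix({"a": [5] * 8})
        t = isoform_ratios(m, group_of("a"), FLIGHT)
        assert t.ratios == pytest.approx((1.0,))

    def test_zero_total_is_undefined(self):
        m = one_pair_matrix({"a": [0] * 8, "b": [0] * 8})
        t = isoform_ratios(m, group_of("a", "b"), FLIGHT)
        assert not t.defined

    def test_member_missing_from_matrix_raises(self):
        m = one_pair_matrix({"a": [1] * 8})
        with pytest.raises(KeyError, match="zz"):
            isoform_ratios(m, group_of("a", "zz"), FLIGHT)

    def test_dominant_member_switch_pattern(self):
        """Three-member group: near-zero minor member plus a majority member
        flipping between flight and ground flips the vector's argmax."""
        m = one_pair_matrix({
            "minor": [2] * 8,
            "up_in_flight": [70] * 4 + [28] * 4,
            "up_in_ground": [28] * 4 + [70] * 4,
        })
        g = group_of("minor", "up_in_flight", "up_in_ground")
        rf = isoform_ratios(m, g, FLIGHT)
        rg = isoform_ratios(m, g, GROUND)
        assert np.argmax(rf.ratios) != np.argmax(rg.ratios)
        assert rf.member_ids[int(np.argmax(rf.ratios))] == "up_in_flight"
        assert rg.member_ids[int(np.argmax(rg.ratios))] == "up_in_ground"

    def test_per_replicate_mean_mode(self):
        # ratios per replicate: (0.5, 0.5), (0.8, 0.2) -> mean (0.65, 0.35)
        m = one_pair_matrix({
            "a": [10, 40, 0, 0, 1, 1, 1, 1],
            "b": [10, 10, 0, 0, 1, 1, 1, 1],
        }, n_rep=2)
        t = isoform_ratios(m, group_of("a", "b"), FLIGHT, mode="per-replicate-mean")
        assert t.ratios == pytest.approx((0.65, 0.35))

    def test_per_replicate_mode_skips_zero_total_replicates(self):
        m = one_pair_matrix({
            "a": [10, 0, 0, 0, 1, 1, 1, 1],
            "b": [30, 0, 0, 0, 1, 1, 1, 1],
        })
        t = isoform_ratios(m, group_of("a", "b"), FLIGHT, mode="per-replicate-mean")
        assert t.ratios == pytest.approx((0.25, 0.75))


class TestFilterLowRatio:
    def _tables(self, flight_ratios, ground_ratios):
        ids = tuple(f"m{i}" for i in range(len(flight_ratios)))
        g = TssGroup("g", "chr1", "+", 1, ids)
        from splicepav.differential import IsoformRatioTable
        tf = IsoformRatioTable(g, FLIGHT, ids, tuple(flight_ratios), True)
        tg = IsoformRatioTable(g, GROUND, ids, tuple(ground_ratios), True)
        return tf, tg

    @pytest.mark.parametrize(
        "rf,rg,kept",
        [
            ((0.005, 0.995), (0.004, 0.996), ["m1"]),          # both below
            ((0.005, 0.995), (0.30, 0.70), ["m0", "m1"]),      # fails "in both"
            ((0.01, 0.99), (0.01, 0.99), ["m0", "m1"]),        # boundary strict <
        ],
    )
    def test_removal_requires_below_epsilon_in_both(self, rf, rg, kept):
        tf, tg = self._tables(rf, rg)
        assert filter_low_ratio(tf, tg, 0.01) == kept

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=8))
    @settings(deadline=None, derandomize=True)
    def test_never_removes_member_at_or_above_epsilon(self, pairs):
        tf, tg = self._tables([p for p, _ in pairs], [q for _, q in pairs])
        kept = set(filter_low_ratio(tf, tg, 0.01))
        for mid, rf, rg in zip(tf.member_ids, tf.ratios, tg.ratios):
            if rf >= 0.01 or rg >= 0.01:
                assert mid in kept

    def test_mismatched_groups_rejected(self):
        tf, _ = self._tables((0.5, 0.5), (0.5, 0.5))
        _, tg = self._tables((0.3, 0.3, 0.4), (0.3, 0.3, 0.4))
        with pytest.raises(ValueError):
            filter_low_ratio(tf, tg)


# ---------------------------------------------------------------------------
# sqrt-JSD
# ---------------------------------------------------------------------------

def jsd_sqrt_oracle(p, q):
    """Direct summation of the JSD formula, log base 2 (test-local oracle)."""
    total = 0.0
    for pi, qi in zip(p, q):
        mi = 0.5 * (pi + qi)
        if pi > 0:
            total += 0.5 * pi * math.log2(pi / mi)
        if qi > 0:
            total += 0.5 * qi * math.log2(qi / mi)
    return math.sqrt(max(total, 0.0))


@st.composite
def ratio_vector_pairs(draw):
    n = draw(st.integers(2, 6))
    def vec():
        raw = draw(st.lists(st.floats(1e-6, 1.0), min_size=n, max_size=n))
        s = sum(raw)
        return [x / s for x in raw]
    return vec(), vec()


class TestJsdSqrt:
    def test_identical_vectors_give_zero(self):
        assert jsd_sqrt([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_disjoint_two_isoform_vectors_give_one(self):
        # closed form: M = (1/2, 1/2), KL(p||M) = KL(q||M) = 1 bit
        assert jsd_sqrt([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0, abs=1e-15)

    def test_frozen_oracle_value(self):
        # direct-summation value for (0.75, 0.25) vs (0.25, 0.75)
        assert jsd_sqrt([0.75, 0.25], [0.25, 0.75]) == pytest.approx(
            0.43442131110348065, abs=1e-12
        )

    def test_agrees_with_direct_summation_and_scipy(self, rng):
        for _ in range(200):
            n = rng.integers(2, 7)
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            v = jsd_sqrt(p, q)
            assert v == pytest.approx(jsd_sqrt_oracle(p, q), abs=1e-12)
            assert v == pytest.approx(jensenshannon(p, q, base=2), abs=1e-9)

    @given(ratio_vector_pairs())
    @settings(deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, pq):
        p, q = pq
        v = jsd_sqrt(p, q)
        assert v == pytest.approx(jsd_sqrt(q, p), abs=1e-12)
        assert 0.0 <= v <= 1.0 + 1e-12

    @given(ratio_vector_pairs(), st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_triangle_inequality(self, pq, seed):
        p, q = pq
        r = np.random.default_rng(seed).dirichlet(np.ones(len(p)))
        assert jsd_sqrt(p, q) <= jsd_sqrt(p, r) + jsd_sqrt(r, q) + 1e-9

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            jsd_sqrt([0.5, 0.6], [0.5, 0.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            jsd_sqrt([0.5, 0.5], [0.3, 0.3, 0.4])


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def exhaustive_oracle_p(matrix, member_ids, n_flight=4):
    """Independent enumeration over all label assignments (test-local oracle).

    Recomputes condition-mean ratio vectors and the direct-summation
    sqrt-JSD for every C(8, 4) assignment with plain python loops.
    """
    cols = list(matrix.values.columns)
    X = {i: [matrix.values.at[i, c] for c in cols] for i in member_ids}

    def stat(flight_idx):
        fl = [np.mean([X[i][j] for j in flight_idx]) for i in member_ids]
        gr_idx = [j for j in range(len(cols)) if j not in flight_idx]
        gr = [np.mean([X[i][j] for j in gr_idx]) for i in member_ids]
        sf, sg = sum(fl), sum(gr)
        if sf == 0 or sg == 0:
            return float("nan")
        return jsd_sqrt_oracle([x / sf for x in fl], [x / sg for x in gr])

    observed = stat(tuple(range(n_flight)))
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(cols)), n_flight):
        total += 1
        s = stat(comb)
        if math.isnan(s) or s >= observed - 1e-12:
            count += 1
    return observed, count / total


class TestPermutationTest:
    def test_identical_columns_give_p_one(self):
        m = one_pair_matrix({"a": [30] * 8, "b": [10] * 8})
        res = permutation_test(m, group_of("a", "b"), PAIR)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.exhaustive and res.n_assignments == 70

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            m = one_pair_matrix({
                "a": list(rng.uniform(5, 100, 8)),
                "b": list(rng.uniform(5, 100, 8)),
                "c": list(rng.uniform(5, 100, 8)),
            })
            g = group_of("a", "b", "c")
            res = permutation_test(m, g, PAIR)
            obs, p = exhaustive_oracle_p(m, g.member_ids)
            assert res.statistic == pytest.approx(obs, abs=1e-12)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_noise_free_complete_switch_attains_minimal_p(self):
        """The true labelling and its mirror are the only assignments
        reaching the observed statistic: p = 2/70."""
        m = one_pair_matrix({"a": [80] * 4 + [20] * 4, "b": [20] * 4 + [80] * 4})
        res = permutation_test(m, group_of("a", "b"), PAIR)
        assert res.p_value == pytest.approx(2 / 70)

    def test_deterministic_given_seed_in_monte_carlo_mode(self):
        m = one_pair_matrix({"a": [80] * 4 + [20] * 4, "b": [20] * 4 + [80] * 4})
        g = group_of("a", "b")
        r1 = permutation_test(m, g, PAIR, n_perm=200, seed=7, exhaustive_limit=1)
        r2 = permutation_test(m, g, PAIR, n_perm=200, seed=7, exhaustive_limit=1)
        assert not r1.exhaustive
        assert r1.p_value == r2.p_value > 0

    def test_too_few_replicates_rejected(self):
        m = one_pair_matrix({"a": [1, 2], "b": [3, 4]}, n_rep=1)
        with pytest.raises(ValueError, match="replicates"):
            permutation_test(m, group_of("a", "b"), PAIR)

    def test_singleton_group_rejected(self):
        m = one_pair_matrix({"a": [1] * 8})
        with pytest.raises(ValueError, match="members"):
            permutation_test(m, group_of("a"), PAIR)


# ---------------------------------------------------------------------------
# dAS calling and switch flags
# ---------------------------------------------------------------------------

def das_result(gene, p, switch=False):
    return DasResult(
        gene_id=gene, tss_key=f"{gene}@chr1:1(+)", member_ids=("a", "b"),
        ratios_flight=(0.7, 0.3), ratios_ground=(0.3, 0.7),
        jsd_sqrt=0.4, p_value=p, n_assignments=70, exhaustive=True,
        switch=switch,
    )


class TestCallDas:
    def test_all_p_one_yields_no_das_genes(self):
        results, genes = call_das([das_result(f"g{i}", 1.0) for i in range(5)])
        assert genes == set()
        assert all(r.q_value == 1.0 for r in results)

    def test_bh_adjustment_matches_hand_computation(self):
        # hand-derived BH on five p-values
        ps = [0.01, 0.02, 0.2, 0.5, 1.0]
        results, genes = call_das(
            [das_result(f"g{i}", p) for i, p in enumerate(ps)], alpha=0.05
        )
        qs = [r.q_value for r in results]
        assert qs == pytest.approx([0.05, 0.05, 1 / 3, 0.625, 1.0])
        assert genes == {"g0", "g1"}

    def test_gene_called_if_any_group_significant(self):
        results, genes = call_das(
            [das_result("g", 0.001), das_result("g", 1.0)], alpha=0.05
        )
        assert genes == {"g"}

    def test_switch_flag_follows_argmax(self):
        m = one_pair_matrix({
            "a": [75] * 4 + [25] * 4,
            "b": [25] * 4 + [75] * 4,
            "c": [100] * 8,
        })
        res_switch = score_tss_group(m, group_of("a", "b"), PAIR, members=["a", "b"])
        assert res_switch.switch
        res_stable = score_tss_group(m, group_of("a", "c"), PAIR, members=["a", "c"])
        assert not res_stable.switch


class TestEcotypeOverlap:
    def test_pooled_overlap_counts(self):
        ov = ecotype_overlap({"Col-0": {"g1", "g2"}, "WS": {"g2", "g3", "g4"}})
        pair = ov["pairs"][("Col-0", "WS")]
        assert pair["common"] == {"g2"}
        assert len(pair["Col-0_only"]) == 1
        assert len(pair["WS_only"]) == 2

    def test_disjoint_and_identical_pools(self):
        ov = ecotype_overlap({"A": {"x"}, "B": {"y"}})
        assert ov["pairs"][("A", "B")]["common"] == frozenset()
        ov2 = ecotype_overlap({"A": {"x"}, "B": {"x"}})
        d = ov2["pairs"][("A", "B")]
        assert not d["A_only"] and not d["B_only"]

    def test_single_background_rejected(self):
        with pytest.raises(ValueError):
            ecotype_overlap({"A": {"x"}})
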